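import numpy as np
import pytest

from crosscount import (
    CountTable,
    FamilyMap,
    ReferenceSet,
    ScoringScheme,
    TranscriptRecord,
)


def make_reference(genes, family_map=None, excluded=(), seed=0):
    """Build a ReferenceSet from {gene_id: (symbol, [sequences...])}."""
    records = []
    for gid, (symbol, seqs) in genes.items():
        for i, seq in enumerate(seqs, start=1):
            records.append(TranscriptRecord(f"{gid}.T{i}", gid, symbol, seq))
    return ReferenceSet.from_records(
        records, excluded=excluded, family_map=FamilyMap(family_map or {})
    )


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def scheme():
    return ScoringScheme()


@pytest.fixture
def toy_ref(rng):
    """Six genes: three singletons, a two-member Krt-like family, one excluded gene."""
    seqs = {f"g{i}": random_seq(rng, 300) for i in range(1, 5)}
    krt = random_seq(rng, 300)
    genes = {
        "GENE_A": ("GeneA", [seqs["g1"]]),
        "GENE_B": ("GeneB", [seqs["g2"]]),
        "GENE_C": ("GeneC", [seqs["g3"]]),
        "GENE_X": ("GeneX", [seqs["g4"]]),  # excluded
        "KRT6A": ("Krt6a", [krt]),
        "KRT6B": ("Krt6b", [krt]),  # identical paralog pair
    }
    return make_reference(
        genes,
        family_map={"Krt6a": "Krt", "Krt6b": "Krt"},
        excluded={"GENE_X"},
    )


def make_counts(matrix, samples, groups, index=None):
    import pandas as pd

    df = pd.DataFrame(np.asarray(matrix), columns=samples)
    if index is not None:
        df.index = index
    else:
        df.index = [f"gene{i}" for i in range(df.shape[0])]
    return CountTable(counts=df, groups=dict(zip(samples, groups)))
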