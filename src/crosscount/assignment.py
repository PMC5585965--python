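"""Per-read adjudication of alignment hits into gene-level counts.

Each read's hit list is reduced to one fate:

1. Antisense-strand hits are dropped first (the library is stranded and the
   merged composite reads carry mRNA sense). A read with only antisense
   hits is ``wrong_strand_only``; with no hits at all, ``unaligned``.
2. The maximum score over the surviving hits is taken and the tied top
   transcripts are collapsed to their genes (the transcript-to-gene
   collapse precedes adjudication, so a tie between two transcripts of one
   gene is silently a unique gene call). "Equivalent score" means exact
   integer equality.
3. A single top gene gives ``unique_gene`` (unless flagged excluded). With
   several top genes, excluded genes are removed first: nothing left is
   ``excluded_only``; one left is ``unique_gene``; several that all share
   one paralog-family symbol collapse to ``family_collapsed`` under that
   family; anything else is ``ambiguous`` and is not counted.

Counting reports unique-gene reads under the family-resolved symbol so that
a family's rows are comparable across species; an un-collapsed per-gene
table can be produced by passing an empty family map.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import SENSE, AlignmentHit, read_divergence
from .reference_db import ExclusionList, ReferenceSet

__all__ = [
    "FATES",
    "ReadAssignment",
    "CountTable",
    "DivergenceSummary",
    "assign_read",
    "count_reads",
    "divergence_profile",
    "propose_exclusions",
]

FATES = (
    "unique_gene",
    "family_collapsed",
    "ambiguous",
    "excluded_only",
    "wrong_strand_only",
    "unaligned",
)

COUNTED_FATES = frozenset({"unique_gene", "family_collapsed"})


@dataclass(frozen=True)
class ReadAssignment:
    """The adjudicated fate of one read.

    ``tied_genes`` records the genes tied at the top score after strand
    filtering and before exclusion handling; it drives the exclusion-list
    reconstruction heuristic.
    """

    read_id: str
    fate: str
    assigned_symbol: str | None = None
    assigned_gene: str | None = None
    best_score: int | None = None
    sdi: float | None = None
    tied_genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if (self.assigned_symbol is not None) != (self.fate in COUNTED_FATES):
            raise ValueError("assigned_symbol must be present iff the read is counted")
        if (self.sdi is None) != (self.best_score is None):
            raise ValueError("sdi present iff best_score present")

    @property
    def counted(self) -> bool:
        return self.fate in COUNTED_FATES


@dataclass
class CountTable:
    """Gene/family symbols x samples integer counts with group labels."""

    counts: pd.DataFrame  # rows: symbols, columns: sample ids
    groups: dict[str, str]

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate row symbols")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_symbols(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_of(self, sample_id: str) -> str:
        return self.groups[sample_id]

    @classmethod
    def from_columns(
        cls, columns: Mapping[str, Mapping[str, int]], groups: Mapping[str, str]
    ) -> "CountTable":
        df = pd.DataFrame(columns).fillna(0).astype(int)
        df = df.sort_index()
        return cls(counts=df, groups=dict(groups))


@dataclass(frozen=True)
class DivergenceSummary:
    """Mean/SD and a 50-bin histogram of per-read divergence (SDI) for one sample."""

    sample_id: str
    n_reads: int
    mean_sdi: float
    sd_sdi: float
    bin_edges: tuple[float, ...]
    densities: tuple[float, ...]


def assign_read(hits: Sequence[AlignmentHit], ref: ReferenceSet) -> ReadAssignment:
    """Adjudicate one read's hit list (see module docstring for the rule)."""
    read_ids = {h.read_id for h in hits}
    if len(read_ids) > 1:
        raise ValueError(f"hits span multiple reads: {sorted(read_ids)}")
    read_id = hits[0].read_id if hits else ""

    sense_hits = [h for h in hits if h.strand == SENSE]
    if not sense_hits:
        fate = "wrong_strand_only" if hits else "unaligned"
        return ReadAssignment(read_id=read_id, fate=fate)

    top = max(h.score for h in sense_hits)
    top_hits = [h for h in sense_hits if h.score == top]
    genes = sorted({ref.gene_of(h.transcript_id) for h in top_hits})
    sdi = read_divergence(top_hits[0])

    def _result(fate: str, gene: str | None, symbol: str | None) -> ReadAssignment:
        return ReadAssignment(
            read_id=read_id,
            fate=fate,
            assigned_symbol=symbol,
            assigned_gene=gene,
            best_score=top,
            sdi=sdi,
            tied_genes=tuple(genes),
        )

    retained = [g for g in genes if g not in ref.excluded]
    if not retained:
        return _result("excluded_only", None, None)
    if len(retained) == 1:
        g = retained[0]
        return _result("unique_gene", g, ref.family_of_gene(g))
    families = {ref.family_of_gene(g) for g in retained}
    if len(families) == 1:
        return _result("family_collapsed", None, families.pop())
    return _result("ambiguous", None, None)


def count_reads(
    assignments: Iterable[ReadAssignment],
    sample_id: str,
    ref: ReferenceSet | None = None,
) -> tuple[Counter, Counter]:
    """Aggregate one sample's assignments into a count column and a fate tally.

    Returns ``(column, tally)``: ``column`` maps row symbol -> count over the
    counted fates only (so its total equals ``tally["unique_gene"] +
    tally["family_collapsed"]``); ``tally`` maps fate -> reads.
    """
    column: Counter = Counter()
    tally: Counter = Counter({f: 0 for f in FATES})
    for a in assignments:
        tally[a.fate] += 1
        if a.counted:
            column[a.assigned_symbol] += 1
    return column, tally


def divergence_profile(
    assignments: Iterable[ReadAssignment], sample_id: str, n_bins: int = 50
) -> DivergenceSummary:
    """Mean, SD and a 50-bin density histogram of SDI over the counted reads."""
    sdis = np.array([a.sdi for a in assignments if a.counted], dtype=float)
    if sdis.size == 0:
        raise ValueError(f"sample {sample_id!r}: no counted reads")
    upper = max(float(sdis.max()), 1e-9)
    dens, edges = np.histogram(sdis, bins=n_bins, range=(0.0, upper))
    dens = dens / dens.sum()
    return DivergenceSummary(
        sample_id=sample_id,
        n_reads=int(sdis.size),
        mean_sdi=float(sdis.mean()),
        sd_sdi=float(sdis.std(ddof=0)),
        bin_edges=tuple(float(e) for e in edges),
        densities=tuple(float(d) for d in dens),
    )


def propose_exclusions(
    assignments: Iterable[ReadAssignment],
    ref: ReferenceSet,
    min_fraction: float = 0.5,
    min_reads: int = 10,
) -> tuple[ExclusionList, pd.DataFrame]:
    """Reconstruction heuristic for the curated exclusion list.

    From assignments computed with an *empty* exclusion list, propose genes
    whose share of equal-top-score multi-gene involvement exceeds
    ``min_fraction`` with at least ``min_reads`` supporting reads — the
    signature of duplicate annotations, pseudogene copies and overlapping
    genes. Returns the candidate list plus a table annotated with each
    gene's tie fraction and most frequent partner genes, ordered by
    (fraction desc, gene_id). This is an explicit heuristic, not a claimed
    reproduction of any curated list.
    """
    if ref.excluded:
        raise ValueError("propose_exclusions expects assignments from an un-excluded reference")
    top_involvement: Counter = Counter()
    tie_involvement: Counter = Counter()
    partners: dict[str, Counter] = {}
    for a in assignments:
        if a.best_score is None:
            continue
        for g in a.tied_genes:
            top_involvement[g] += 1
            if len(a.tied_genes) > 1:
                tie_involvement[g] += 1
                partners.setdefault(g, Counter()).update(
                    p for p in a.tied_genes if p != g
                )
    rows = []
    for g, n_tie in tie_involvement.items():
        frac = n_tie / top_involvement[g]
        if frac > min_fraction and n_tie >= min_reads:
            top_partners = ",".join(p for p, _ in partners[g].most_common(3))
            rows.append({"gene_id": g, "tie_fraction": frac, "tie_reads": n_tie,
                         "partners": top_partners})
    table = pd.DataFrame(rows, columns=["gene_id", "tie_fraction", "tie_reads", "partners"])
    if not table.empty:
        table = table.sort_values(
            ["tie_fraction", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    excl = ExclusionList.from_ids(
        table["gene_id"].tolist(),
        {r.gene_id: f"tie_fraction={r.tie_fraction:.3f}" for r in table.itertuples()},
    )
    return excl, table
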