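"""Model-species CDS reference handling.

The alignment target space of the pipeline is a set of protein-coding
transcript sequences (e.g. the GENCODE mouse ``pc_transcripts`` FASTA).
Each transcript belongs to exactly one gene; counting happens at the gene
level (ENSMUST-style transcript ids are collapsed to ENSMUSG-style gene
ids), optionally further collapsed to paralog-family symbols (Lce, Sprr,
Krt clusters), and a curated exclusion list flags genes whose counts are
unreliable (pseudogenes, duplicate/overlapping annotations).

Excluded genes are *flagged*, never removed: their transcripts stay in the
alignment target set so that multi-map adjudication can distinguish a read
that would only hit excluded genes from one that never aligned at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "ReferenceSet",
    "FamilyMap",
    "ExclusionList",
    "load_reference",
    "write_reference",
    "load_family_map",
    "load_exclusion_list",
    "apply_exclusions",
    "family_symbol",
]

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class TranscriptRecord:
    """One CDS transcript: unique transcript id, owning gene id, symbol, sequence."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for transcript {self.transcript_id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class FamilyMap:
    """Gene-symbol -> paralog-family-symbol map (e.g. Sprr2a1 -> Sprr2, Krt24 -> Krt).

    Family symbols are fixed points: composing the map with itself changes nothing.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for sym, fam in self.entries.items():
            # fixed-point requirement: a family symbol never maps elsewhere
            if fam in self.entries and self.entries[fam] != fam:
                raise ValueError(
                    f"family symbol {fam!r} (target of {sym!r}) itself maps to "
                    f"{self.entries[fam]!r}; family symbols must be fixed points"
                )

    def __getitem__(self, symbol: str) -> str:
        return self.entries.get(symbol, symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries


@dataclass(frozen=True)
class ExclusionList:
    """Curated gene ids to exclude from counting, with optional per-id reasons."""

    gene_ids: frozenset[str]
    reasons: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_ids(cls, ids: Iterable[str], reasons: Mapping[str, str] | None = None):
        return cls(gene_ids=frozenset(ids), reasons=dict(reasons or {}))


@dataclass(frozen=True)
class ReferenceSet:
    """An indexed CDS reference: transcripts, gene index, symbols, exclusions, families."""

    transcripts: tuple[TranscriptRecord, ...]
    gene_index: Mapping[str, tuple[str, ...]]
    symbol_map: Mapping[str, str]
    excluded: frozenset[str] = frozenset()
    family_map: FamilyMap = field(default_factory=FamilyMap)

    @classmethod
    def from_records(
        cls,
        records: Iterable[TranscriptRecord],
        excluded: Iterable[str] = (),
        family_map: FamilyMap | None = None,
    ) -> "ReferenceSet":
        records = tuple(records)
        if not records:
            raise ValueError("no records")
        seen: set[str] = set()
        gene_index: dict[str, list[str]] = {}
        symbol_map: dict[str, str] = {}
        for rec in records:
            if rec.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {rec.transcript_id!r}")
            seen.add(rec.transcript_id)
            gene_index.setdefault(rec.gene_id, []).append(rec.transcript_id)
            prev = symbol_map.setdefault(rec.gene_id, rec.gene_symbol)
            if prev != rec.gene_symbol:
                raise ValueError(
                    f"gene {rec.gene_id!r} carries two symbols: {prev!r}, {rec.gene_symbol!r}"
                )
        return cls(
            transcripts=records,
            gene_index={g: tuple(ts) for g, ts in gene_index.items()},
            symbol_map=symbol_map,
            excluded=frozenset(excluded),
            family_map=family_map or FamilyMap(),
        )

    # -- lookups -------------------------------------------------------------

    def transcript(self, transcript_id: str) -> TranscriptRecord:
        return self._by_transcript[transcript_id]

    @property
    def _by_transcript(self) -> dict[str, TranscriptRecord]:
        cached = self.__dict__.get("_by_transcript_cache")
        if cached is None:
            cached = {t.transcript_id: t for t in self.transcripts}
            object.__setattr__(self, "_by_transcript_cache", cached)
        return cached

    def gene_of(self, transcript_id: str) -> str:
        return self.transcript(transcript_id).gene_id

    def symbol_of_gene(self, gene_id: str) -> str:
        return self.symbol_map[gene_id]

    def family_of_gene(self, gene_id: str) -> str:
        return self.family_map[self.symbol_map[gene_id]]

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.gene_index)

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    def with_family_map(self, family_map: FamilyMap) -> "ReferenceSet":
        return replace(self, family_map=family_map)


def _parse_header(description: str, header_dialect: str, symbol_field: int) -> tuple[str, str, str]:
    if header_dialect == "pipe_delimited":
        fields = description.split("|")
        if len(fields) < 3:
            raise ValueError(
                f"malformed pipe-delimited header {description!r}: "
                "expected at least transcript_id|gene_id|gene_symbol"
            )
        symbol_ix = symbol_field if symbol_field < len(fields) else 2
        return fields[0], fields[1], fields[symbol_ix]
    if header_dialect == "plain":
        return description.split()[0], "", ""
    raise ValueError(f"unknown header dialect {header_dialect!r}")


def load_reference(
    fasta_path: str | Path,
    header_dialect: str = "pipe_delimited",
    id_map: Mapping[str, tuple[str, str]] | None = None,
    symbol_field: int = 2,
) -> ReferenceSet:
    """Parse a CDS transcript FASTA into an indexed :class:`ReferenceSet`.

    Parameters
    ----------
    fasta_path
        FASTA of CDS transcript sequences (upper- or lower-case; Ns allowed).
    header_dialect
        ``"pipe_delimited"`` expects GENCODE-style headers with the transcript
        id in field 0 and the gene id in field 1; the symbol is taken from
        ``symbol_field`` (default field 2; pass 5 for a full ``pc_transcripts``
        header where the symbol sits in the sixth field). ``"plain"`` expects a
        bare transcript id and requires ``id_map``.
    id_map
        For the plain dialect: transcript_id -> (gene_id, gene_symbol),
        typically loaded from a sidecar TSV.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(str(fasta_path))
    records: list[TranscriptRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tid, gid, sym = _parse_header(rec.description, header_dialect, symbol_field)
        if header_dialect == "plain":
            if id_map is None or tid not in id_map:
                raise ValueError(
                    f"plain-dialect record {tid!r} has no entry in the sidecar id map"
                )
            gid, sym = id_map[tid]
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {tid!r}: empty sequence")
        records.append(TranscriptRecord(tid, gid, sym, seq))
    if not records:
        raise ValueError(f"no records in {fasta_path}")
    return ReferenceSet.from_records(records)


def write_reference(ref: ReferenceSet, fasta_path: str | Path) -> None:
    """Write a reference back to FASTA with pipe-delimited headers (load round-trips)."""
    recs = [
        SeqRecord(
            Seq(t.sequence),
            id=f"{t.transcript_id}|{t.gene_id}|{t.gene_symbol}",
            description="",
        )
        for t in ref.transcripts
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")


def load_family_map(tsv_path: str | Path) -> FamilyMap:
    """Load a two-column TSV (gene_symbol <TAB> family_symbol)."""
    entries: dict[str, str] = {}
    for line in Path(tsv_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, fam = line.split("\t")[:2]
        if sym in entries and entries[sym] != fam:
            raise ValueError(f"symbol {sym!r} maps to two families: {entries[sym]!r}, {fam!r}")
        entries[sym] = fam
    for fam in set(entries.values()):
        entries.setdefault(fam, fam)
    return FamilyMap(entries=entries)


def load_exclusion_list(tsv_path: str | Path) -> ExclusionList:
    """Load a TSV of gene_id [<TAB> reason] rows."""
    ids: list[str] = []
    reasons: dict[str, str] = {}
    for line in Path(tsv_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        ids.append(parts[0])
        if len(parts) > 1 and parts[1]:
            reasons[parts[0]] = parts[1]
    return ExclusionList.from_ids(ids, reasons)


def apply_exclusions(ref: ReferenceSet, excl: ExclusionList) -> ReferenceSet:
    """Flag excluded genes on a reference (idempotent; transcripts stay alignable).

    Exclusion ids absent from the reference are reported via ``warnings.warn``
    and skipped, never fatal.
    """
    known = ref.gene_ids
    unknown = sorted(set(excl.gene_ids) - known)
    if unknown:
        warnings.warn(
            f"{len(unknown)} exclusion-list gene id(s) not in the reference "
            f"(first few: {unknown[:5]})",
            stacklevel=2,
        )
    return replace(ref, excluded=ref.excluded | (frozenset(excl.gene_ids) & known))


def family_symbol(symbol: str, fm: FamilyMap) -> str:
    """Resolve a gene symbol to its paralog-family symbol (identity if unmapped)."""
    return fm[symbol]
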