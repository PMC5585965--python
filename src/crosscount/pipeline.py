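"""End-to-end orchestration: align -> assign/count -> normalize -> MDS/BCV -> DE -> enrichment.

Mirrors the analysis surface of the cross-species map-and-count study:
stranded reads from each sample are aligned to the CDS reference, assigned
to genes by maximum score with paralog-aware adjudication, counted
(per-gene and family-collapsed), filtered at 5 CPM in >= 3 samples, TMM
normalized, summarized (MDS, BCV, divergence profiles, between-group
correlation), tested for differential abundance, and the per-direction
ranked lists fed to ordered enrichment. Every stage writes TSV artifacts
plus a JSON run manifest; a stage failure leaves partial outputs and a
FAILED marker naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from . import __version__
from .aligner import KmerIndex, ScoringScheme, align_read
from .assignment import CountTable, assign_read, count_reads, divergence_profile
from .de_test import TEST_METADATA, nb_test, ranked_lists, results_to_table
from .enrichment import calibrate_threshold, compare_lists, load_gmt
from .expression import (
    dispersion_bcv,
    filter_detected,
    group_correlation,
    mds_leading,
    normalize,
)
from .reference_db import (
    ReferenceSet,
    apply_exclusions,
    load_exclusion_list,
    load_family_map,
    load_reference,
)

log = logging.getLogger("crosscount")

__all__ = ["PipelineConfig", "run_pipeline", "quantify_samples", "self_vs_cross"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one full run; loadable from a TOML file."""

    reference: str
    reads: dict[str, str]  # sample_id -> FASTQ/FASTA path
    groups: dict[str, str]  # sample_id -> group label
    out_dir: str = "crosscount_out"
    exclusion_list: str | None = None
    family_map: str | None = None
    gene_sets: str | None = None
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    align_mode: str = "seed"
    seed_k: int = 12
    cpm_min: float = 5.0
    min_below: int = 3
    mds_top_genes: int = 500
    fdr: float = 0.01
    ranked_n: int = 1000
    enrich_alpha: float = 0.05
    enrich_n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        scoring = ScoringScheme(**raw.pop("scoring", {}))
        return cls(scoring=scoring, **raw)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.reference, self.exclusion_list, self.family_map, self.gene_sets,
                      *self.reads.values()]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if set(self.reads) != set(self.groups):
            raise ValueError("reads and groups must cover the same sample ids")

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["scoring"] = dataclasses.asdict(self.scoring)
        d["version"] = __version__
        d["de_test"] = TEST_METADATA
        return d


def _read_sequences(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def quantify_samples(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    ref: ReferenceSet,
    scoring: ScoringScheme = ScoringScheme(),
    groups: dict[str, str] | None = None,
    mode: str = "seed",
    seed_k: int = 12,
) -> dict:
    """Align + assign + count every sample against one reference.

    Returns a dict with per-gene and family-collapsed :class:`CountTable`s,
    fate tallies, per-sample assignments and divergence summaries. In the
    per-gene table, family-collapsed reads appear under their family symbol
    (they have no single member gene); unique-gene reads appear under the
    gene symbol. In the family table every family member's reads fold into
    the family row.
    """
    index = KmerIndex.build(ref, k=seed_k) if mode == "seed" else None
    ref_nofam = dataclasses.replace(ref, family_map=type(ref.family_map)())
    gene_cols, fam_cols, tallies, assignments, divergence = {}, {}, {}, {}, {}
    for sample, reads in reads_by_sample.items():
        t0 = time.time()
        asn_fam, asn_gene = [], []
        for read_id, seq in reads:
            hits = align_read(seq, ref, scoring, read_id=read_id, mode=mode, index=index)
            asn_fam.append(assign_read(hits, ref))
            asn_gene.append(assign_read(hits, ref_nofam))
        fam_cols[sample], tallies[sample] = count_reads(asn_fam, sample)
        gene_cols[sample], _ = count_reads(asn_gene, sample)
        assignments[sample] = asn_fam
        if any(a.counted for a in asn_fam):
            divergence[sample] = divergence_profile(asn_fam, sample)
        log.info(
            "sample %s: %d reads in %.1fs; fates %s",
            sample, len(reads), time.time() - t0, dict(tallies[sample]),
        )
    groups = groups or {s: s for s in reads_by_sample}
    return {
        "gene_counts": CountTable.from_columns(gene_cols, groups),
        "family_counts": CountTable.from_columns(fam_cols, groups),
        "fate_tallies": pd.DataFrame(tallies).fillna(0).astype(int),
        "assignments": assignments,
        "divergence": divergence,
    }


def _write_divergence(divergence: dict, out: Path) -> None:
    rows = [
        {"sample_id": d.sample_id, "n_reads": d.n_reads, "mean_sdi": d.mean_sdi, "sd_sdi": d.sd_sdi}
        for d in divergence.values()
    ]
    pd.DataFrame(rows).to_csv(out / "divergence_summary.tsv", sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig, stop_after: str | None = None) -> dict:
    """Run every stage, writing artifacts under ``cfg.out_dir``; returns them in memory.

    ``stop_after="count"`` stops once count matrices and divergence
    summaries are written (the ``count`` subcommand).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    results: dict = {}
    try:
        (out / "manifest.json").write_text(json.dumps(cfg.manifest(), indent=2))

        stage = "reference"
        ref = load_reference(cfg.reference)
        if cfg.family_map:
            ref = ref.with_family_map(load_family_map(cfg.family_map))
        if cfg.exclusion_list:
            ref = apply_exclusions(ref, load_exclusion_list(cfg.exclusion_list))

        stage = "align_count"
        reads = {s: _read_sequences(p) for s, p in cfg.reads.items()}
        q = quantify_samples(reads, ref, cfg.scoring, cfg.groups, cfg.align_mode, cfg.seed_k)
        results.update(q)
        q["gene_counts"].counts.to_csv(out / "counts_gene.tsv", sep="\t")
        q["family_counts"].counts.to_csv(out / "counts_family.tsv", sep="\t")
        q["fate_tallies"].to_csv(out / "fate_tally.tsv", sep="\t")
        _write_divergence(q["divergence"], out)
        if stop_after == "count":
            return results

        stage = "filter_normalize"
        detected = filter_detected(q["family_counts"], cfg.cpm_min, cfg.min_below)
        norm = normalize(detected)
        results["detected"] = detected
        results["normalized"] = norm
        norm.norm_factors.to_frame().to_csv(out / "norm_factors.tsv", sep="\t")
        norm.log2_cpm.to_csv(out / "log2_cpm.tsv", sep="\t")
        log.info("detected %d of %d rows", detected.counts.shape[0], q["family_counts"].counts.shape[0])

        stage = "mds_bcv"
        mds = mds_leading(detected, cfg.mds_top_genes, norm_factors=norm.norm_factors)
        disp = dispersion_bcv(detected, norm_factors=norm.norm_factors)
        rho = group_correlation(detected, norm_factors=norm.norm_factors)
        results.update(mds=mds, dispersion=disp, group_correlation=rho)
        mds.coordinates.to_csv(out / "mds_coordinates.tsv", sep="\t")
        pd.DataFrame(
            {"eigenvalue": mds.eigenvalues, "variance_explained": mds.variance_explained}
        ).to_csv(out / "mds_eigenvalues.tsv", sep="\t", index=False)
        (out / "summary_stats.json").write_text(
            json.dumps(
                {"bcv": disp.bcv, "common_dispersion": disp.common_dispersion,
                 "spearman_between_groups": rho,
                 "n_detected": int(detected.counts.shape[0])},
                indent=2,
            )
        )
        log.info("BCV %.3f; between-group Spearman %.3f", disp.bcv, rho)

        stage = "de"
        de = nb_test(detected, disp, fdr=cfg.fdr, norm_factors=norm.norm_factors)
        results["de"] = de
        results_to_table(de).to_csv(out / "de_results.tsv", sep="\t", index=False)
        up_a, up_b = ranked_lists(de, n=cfg.ranked_n)
        results["ranked"] = (up_a, up_b)
        (out / "ranked_up_A.txt").write_text("\n".join(up_a.symbols) + "\n")
        (out / "ranked_up_B.txt").write_text("\n".join(up_b.symbols) + "\n")
        n_sig = sum(r.significant for r in de)
        log.info("%d significant at FDR<%g (%d up in A, %d up in B)",
                 n_sig, cfg.fdr, len(up_a.symbols), len(up_b.symbols))

        if cfg.gene_sets:
            stage = "enrichment"
            gsc = load_gmt(cfg.gene_sets, universe=detected.row_symbols)
            length = max(len(up_a.symbols), len(up_b.symbols))
            thr = None
            if length:
                thr = calibrate_threshold(
                    gsc, length, cfg.enrich_alpha, cfg.enrich_n_perm, seed=cfg.seed
                )
            paired = compare_lists(up_a.symbols, up_b.symbols, gsc, threshold=thr)
            results["enrichment"] = paired
            results["enrichment_threshold"] = thr
            paired.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results


def self_vs_cross(
    species_reads: dict[str, list[tuple[str, str]]] | list[tuple[str, str]],
    self_reference: ReferenceSet,
    ancestral_reference: ReferenceSet,
    scoring: ScoringScheme = ScoringScheme(),
    mode: str = "seed",
    ortholog_map: dict[str, str] | None = None,
) -> dict:
    """Validation analog: quantify the same reads against 'self' and ancestral targets.

    Runs assignment twice — once with the species' own transcripts as the
    target set, once with the ancestral (model-species) reference — joins
    per-gene counts through ``ortholog_map`` (identity by default, as for
    simulated descendants that keep ancestral gene ids), and reports Pearson
    and Spearman correlations over genes detected (nonzero) in both
    mappings, plus the paired count table.
    """
    if isinstance(species_reads, list):
        species_reads = {"sample": species_reads}
    q_self = quantify_samples(species_reads, self_reference, scoring, mode=mode)
    q_cross = quantify_samples(species_reads, ancestral_reference, scoring, mode=mode)
    self_counts = q_self["gene_counts"].counts.sum(axis=1)
    cross_counts = q_cross["gene_counts"].counts.sum(axis=1)
    if ortholog_map is not None:
        self_counts = self_counts.rename(index=ortholog_map)
        self_counts = self_counts.groupby(level=0).sum()
    paired = pd.concat(
        [self_counts.rename("self"), cross_counts.rename("cross")], axis=1
    ).fillna(0)
    both = paired[(paired["self"] > 0) & (paired["cross"] > 0)]
    if both.empty:
        raise ValueError("no gene detected in both mappings")
    pearson = float(stats.pearsonr(both["self"], both["cross"]).statistic)
    spearman = float(stats.spearmanr(both["self"], both["cross"]).statistic)
    log.info("self-vs-cross: %d shared genes, Pearson %.4f, Spearman %.4f",
             both.shape[0], pearson, spearman)
    return {
        "paired_counts": paired,
        "n_shared": int(both.shape[0]),
        "pearson": pearson,
        "spearman": spearman,
        "fate_tallies_self": q_self["fate_tallies"],
        "fate_tallies_cross": q_cross["fate_tallies"],
    }
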