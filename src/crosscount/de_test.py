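"""Two-group negative-binomial differential abundance testing.

The test is an exact-style NB conditional test at a common dispersion: with
counts equalized to a common effective library size, the within-group sums
are negative-binomial, and the distribution of group A's sum conditional on
the grand total is free of the gene's mean. The two-sided p-value doubles
the smaller conditional tail (capped at 1). At dispersion zero the NB sums
become Poisson and the conditional law is exactly binomial.

Fold-changes are log2 ratios of offset-normalized group means with a 0.5
pseudocount per group, so on/off genes get large finite values.
Benjamini-Hochberg step-up correction yields q-values; ranked lists for
ordered enrichment are the per-direction top genes sorted by fold-change
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .assignment import CountTable
from .expression import DispersionEstimate, _group_blocks

__all__ = [
    "DEResult",
    "RankedList",
    "nb_test",
    "bh_adjust",
    "ranked_lists",
    "results_to_table",
]

TEST_METADATA = (
    "exact-style NB conditional test at common dispersion "
    "(two-sided, doubled smaller tail)"
)


@dataclass(frozen=True)
class DEResult:
    symbol: str
    log2_fc: float  # group A over group B
    p_value: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class RankedList:
    """Symbols ordered by descending log2 fold-change magnitude in one direction."""

    direction: str  # group label the genes are up in
    symbols: tuple[str, ...]


def _exact_nb_p(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided conditional p-value for group sums (sa, sb) at dispersion phi."""
    t = sa + sb
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if phi <= 0:
        # Poisson limit: conditional law is Binomial(t, na/(na+nb))
        logp = stats.binom.logpmf(s, t, na / (na + nb))
    else:
        r = 1.0 / phi
        ra, rb = na * r, nb * r
        logp = (
            special.gammaln(s + ra)
            - special.gammaln(s + 1)
            - special.gammaln(ra)
            + special.gammaln(t - s + rb)
            - special.gammaln(t - s + 1)
            - special.gammaln(rb)
        )
        logp -= special.logsumexp(logp)
    p = np.exp(logp)
    lower = p[: sa + 1].sum()
    upper = p[sa:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_test(
    table: CountTable,
    dispersion: DispersionEstimate | float,
    fdr: float = 0.01,
    norm_factors: pd.Series | None = None,
    group_a: str | None = None,
) -> list[DEResult]:
    """Per-gene exact-style NB test between the table's two groups.

    ``group_a`` names the focal group (numerator of the fold-change);
    defaults to the first group in sample order. Offsets are library size
    times normalization factor; counts are equalized to the geometric-mean
    effective library before the conditional test.
    """
    phi = dispersion.common_dispersion if isinstance(dispersion, DispersionEstimate) else float(dispersion)
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    labels = [table.group_of(s) for s in table.sample_ids]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    if group_a is None:
        group_a = uniq[0]
    group_b = uniq[1] if group_a == uniq[0] else uniq[0]
    ix_a = np.array([j for j, l in enumerate(labels) if l == group_a])
    ix_b = np.array([j for j, l in enumerate(labels) if l == group_b])
    if ix_a.size < 2 or ix_b.size < 2:
        raise ValueError("each group needs at least two samples")

    counts = table.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(table.sample_ids).to_numpy()
    n_geo = np.exp(np.mean(np.log(lib)))
    pseudo = counts * (n_geo / lib)[None, :]

    sa = np.rint(pseudo[:, ix_a].sum(axis=1)).astype(np.int64)
    sb = np.rint(pseudo[:, ix_b].sum(axis=1)).astype(np.int64)
    mean_a = pseudo[:, ix_a].mean(axis=1)
    mean_b = pseudo[:, ix_b].mean(axis=1)
    lfc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    pvals = np.array(
        [_exact_nb_p(int(a), int(b), ix_a.size, ix_b.size, phi) for a, b in zip(sa, sb)]
    )
    qvals = bh_adjust(pvals)
    return [
        DEResult(
            symbol=sym,
            log2_fc=float(l),
            p_value=float(p),
            q_value=float(q),
            significant=bool(q < fdr),
        )
        for sym, l, p, q in zip(table.row_symbols, lfc, pvals, qvals)
    ]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ranked_lists(
    results: list[DEResult], n: int = 1000, significant_only: bool = True
) -> tuple[RankedList, RankedList]:
    """Per-direction top-``n`` gene lists ordered by |log2FC| descending.

    The A-up list holds genes with positive log2FC sorted descending, the
    B-up list genes with negative log2FC sorted by magnitude descending;
    ties break alphabetically; genes with log2FC exactly 0 appear in
    neither. With ``significant_only`` (default) only FDR-significant genes
    are ranked.
    """
    if not results:
        raise ValueError("no results")
    pool = [r for r in results if r.significant] if significant_only else list(results)
    up_a = sorted(
        (r for r in pool if r.log2_fc > 0), key=lambda r: (-r.log2_fc, r.symbol)
    )
    up_b = sorted(
        (r for r in pool if r.log2_fc < 0), key=lambda r: (r.log2_fc, r.symbol)
    )
    return (
        RankedList(direction="A", symbols=tuple(r.symbol for r in up_a[:n])),
        RankedList(direction="B", symbols=tuple(r.symbol for r in up_b[:n])),
    )


def results_to_table(results: list[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame (TSV-ready); carries the test description as metadata."""
    df = pd.DataFrame(
        [
            {
                "symbol": r.symbol,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    df.attrs["test"] = TEST_METADATA
    return df
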