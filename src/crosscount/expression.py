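"""Filtering, normalization and exploratory statistics on the count matrix.

Implements the standard bulk RNA-seq preprocessing applied to map-and-count
output: a counts-per-million detection filter (drop genes below 5 CPM in
three or more samples), trimmed-mean-of-M-values (TMM) normalization to
remove between-library composition bias, a common negative-binomial
dispersion / biological coefficient of variation (BCV) estimate by
conditional maximum likelihood, leading-log-fold-change multidimensional
scaling, and between-group rank correlation.

TMM follows the published algorithm: per-gene log2 ratios (M) and average
log2 abundances (A) against a reference sample, double trimming (30% on M,
5% on A by default), precision weighting by the asymptotic binomial
variance, and re-centering of the factors to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .assignment import CountTable

__all__ = [
    "NormalizedCounts",
    "DispersionEstimate",
    "MdsResult",
    "cpm",
    "filter_detected",
    "tmm_factors",
    "normalize",
    "dispersion_bcv",
    "mds_leading",
    "group_correlation",
    "sample_correlation_matrix",
]


@dataclass(frozen=True)
class NormalizedCounts:
    source: CountTable
    library_sizes: pd.Series
    norm_factors: pd.Series  # geometric mean 1
    log2_cpm: pd.DataFrame


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion phi; BCV = sqrt(phi)."""

    common_dispersion: float

    @property
    def bcv(self) -> float:
        return float(np.sqrt(self.common_dispersion))


@dataclass(frozen=True)
class MdsResult:
    coordinates: pd.DataFrame  # samples x dimensions
    eigenvalues: np.ndarray  # non-increasing
    variance_explained: np.ndarray  # eigenvalue / sum of positive eigenvalues


def cpm(
    table: CountTable,
    log: bool = False,
    prior: float = 0.5,
    norm_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million: count / effective library size * 1e6.

    With ``log=True``, returns log2((count + prior) / effective_lib * 1e6),
    pseudocount ``prior`` (default 0.5) keeping zeros finite.
    """
    lib = table.library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if norm_factors is not None:
        lib = lib * norm_factors
    if log:
        return np.log2((table.counts + prior).div(lib, axis=1) * 1e6)
    return table.counts.div(lib, axis=1) * 1e6


def filter_detected(table: CountTable, cpm_min: float = 5.0, min_below: int = 3) -> CountTable:
    """Drop genes with CPM below ``cpm_min`` in ``min_below`` or more samples.

    The detection rule of the pipeline ("below 5 CPM in three or more
    samples were removed"); idempotent, row order preserved.
    """
    if table.counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    c = cpm(table)
    keep = (c < cpm_min).sum(axis=1) < min_below
    return CountTable(counts=table.counts.loc[keep].copy(), groups=dict(table.groups))


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_logfc: float,
    trim_abundance: float,
) -> float:
    """Single TMM factor of one sample against the reference sample (log2 scale -> linear)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        raise ValueError("disjoint supports: no gene expressed in both samples")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_logfc) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_abundance) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    table: CountTable,
    trim_logfc: float = 0.30,
    trim_abundance: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample defaults to the column whose 75th count percentile
    (scaled by library size) is closest to the mean across samples.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = counts.sum(axis=0)
    samples = table.sample_ids
    if ref_sample is None:
        f75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(len(samples))]) / lib
        ref_ix = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_ix = samples.index(ref_sample)
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref_ix:
            continue
        factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref_ix], lib[j], lib[ref_ix], trim_logfc, trim_abundance
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="norm_factor")


def normalize(table: CountTable, prior: float = 0.5) -> NormalizedCounts:
    """Library sizes + TMM factors + log2 CPM in one container."""
    nf = tmm_factors(table)
    return NormalizedCounts(
        source=table,
        library_sizes=table.library_sizes,
        norm_factors=nf,
        log2_cpm=cpm(table, log=True, prior=prior, norm_factors=nf),
    )


# ---------------------------------------------------------------------------
# common dispersion / BCV
# ---------------------------------------------------------------------------


def _group_blocks(table: CountTable) -> list[np.ndarray]:
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(table.sample_ids):
        groups.setdefault(table.group_of(s), []).append(j)
    return [np.asarray(ix) for ix in groups.values()]


def dispersion_bcv(
    table: CountTable, norm_factors: pd.Series | None = None
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood within groups.

    Counts are first equalized to the geometric-mean effective library size
    (linear scaling); the conditional log-likelihood of each gene's counts
    given their within-group sum — which is free of the gene's mean under
    equal library sizes — is summed over genes and groups and maximized over
    the dispersion. BCV is the square root of the dispersion.
    """
    counts = table.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(table.sample_ids).to_numpy()
    blocks = [ix for ix in _group_blocks(table) if ix.size >= 2]
    if not blocks:
        raise ValueError("no group with at least two samples")
    n_geo = np.exp(np.mean(np.log(lib)))
    pseudo = counts * (n_geo / lib)[None, :]

    parts = []  # (y matrix, n) per group, genes with positive totals only
    for ix in blocks:
        y = pseudo[:, ix]
        z = y.sum(axis=1)
        y = y[z > 0]
        if y.size:
            parts.append((y, ix.size))
    if not parts:
        raise ValueError("all counts zero")

    def neg_cll(log_phi: float) -> float:
        r = np.exp(-log_phi)  # 1/phi
        total = 0.0
        for y, n in parts:
            z = y.sum(axis=1)
            ll = (
                special.gammaln(y + r).sum(axis=1)
                - n * special.gammaln(r)
                + special.gammaln(n * r)
                - special.gammaln(z + n * r)
            )
            total += ll.sum()
        return -total

    res = optimize.minimize_scalar(neg_cll, bounds=(np.log(1e-6), np.log(10.0)), method="bounded")
    phi = float(np.exp(res.x))
    if phi <= 2e-6:  # optimum at the lower bound: Poisson-like data
        phi = 0.0
    return DispersionEstimate(common_dispersion=phi)


# ---------------------------------------------------------------------------
# leading-logFC MDS
# ---------------------------------------------------------------------------


def mds_leading(
    table: CountTable,
    top_genes: int = 500,
    n_dim: int | None = None,
    prior: float = 0.5,
    norm_factors: pd.Series | None = None,
) -> MdsResult:
    """Classical MDS on pairwise leading-log-fold-change distances.

    The distance between two samples is the root-mean-square log2
    fold-change over the ``top_genes`` genes with the largest absolute
    fold-change *for that pair* (computed on log2 CPM), the standard
    "leading logFC" MDS for RNA-seq samples.
    """
    n = len(table.sample_ids)
    if n < 3:
        raise ValueError("need at least three samples")
    x = cpm(table, log=True, prior=prior, norm_factors=norm_factors).to_numpy()
    top = min(top_genes, x.shape[0])
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (x[:, i] - x[:, j]) ** 2
            lead = np.sort(diff2)[-top:]
            d2[i, j] = d2[j, i] = lead.mean()
    # classical (Torgerson) MDS by double-centering
    jmat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * jmat @ d2 @ jmat
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n_dim is None:
        n_dim = n - 1
    n_dim = min(n_dim, n - 1)
    pos = np.clip(evals[:n_dim], 0.0, None)
    coords = evecs[:, :n_dim] * np.sqrt(pos)[None, :]
    pos_sum = evals[evals > 0].sum()
    var_exp = np.zeros(n_dim) if pos_sum <= 0 else np.clip(evals[:n_dim], 0, None) / pos_sum
    return MdsResult(
        coordinates=pd.DataFrame(
            coords, index=table.sample_ids, columns=[f"dim{k+1}" for k in range(n_dim)]
        ),
        eigenvalues=evals[:n_dim],
        variance_explained=var_exp,
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def group_correlation(
    table: CountTable,
    method: str = "spearman",
    prior: float = 0.5,
    norm_factors: pd.Series | None = None,
) -> float:
    """Rank (or Pearson) correlation of per-group mean log2 CPM between the two groups."""
    blocks = _group_blocks(table)
    if len(blocks) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(blocks)}")
    x = cpm(table, log=True, prior=prior, norm_factors=norm_factors).to_numpy()
    a = x[:, blocks[0]].mean(axis=1)
    b = x[:, blocks[1]].mean(axis=1)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def sample_correlation_matrix(
    table: CountTable,
    method: str = "spearman",
    prior: float = 0.5,
    norm_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Full sample-by-sample correlation matrix of log2 CPM profiles."""
    x = cpm(table, log=True, prior=prior, norm_factors=norm_factors)
    return x.corr(method=method)
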