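"""CPM, detection filter, TMM factors, BCV estimation, MDS and correlations."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import crosscount as cc

from conftest import make_counts


def equal_lib_counts(rows, lib=1_000_000):
    """Counts whose columns each sum to ``lib`` so CPM equals the stated values."""
    rows = np.asarray(rows, dtype=int)
    filler = lib - rows.sum(axis=0)
    return np.vstack([rows, filler])


class TestCpm:
    def test_definition(self):
        t = make_counts(equal_lib_counts([[50] * 2]), ["s1", "s2"], ["A", "B"])
        assert cc.cpm(t).iloc[0, 0] == pytest.approx(50.0)

    def test_zero_count_is_zero(self):
        t = make_counts(equal_lib_counts([[0, 5]]), ["s1", "s2"], ["A", "B"])
        assert cc.cpm(t).iloc[0, 0] == 0.0

    def test_equal_counts_equal_libraries_equal_cpm(self):
        t = make_counts(equal_lib_counts([[7, 7, 7]]), ["a", "b", "c"], ["A", "A", "B"])
        vals = cc.cpm(t).iloc[0]
        assert vals.nunique() == 1

    def test_zero_library_errors(self):
        t = make_counts([[0, 1]], ["s1", "s2"], ["A", "B"])
        with pytest.raises(ValueError, match="library"):
            cc.cpm(t)


class TestFilterDetected:
    @pytest.mark.parametrize(
        "cpms,kept",
        [
            ([6, 6, 6, 4, 4, 4], False),  # 3 samples below 5 -> removed
            ([6, 6, 6, 6, 4, 4], True),  # only 2 below -> retained
            ([0, 0, 0, 0, 0, 0], False),  # all-zero gene removed
        ],
    )
    def test_five_cpm_in_three_samples_rule(self, cpms, kept):
        samples = [f"s{i}" for i in range(6)]
        t = make_counts(equal_lib_counts([cpms]), samples, ["A"] * 3 + ["B"] * 3)
        out = cc.filter_detected(t)
        assert ("gene0" in out.row_symbols) is kept

    def test_idempotent_and_order_preserving(self, rng):
        counts = rng.integers(0, 50, size=(40, 6))
        t = make_counts(counts * 1000, [f"s{i}" for i in range(6)], ["A"] * 3 + ["B"] * 3)
        once = cc.filter_detected(t)
        twice = cc.filter_detected(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        kept = [s for s in t.row_symbols if s in set(once.row_symbols)]
        assert once.row_symbols == kept


def edger_tmm_factors(counts: pd.DataFrame) -> np.ndarray:
    """Independent TMM oracle: edgeR::calcNormFactors through Rscript."""
    script = textwrap.dedent(
        """
        suppressMessages(library(edgeR))
        x <- as.matrix(read.csv("stdin", row.names = 1))
        cat(calcNormFactors(x, method = "TMM"), sep = "\\n")
        """
    )
    proc = subprocess.run(
        ["Rscript", "-e", script],
        input=counts.to_csv(),
        capture_output=True,
        text=True,
        check=True,
    )
    return np.array([float(v) for v in proc.stdout.split()])


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101)
        t = make_counts(np.column_stack([col] * 4), [f"s{i}" for i in range(4)], ["A", "A", "B", "B"])
        assert np.allclose(cc.tmm_factors(t), 1.0)

    def test_pure_depth_change_absorbed_by_library_size(self, rng):
        col = rng.integers(1, 500, size=200)
        t = make_counts(
            np.column_stack([col, 2 * col, col]), ["s1", "s2", "s3"], ["A", "A", "B"]
        )
        assert np.allclose(cc.tmm_factors(t), 1.0, atol=1e-12)

    def test_geometric_mean_one(self, rng):
        counts = rng.negative_binomial(5, 0.05, size=(300, 5))
        t = make_counts(counts, [f"s{i}" for i in range(5)], ["A"] * 2 + ["B"] * 3)
        f = cc.tmm_factors(t)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-9)

    def test_composition_bias_matches_edger_within_1e6(self, rng):
        # spike 5% of genes 8-fold in sample 0: its factor must deviate from 1
        # in the direction that removes the composition bias
        counts = rng.negative_binomial(10, 0.02, size=(400, 4)) + 1
        spiked = rng.choice(400, size=20, replace=False)
        counts[spiked, 0] *= 8
        t = make_counts(counts, [f"s{i}" for i in range(4)], ["A", "A", "B", "B"])
        ours = cc.tmm_factors(t).to_numpy()
        theirs = edger_tmm_factors(t.counts)
        assert np.allclose(ours, theirs, atol=1e-6)
        # the spiked library's unspiked majority is diluted; its factor falls
        # below 1 so their CPM is restored
        assert ours[0] < 1.0

    def test_invariant_to_relabeling_and_depth(self, rng):
        counts = rng.negative_binomial(8, 0.03, size=(250, 4)) + 1
        samples = [f"s{i}" for i in range(4)]
        t = make_counts(counts, samples, ["A", "A", "B", "B"])
        f = cc.tmm_factors(t)
        perm = [2, 0, 3, 1]
        t2 = make_counts(counts[:, perm], [samples[i] for i in perm], ["B", "A", "B", "A"])
        f2 = cc.tmm_factors(t2)
        assert np.allclose(f.to_numpy()[perm], f2.to_numpy(), rtol=1e-12)
        t3 = make_counts(counts * 3, samples, ["A", "A", "B", "B"])
        assert np.allclose(cc.tmm_factors(t3), f, rtol=1e-12)


def nb_counts(rng, n_genes, n_samples, mean, phi):
    if phi == 0:
        return rng.poisson(mean, size=(n_genes, n_samples))
    lam = rng.gamma(1.0 / phi, mean * phi, size=(n_genes, n_samples))
    return rng.poisson(lam)


class TestDispersionBcv:
    def test_poisson_counts_give_near_zero_bcv(self, rng):
        counts = nb_counts(rng, 2000, 6, 100.0, 0.0)
        t = make_counts(counts, [f"s{i}" for i in range(6)], ["A"] * 3 + ["B"] * 3)
        assert cc.dispersion_bcv(t).bcv < 0.05

    def test_recovers_bcv_034(self, rng):
        counts = nb_counts(rng, 2000, 6, 200.0, 0.34**2)
        t = make_counts(counts, [f"s{i}" for i in range(6)], ["A"] * 3 + ["B"] * 3)
        assert cc.dispersion_bcv(t).bcv == pytest.approx(0.34, abs=0.03)

    def test_equal_counts_everywhere_zero_dispersion(self):
        t = make_counts([[50] * 4], [f"s{i}" for i in range(4)], ["A", "A", "B", "B"])
        est = cc.dispersion_bcv(t)
        assert est.common_dispersion == 0.0
        assert est.bcv == 0.0

    def test_singleton_groups_rejected(self):
        t = make_counts([[5, 6]], ["s1", "s2"], ["A", "B"])
        with pytest.raises(ValueError, match="two samples"):
            cc.dispersion_bcv(t)


class TestMdsLeading:
    def test_two_groups_separate_on_dimension_one(self, rng):
        a = rng.integers(50, 500, size=100)
        b = a.copy()
        b[:30] = a[:30] * 4  # group difference
        counts = np.column_stack([a, a, b, b])
        t = make_counts(counts, ["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"])
        res = cc.mds_leading(t, top_genes=50)
        d1 = res.coordinates["dim1"]
        assert np.sign(d1["a1"]) == np.sign(d1["a2"]) != np.sign(d1["b1"])
        # identical columns within group coincide
        assert d1["a1"] == pytest.approx(d1["a2"], abs=1e-9)

    def test_identical_columns_zero_eigenvalues(self, rng):
        col = rng.integers(1, 100, size=50)
        t = make_counts(np.column_stack([col] * 4), [f"s{i}" for i in range(4)], ["A"] * 2 + ["B"] * 2)
        res = cc.mds_leading(t)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-9)

    def test_de_simulation_puts_most_variance_on_dim1(self):
        cfg = cc.SimConfig(n_genes=300, n_de=30, log2fc=2.0, reads_per_sample=300_000, seed=5)
        counts, _ = cc.simulate_counts(cfg, seed=5)
        t = cc.CountTable(counts=counts, groups={s: s[0] for s in counts.columns})
        res = cc.mds_leading(cc.filter_detected(t))
        assert res.variance_explained[0] == max(res.variance_explained)
        assert res.variance_explained.sum() <= 1.0 + 1e-9

    def test_fewer_than_three_samples_rejected(self):
        t = make_counts([[1, 2]], ["s1", "s2"], ["A", "B"])
        with pytest.raises(ValueError, match="three samples"):
            cc.mds_leading(t)


class TestGroupCorrelation:
    def test_identical_profiles_give_one(self, rng):
        col = rng.integers(1, 1000, size=80)
        t = make_counts(np.column_stack([col] * 4), [f"s{i}" for i in range(4)], ["A", "A", "B", "B"])
        assert cc.group_correlation(t) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        a = np.arange(1, 41) * 100
        b = a[::-1].copy()
        t = make_counts(np.column_stack([a, b]), ["s1", "s2"], ["A", "B"])
        assert cc.group_correlation(t) == pytest.approx(-1.0)

    def test_null_simulation_high_correlation(self):
        cfg = cc.SimConfig(n_genes=1000, n_de=0, bcv=0.34, reads_per_sample=1_000_000, seed=9)
        counts, _ = cc.simulate_counts(cfg, seed=9)
        t = cc.CountTable(counts=counts, groups={s: s[0] for s in counts.columns})
        assert cc.group_correlation(cc.filter_detected(t)) > 0.9

    def test_requires_two_groups(self):
        t = make_counts([[1, 2, 3]], ["s1", "s2", "s3"], ["A", "B", "C"])
        with pytest.raises(ValueError, match="2 groups"):
            cc.group_correlation(t)

    def test_sample_matrix_is_symmetric(self, rng):
        counts = rng.integers(0, 400, size=(60, 4))
        t = make_counts(counts, [f"s{i}" for i in range(4)], ["A", "A", "B", "B"])
        m = cc.sample_correlation_matrix(t)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
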