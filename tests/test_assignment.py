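"""Multi-map adjudication, counting, divergence summaries, exclusion proposal."""

import dataclasses

import numpy as np
import pytest

import crosscount as cc
from crosscount.aligner import AlignmentHit
from crosscount.assignment import FATES, count_reads

from conftest import make_reference, random_seq


def hit(read_id, transcript_id, score, strand="sense", subs=0):
    matches = max(score, 1)
    return AlignmentHit(
        read_id=read_id, transcript_id=transcript_id, strand=strand, score=score,
        matches=matches, substitutions=subs, insertions=0, deletions=0,
        read_interval=(0, matches + subs), target_interval=(0, matches + subs),
    )


class TestAssignRead:
    """toy_ref genes: GENE_A/B/C singletons, GENE_X excluded, KRT6A/KRT6B family 'Krt'."""

    def test_max_score_wins(self, toy_ref):
        a = cc.assign_read([hit("r", "GENE_A.T1", 95), hit("r", "GENE_B.T1", 80)], toy_ref)
        assert a.fate == "unique_gene"
        assert a.assigned_gene == "GENE_A" and a.assigned_symbol == "GeneA"
        assert a.best_score == 95

    def test_equal_scores_same_family_collapse(self, toy_ref):
        a = cc.assign_read([hit("r", "KRT6A.T1", 90), hit("r", "KRT6B.T1", 90)], toy_ref)
        assert a.fate == "family_collapsed" and a.assigned_symbol == "Krt"

    def test_equal_scores_unrelated_genes_ambiguous(self, toy_ref):
        a = cc.assign_read([hit("r", "GENE_A.T1", 90), hit("r", "GENE_C.T1", 90)], toy_ref)
        assert a.fate == "ambiguous" and a.assigned_symbol is None
        assert a.tied_genes == ("GENE_A", "GENE_C")

    def test_exclusion_releases_read_to_other_gene(self, toy_ref):
        a = cc.assign_read([hit("r", "GENE_X.T1", 90), hit("r", "GENE_B.T1", 90)], toy_ref)
        assert a.fate == "unique_gene" and a.assigned_gene == "GENE_B"

    def test_excluded_only(self, toy_ref):
        a = cc.assign_read([hit("r", "GENE_X.T1", 90)], toy_ref)
        assert a.fate == "excluded_only" and a.assigned_symbol is None

    def test_antisense_dropped_before_adjudication(self, toy_ref):
        a = cc.assign_read(
            [hit("r", "GENE_A.T1", 99, strand="antisense"), hit("r", "GENE_B.T1", 60)],
            toy_ref,
        )
        assert a.fate == "unique_gene" and a.assigned_gene == "GENE_B"

    def test_wrong_strand_only_and_unaligned(self, toy_ref):
        a = cc.assign_read([hit("r", "GENE_A.T1", 99, strand="antisense")], toy_ref)
        assert a.fate == "wrong_strand_only"
        assert cc.assign_read([], toy_ref).fate == "unaligned"

    def test_within_gene_transcript_tie_is_unique(self, rng):
        seq = random_seq(rng, 200)
        ref = make_reference({"G1": ("S1", [seq, seq])})
        a = cc.assign_read([hit("r", "G1.T1", 80), hit("r", "G1.T2", 80)], ref)
        assert a.fate == "unique_gene" and a.assigned_gene == "G1"

    def test_sdi_comes_from_top_hit(self, toy_ref):
        hits = [hit("r", "GENE_A.T1", 95, subs=2), hit("r", "GENE_B.T1", 60, subs=9)]
        a = cc.assign_read(hits, toy_ref)
        assert a.sdi == pytest.approx(2 / 97)

    def test_mixed_read_ids_rejected(self, toy_ref):
        with pytest.raises(ValueError, match="multiple reads"):
            cc.assign_read([hit("r1", "GENE_A.T1", 90), hit("r2", "GENE_B.T1", 90)], toy_ref)


class TestCountReads:
    def test_column_and_tally(self, toy_ref):
        assignments = (
            [cc.assign_read([hit(f"a{i}", "GENE_A.T1", 90)], toy_ref) for i in range(7)]
            + [cc.assign_read([hit(f"k{i}", "KRT6A.T1", 80), hit(f"k{i}", "KRT6B.T1", 80)], toy_ref)
               for i in range(2)]
            + [cc.assign_read([hit("amb", "GENE_A.T1", 70), hit("amb", "GENE_C.T1", 70)], toy_ref)]
        )
        column, tally = count_reads(assignments, "s1")
        assert column == {"GeneA": 7, "Krt": 2}
        assert sum(column.values()) == tally["unique_gene"] + tally["family_collapsed"] == 9
        assert tally["ambiguous"] == 1

    def test_all_unaligned_gives_empty_column(self, toy_ref):
        column, tally = count_reads([cc.assign_read([], toy_ref) for _ in range(5)], "s1")
        assert column == {} and tally["unaligned"] == 5

    def test_conservation_over_fates(self, toy_ref, rng):
        # random mixture of all fates must tally back to the total
        assignments = []
        for i in range(60):
            kind = int(rng.integers(0, 5))
            if kind == 0:
                assignments.append(cc.assign_read([], toy_ref))
            elif kind == 1:
                assignments.append(
                    cc.assign_read([hit(f"r{i}", "GENE_A.T1", 80, strand="antisense")], toy_ref)
                )
            elif kind == 2:
                assignments.append(cc.assign_read([hit(f"r{i}", "GENE_X.T1", 80)], toy_ref))
            elif kind == 3:
                assignments.append(
                    cc.assign_read([hit(f"r{i}", "GENE_A.T1", 80), hit(f"r{i}", "GENE_C.T1", 80)], toy_ref)
                )
            else:
                assignments.append(cc.assign_read([hit(f"r{i}", "GENE_B.T1", 80)], toy_ref))
        column, tally = count_reads(assignments, "s1")
        assert sum(tally.values()) == 60
        assert sum(tally[f] for f in FATES) == 60
        assert sum(column.values()) == tally["unique_gene"] + tally["family_collapsed"]

    def test_exclusion_never_decreases_other_counts(self, toy_ref):
        hit_sets = [
            [hit("r1", "GENE_A.T1", 90), hit("r1", "GENE_B.T1", 90)],
            [hit("r2", "GENE_B.T1", 85)],
            [hit("r3", "GENE_A.T1", 70)],
        ]
        before, _ = count_reads([cc.assign_read(h, toy_ref) for h in hit_sets], "s")
        more_excluded = dataclasses.replace(
            toy_ref, excluded=toy_ref.excluded | {"GENE_A"}
        )
        after, _ = count_reads([cc.assign_read(h, more_excluded) for h in hit_sets], "s")
        for symbol, n in before.items():
            if symbol != "GeneA":
                assert after[symbol] >= n
        assert after["GeneB"] == 2  # r1 released to GENE_B


class TestDivergenceProfile:
    def _assigned(self, toy_ref, sdis):
        out = []
        for i, s in enumerate(sdis):
            n_sub = int(round(s * 100))
            out.append(
                cc.assign_read(
                    [hit(f"r{i}", "GENE_A.T1", 100 - 3 * n_sub, subs=n_sub)], toy_ref
                )
            )
        return out

    def test_zero_divergence(self, toy_ref):
        d = cc.divergence_profile(self._assigned(toy_ref, [0.0] * 4), "s")
        assert d.mean_sdi == 0.0 and d.sd_sdi == 0.0

    def test_mean_of_two(self, toy_ref):
        # subs counted over (matches + subs) columns: 5/100 and 9/100
        a = self._assigned(toy_ref, [0.0, 0.0])
        h1 = [hit("x1", "GENE_A.T1", 85, subs=5)]
        h2 = [hit("x2", "GENE_A.T1", 73, subs=9)]
        h1[0] = dataclasses.replace(h1[0], matches=95)
        h2[0] = dataclasses.replace(h2[0], matches=91)
        a = [cc.assign_read(h1, toy_ref), cc.assign_read(h2, toy_ref)]
        assert cc.divergence_profile(a, "s").mean_sdi == pytest.approx(0.07)

    def test_histogram_density_sums_to_one(self, toy_ref, rng):
        a = self._assigned(toy_ref, rng.uniform(0, 0.1, size=200))
        d = cc.divergence_profile(a, "s")
        assert np.isclose(sum(d.densities), 1.0)
        assert len(d.densities) == 50

    def test_no_counted_reads_errors(self, toy_ref):
        with pytest.raises(ValueError, match="no counted reads"):
            cc.divergence_profile([cc.assign_read([], toy_ref)], "s")


class TestProposeExclusions:
    def test_duplicate_pair_proposed(self, rng):
        seq = random_seq(rng, 300)
        other = random_seq(rng, 300)
        ref = make_reference({"D1": ("d1", [seq]), "D2": ("d2", [seq]), "U1": ("u1", [other])})
        assignments = [
            cc.assign_read([hit(f"r{i}", "D1.T1", 90), hit(f"r{i}", "D2.T1", 90)], ref)
            for i in range(20)
        ] + [cc.assign_read([hit(f"u{i}", "U1.T1", 90)], ref) for i in range(20)]
        excl, table = cc.propose_exclusions(assignments, ref, min_fraction=0.5, min_reads=10)
        assert excl.gene_ids == {"D1", "D2"}

    def test_no_ties_no_proposal(self, rng):
        ref = make_reference({"G1": ("s1", [random_seq(rng, 300)])})
        assignments = [cc.assign_read([hit(f"r{i}", "G1.T1", 90)], ref) for i in range(30)]
        excl, table = cc.propose_exclusions(assignments, ref)
        assert excl.gene_ids == frozenset() and table.empty

    def test_simulated_duplicates_recovered_exactly(self):
        cfg = cc.SimConfig(n_genes=30, n_families=0, n_duplicate_pairs=3,
                           reads_per_sample=3000, seq_error=0.0, seed=21)
        ref, truth = cc.simulate_reference(cfg)
        counts, _ = cc.simulate_counts(cfg, gene_ids=sorted(ref.gene_ids), seed=22)
        reads, _ = cc.simulate_reads(ref, counts["A1"], cfg, "A1", seed=23)
        from crosscount.pipeline import quantify_samples

        q = quantify_samples({"A1": reads}, ref, groups={"A1": "A"})
        excl, _ = cc.propose_exclusions(q["assignments"]["A1"], ref, min_fraction=0.9, min_reads=5)
        assert excl.gene_ids == frozenset(truth.duplicate_genes)

    def test_requires_unexcluded_reference(self, toy_ref):
        with pytest.raises(ValueError, match="un-excluded"):
            cc.propose_exclusions([], toy_ref)


def test_counts_equal_simulated_truth_without_divergence():
    """No paralogs, zero divergence, zero error: pipeline counts == simulated counts."""
    cfg = cc.SimConfig(n_genes=25, n_families=0, reads_per_sample=700, seq_error=0.0, seed=61)
    ref, _ = cc.simulate_reference(cfg)
    counts, _ = cc.simulate_counts(cfg, gene_ids=sorted(ref.gene_ids), seed=62)
    reads, _ = cc.simulate_reads(ref, counts["A1"], cfg, "A1", seed=63)
    from crosscount.pipeline import quantify_samples

    q = quantify_samples({"A1": reads}, ref, groups={"A1": "A"})
    got = q["gene_counts"].counts["A1"]
    truth = counts["A1"].rename(index=dict(ref.symbol_map))
    truth = truth[truth > 0].sort_index()
    assert got.sort_index().astype(int).equals(truth.astype(int))
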