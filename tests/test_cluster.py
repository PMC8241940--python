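"""SAG grouping, reference admission, concordance, novelty, intervals."""

import numpy as np
import pytest

from sagscreen.cluster import (
    NoveltyThresholds,
    PairwiseMatrix,
    ReferenceMeta,
    concordance_check,
    group_sags,
    naive_fragment_identity,
    novelty_rank,
    reference_filter,
    unique_region_summary,
)
from sagscreen.fixtures import cag_members, cag_pairwise
from sagscreen.simulate import simulate_sag_replicates
from sagscreen.taxonomy import TaxonPath

P = TaxonPath.parse


class TestPairwiseMatrix:
    def test_symmetry_enforced(self):
        m = PairwiseMatrix("ANI")
        m.set("a", "b", 99.0)
        assert m.get("b", "a") == 99.0
        with pytest.raises(ValueError, match="asymmetric"):
            m.set("b", "a", 88.0)

    def test_diagonal_is_100(self):
        m = PairwiseMatrix("ANI")
        assert m.get("a", "a") == 100.0
        with pytest.raises(ValueError, match="diagonal"):
            m.set("a", "a", 97.0)


class TestGroupSags:
    def test_table_memberships_give_15_entities(self):
        ids, id16s, ani = cag_pairwise()
        result = group_sags(ids, id16s, ani)
        assert result.n_entities == 15
        assert sorted(len(c) for c in result.cag_components) == [2, 3, 3, 8]
        assert len(result.singletons) == 11
        members = cag_members()
        component_sets = {frozenset(m) for m in members.values()}
        assert component_sets == set(result.cag_components)

    def test_no_qualifying_pairs_all_singletons(self):
        ani = PairwiseMatrix("ANI", {("a", "b"): 90.0})
        result = group_sags(["a", "b", "c"], ani=ani)
        assert result.n_entities == 3
        assert result.cag_components == ()

    def test_transitive_closure_across_criteria(self):
        ani = PairwiseMatrix("ANI", {("a", "b"): 99.0, ("a", "c"): 80.0})
        id16s = PairwiseMatrix("ID16S", {("b", "c"): 100.0, ("a", "c"): 90.0})
        result = group_sags(["a", "b", "c"], id16s=id16s, ani=ani)
        assert result.components == (frozenset({"a", "b", "c"}),)
        assert result.edges[("a", "b")] == ("ANI",)
        assert result.edges[("b", "c")] == ("16S",)

    def test_ani_threshold_is_strict(self):
        ani = PairwiseMatrix("ANI", {("a", "b"): 98.4})
        assert group_sags(["a", "b"], ani=ani).n_entities == 2

    def test_raising_thresholds_only_refines(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(12)]
        ani = PairwiseMatrix("ANI")
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ani.set(a, b, float(rng.uniform(90, 100)))
        coarse = group_sags(ids, ani=ani, tani=95.0).components
        fine = group_sags(ids, ani=ani, tani=98.4).components
        for comp in fine:
            assert any(comp <= other for other in coarse)

    def test_order_invariance(self):
        ids, id16s, ani = cag_pairwise()
        forward = group_sags(ids, id16s, ani).components
        backward = group_sags(list(reversed(ids)), id16s, ani).components
        assert set(forward) == set(backward)


class TestReferenceFilter:
    @pytest.mark.parametrize(
        "n50, comp, cont, expected",
        [
            (40_000, 75.0, 3.0, True),
            (35_000, 90.0, 1.0, False),   # N50 not > 35 kb
            (100_000, 70.0, 4.9, False),  # completeness not > 70
            (100_000, 80.0, 5.0, False),  # contamination not < 5
        ],
    )
    def test_strict_boundaries(self, n50, comp, cont, expected):
        assert reference_filter(ReferenceMeta("g", n50, comp, cont)) is expected


class TestConcordance:
    def test_three_identical_paths_total_agreement(self):
        path = P("Bacteria;Patescibacteria;Saccharibacteria")
        report = concordance_check({"g": {"16S": path, "gtdb": path, "mlsa": path}})
        assert report.per_genome["g"] == (3, 3, True)
        assert report.n_total_agreement == 1

    def test_two_method_genomes_counted_separately(self):
        path = P("Bacteria;Patescibacteria")
        report = concordance_check({"g": {"16S": path, "gtdb": path}})
        assert report.n_partial_methods == 1
        assert report.n_full_method_agreement == 0
        assert report.n_total_agreement == 1

    def test_divergence_at_genus_agrees_at_family(self):
        a = P("Bacteria;Patescibacteria;Saccharibacteria;O;F;GenusA")
        b = P("Bacteria;Patescibacteria;Saccharibacteria;O;F;GenusB")
        report = concordance_check({"g": {"m1": a, "m2": b}})
        n_methods, depth, total = report.per_genome["g"]
        assert depth == 5  # deepest agreed rank = family
        assert not total

    def test_adding_a_method_never_deepens_agreement(self):
        a = P("Bacteria;Patescibacteria;Saccharibacteria")
        b = P("Bacteria;Patescibacteria")
        with_two = concordance_check({"g": {"m1": a, "m2": a}})
        with_three = concordance_check({"g": {"m1": a, "m2": a, "m3": b}})
        assert with_three.per_genome["g"][1] <= with_two.per_genome["g"][1]


class TestNoveltyRank:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(ani=96.0), "same_species"),
            (dict(ani=91.0, aai=70.0), "novel_species"),
            (dict(ani=80.0, aai=50.0), "novel_genus"),
            (dict(ani=75.0, aai=40.0), "novel_family"),
            (dict(id16s=92.0), "novel_family"),
            (dict(ani=99.0, insufficient_data=True), "indeterminate"),
        ],
    )
    def test_rule_ladder(self, kwargs, expected):
        assert novelty_rank(**kwargs) == expected

    def test_no_metric_is_an_error(self):
        with pytest.raises(ValueError):
            novelty_rank()


class TestUniqueRegions:
    def test_single_gap(self):
        s = unique_region_summary(1000, [(100, 1000)], min_region_bp=0)
        assert (s.unshared_bp, s.unshared_fraction, s.n_regions) == (100, 0.1, 1)

    def test_no_alignment_whole_genome_unshared(self):
        s = unique_region_summary(1000, [], min_region_bp=0)
        assert (s.unshared_bp, s.n_regions) == (1000, 1)

    def test_overlapping_intervals_merged(self):
        s = unique_region_summary(1000, [(0, 500), (400, 900)], min_region_bp=0)
        assert (s.unshared_bp, s.n_regions) == (100, 1)

    def test_minimum_region_filter(self):
        # gaps of 100 and 500 bp; the 100 bp gap falls below the 200 bp floor
        s = unique_region_summary(2000, [(100, 200), (700, 2000)])
        assert (s.unshared_bp, s.n_regions) == (500, 1)
        s = unique_region_summary(2000, [(0, 200), (300, 2000)])
        assert (s.unshared_bp, s.n_regions) == (0, 0)

    def test_complement_identity_without_filter(self):
        rng = np.random.default_rng(9)
        length = 100_000
        intervals = []
        for _ in range(50):
            start = int(rng.integers(0, length - 10))
            end = int(rng.integers(start + 1, min(length, start + 5000) + 1))
            intervals.append((start, min(end, length)))
        s = unique_region_summary(length, intervals, min_region_bp=0)
        merged = unique_region_summary(length, intervals, min_region_bp=0)
        aligned_bp = length - s.unshared_bp
        # recompute merged aligned length independently
        events = sorted(intervals)
        total, cursor = 0, -1
        for a, b in events:
            if a > cursor:
                total += b - a
                cursor = b
            elif b > cursor:
                total += b - cursor
                cursor = b
        assert aligned_bp == total

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            unique_region_summary(1000, [(500, 1500)])


class TestNaiveFragmentIdentity:
    @staticmethod
    def random_seq(rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_identical_sequences_score_100(self):
        rng = np.random.default_rng(21)
        seq = self.random_seq(rng, 5000)
        assert naive_fragment_identity(seq, seq) == pytest.approx(100.0)

    def test_five_percent_substitutions_score_near_95(self):
        rng = np.random.default_rng(22)
        seq = list(self.random_seq(rng, 10_200))
        mutated = seq.copy()
        for pos in rng.choice(len(seq), size=int(0.05 * len(seq)), replace=False):
            alternatives = [b for b in "ACGT" if b != mutated[pos]]
            mutated[pos] = alternatives[rng.integers(3)]
        identity = naive_fragment_identity("".join(seq), "".join(mutated))
        assert identity == pytest.approx(95.0, abs=1.0)

    def test_unrelated_sequences_score_low(self):
        rng = np.random.default_rng(23)
        a = self.random_seq(rng, 5100)
        b = self.random_seq(rng, 5100)
        assert naive_fragment_identity(a, b) < 80.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            naive_fragment_identity("ACGT" * 10, "ACGT" * 500)


class TestSimulatedReplicates:
    def test_recovers_planted_partition(self):
        ids, id16s, ani, truth = simulate_sag_replicates([2, 3, 3, 8], n_singletons=11, seed=3)
        result = group_sags(ids, id16s, ani)
        assert set(result.components) == set(truth)
        assert result.n_entities == 15

    def test_single_group(self):
        ids, id16s, ani, truth = simulate_sag_replicates([5], seed=1)
        assert group_sags(ids, id16s, ani).components == (frozenset(ids),)

    def test_all_singletons(self):
        ids, id16s, ani, truth = simulate_sag_replicates([], n_singletons=6, seed=1)
        assert group_sags(ids, id16s, ani).n_entities == 6

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="ambiguous construction"):
            simulate_sag_replicates([2, 2], within_ani=(90.0, 100.0), between_ani=(70.0, 95.0))
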