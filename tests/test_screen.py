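"""Hierarchical contig classification and contamination screening."""

import numpy as np
import pytest

from sagscreen.screen import (
    ContigRecord,
    MarkerHit,
    classify_contig,
    classify_contigs,
    dominant_taxon,
    filter_assembly,
    flag_contaminants,
    screen_assembly,
)
from sagscreen.simulate import CommunitySpec, ContaminationSpec, TaxonSpec, inject_contamination, simulate_community
from sagscreen.taxonomy import RankConfig, TaxonPath

P = TaxonPath.parse
PATES = P("Bacteria;Patescibacteria;Saccharibacteria")
BACTE = P("Bacteria;Bacteroidetes;Bacteroidia")


def contig(cid, length=10_000, coverage=10.0, hits=()):
    c = ContigRecord(contig_id=cid, genome_id="G", length_bp=length, mean_coverage=coverage)
    for i, (cls, taxon, ident) in enumerate(hits):
        c.hits.append(MarkerHit(f"{cid}_g{i}", cid, cls, taxon, ident))
    return c


class TestClassifyContig:
    def test_rrna_outranks_many_protein_hits(self):
        c = contig("c1", hits=[("RRNA", PATES, 98.0)] + [("PROT", BACTE, 60.0)] * 5)
        result = classify_contig(c)
        assert result.selected_class == "RRNA"
        assert result.lca_taxon == PATES
        assert result.mean_identity == 98.0
        assert result.n_hits == 1

    def test_hitless_contig_is_unclassified(self):
        result = classify_contig(contig("c1"))
        assert result.selected_class == "NONE"
        assert result.lca_taxon.is_root
        assert result.mean_identity == 0.0

    def test_scg_lca_and_mean_identity(self):
        hits = [
            ("SCG", P("Bacteria;Patescibacteria;Saccharibacteria"), 50.0),
            ("SCG", P("Bacteria;Patescibacteria;Gracilibacteria"), 60.0),
            ("SCG", P("Bacteria;Patescibacteria;Saccharibacteria;Ord1"), 70.0),
        ]
        result = classify_contig(contig("c1", hits=hits))
        assert result.selected_class == "SCG"
        assert result.lca_taxon == P("Bacteria;Patescibacteria")
        assert result.mean_identity == pytest.approx(60.0)

    def test_precedence_monotonicity(self):
        """Adding PROT hits never changes an RRNA/SCG classification."""
        base = contig("c1", hits=[("SCG", PATES, 80.0)])
        before = classify_contig(base)
        base.hits.append(MarkerHit("g9", "c1", "PROT", BACTE, 99.0))
        after = classify_contig(base)
        assert (after.selected_class, after.lca_taxon, after.mean_identity) == (
            before.selected_class,
            before.lca_taxon,
            before.mean_identity,
        )


class TestDominantTaxon:
    def test_majority_by_length(self, cfg):
        contigs = [
            contig(f"c{i}", length=100_000, hits=[("SCG", PATES, 80.0)]) for i in range(9)
        ] + [contig("c9", length=10_000, hits=[("SCG", BACTE, 80.0)])]
        result = dominant_taxon(classify_contigs(contigs), contigs, cfg)
        assert result == PATES

    def test_length_tie_broken_lexicographically(self, cfg):
        contigs = [
            contig("c0", length=50_000, hits=[("SCG", P("Bacteria;Beta"), 80.0)]),
            contig("c1", length=50_000, hits=[("SCG", P("Bacteria;Alpha"), 80.0)]),
        ]
        result = dominant_taxon(classify_contigs(contigs), contigs, cfg)
        assert result == P("Bacteria;Alpha")

    def test_result_truncated_at_deepest_unanimous_rank(self, cfg):
        contigs = [
            contig("c0", hits=[("SCG", P("Bacteria;Patescibacteria;Saccharibacteria"), 80.0)]),
            contig("c1", hits=[("SCG", P("Bacteria;Patescibacteria;Gracilibacteria"), 80.0)]),
        ]
        result = dominant_taxon(classify_contigs(contigs), contigs, cfg)
        assert result == P("Bacteria;Patescibacteria")

    def test_all_unclassified_is_an_error(self, cfg):
        contigs = [contig("c0"), contig("c1")]
        with pytest.raises(ValueError, match="no dominant taxon"):
            dominant_taxon(classify_contigs(contigs), contigs, cfg)


class TestFlagContaminants:
    def make(self, identity):
        contigs = [
            contig("host", length=900_000, hits=[("SCG", PATES, 90.0)]),
            contig("cont", length=10_000, hits=[("PROT", BACTE, identity)]),
        ]
        return contigs, classify_contigs(contigs)

    def test_contradicting_contig_above_threshold_is_flagged(self, cfg):
        contigs, cls = self.make(55.0)
        flagged = flag_contaminants(cls, P("Bacteria;Patescibacteria"), 40.0, cfg)
        assert [f.contig_id for f in flagged] == ["cont"]
        assert all(f.flagged for f in flagged)

    def test_threshold_is_strict(self, cfg):
        contigs, cls = self.make(40.0)
        assert flag_contaminants(cls, P("Bacteria;Patescibacteria"), 40.0, cfg) == []

    def test_indeterminate_lineage_is_never_flagged(self, cfg):
        contigs = [contig("c0", hits=[("PROT", P("Bacteria"), 90.0)])]
        cls = classify_contigs(contigs)
        assert flag_contaminants(cls, P("Bacteria;Patescibacteria"), 40.0, cfg) == []

    def test_monotone_in_identity_threshold(self, cfg):
        rng = np.random.default_rng(3)
        contigs = [
            contig(f"c{i}", hits=[("PROT", BACTE, float(rng.uniform(20, 90)))])
            for i in range(30)
        ] + [contig("host", length=10**6, hits=[("SCG", PATES, 90.0)])]
        cls = classify_contigs(contigs)
        dom = P("Bacteria;Patescibacteria")
        previous = None
        for threshold in (20.0, 40.0, 60.0, 80.0):
            flagged = {f.contig_id for f in flag_contaminants(cls, dom, threshold, cfg)}
            if previous is not None:
                assert flagged <= previous
            previous = flagged


class TestFilterAssembly:
    def test_counts_and_fractions(self, cfg):
        contigs = [
            contig(f"c{i}", hits=[("SCG", PATES if i >= 10 else BACTE, 80.0)])
            for i in range(100)
        ]
        cls = classify_contigs(contigs)
        flags = flag_contaminants(cls, P("Bacteria;Patescibacteria"), 40.0, cfg)
        retained, report = filter_assembly(contigs, flags)
        assert len(retained) == 90
        assert report.fraction_removed_by_count == pytest.approx(0.10)

    def test_no_flags_is_identity(self):
        contigs = [contig("c0"), contig("c1")]
        retained, report = filter_assembly(contigs, [])
        assert retained == contigs
        assert report.fraction_removed_by_count == 0.0

    def test_unknown_contig_in_flags_is_an_error(self, cfg):
        contigs = [contig("host", hits=[("SCG", PATES, 90.0)])]
        cls = classify_contigs([contig("ghost", hits=[("PROT", BACTE, 90.0)])])
        with pytest.raises(ValueError, match="unknown contig"):
            filter_assembly(contigs, cls)

    def test_dominant_lineage_survives_filtering(self, cfg):
        """Screening never removes supporters; the dominant taxon is stable."""
        host = P("Bacteria;Patescibacteria;Saccharibacteria")
        spec = CommunitySpec(
            taxa=(TaxonSpec(host, 1.0, genome_size_bp=2_000_000),), seed=5
        )
        contigs, _ = simulate_community(spec)
        contigs, _ = inject_contamination(
            contigs, ContaminationSpec(rate=0.1, source_taxon=BACTE, seed=5)
        )
        retained, flags, report = screen_assembly(contigs)
        dom_before = dominant_taxon(classify_contigs(contigs), contigs)
        dom_after = dominant_taxon(classify_contigs(retained), retained)
        assert dom_before == dom_after == host
        flagged_ids = {f.contig_id for f in flags}
        supporters = {
            c.contig_id
            for c, cl in zip(contigs, classify_contigs(contigs))
            if cl.lca_taxon and P("Bacteria;Patescibacteria").is_prefix_of(cl.lca_taxon)
        }
        assert not flagged_ids & supporters


class TestSyntheticRecovery:
    @pytest.mark.parametrize("rate", [0.05, 0.1, 0.2])
    def test_flagged_fraction_recovers_planted_rate(self, rate):
        """Mean flagged fraction within 3 points of the planted rate (20 reps)."""
        host = P("Bacteria;Patescibacteria;Saccharibacteria")
        fractions = []
        for seed in range(20):
            spec = CommunitySpec(
                taxa=(TaxonSpec(host, 1.0, genome_size_bp=5_000_000),), seed=seed
            )
            contigs, _ = simulate_community(spec)
            assert len(contigs) >= 200
            contigs, truth = inject_contamination(
                contigs,
                ContaminationSpec(
                    rate=rate, source_taxon=BACTE, identity_range=(50.0, 70.0), seed=seed
                ),
            )
            _, flags, report = screen_assembly(contigs)
            fractions.append(report.fraction_removed_by_count)
            # unambiguous construction: perfect recall and precision
            flagged = {f.contig_id for f in flags}
            planted = set(truth.loc[truth.is_contaminant, "contig_id"])
            assert flagged == planted
        assert abs(np.mean(fractions) - rate) < 0.03
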