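import numpy as np
import pytest
from scipy import stats as sps

from sgskit.followup import (
    GeneModel,
    VariantAnnotation,
    enrichment_test,
    familial_variant_screen,
    popfreq_association,
    select_assoc_variants,
    target_genes,
)
from sgskit.genoqc import GenotypeMatrix
from sgskit.multi_family import FamilyEvidence, RegionEvidence
from sgskit.stats import bonferroni_threshold

from oracles import fisher_enumeration


def region(chrom="chr1", start=1000, end=5000, subset=("a", "b", "c")):
    return RegionEvidence(
        chrom=chrom, start_bp=start, end_bp=end,
        families=[FamilyEvidence("fam1", 1e-6, len(subset), frozenset(subset),
                                 "significant")],
    )


def gene(gid, chrom="chr1", coding=(), regulatory=(), blacklisted=False):
    return GeneModel(gid, chrom, list(coding), list(regulatory), blacklisted)


def variant(vid="v1", bp=2000, gene_id="G1", consequence="missense",
            sift="damaging", polyphen="benign", ref_maf=0.05, **kw):
    defaults = dict(ref_minor_chroms=100, ref_total_chroms=60_000,
                    case_minor_chroms=10, case_total_chroms=2600)
    defaults.update(kw)
    return VariantAnnotation(vid, "chr1", bp, gene_id, consequence, sift,
                             polyphen, ref_maf, **defaults)


class TestTargetGenes:
    def test_gene_inside_region_included(self):
        assert target_genes([region()], [gene("G1", coding=[(2000, 3000)])]) == ["G1"]

    def test_regulatory_only_overlap_included(self):
        g = gene("G2", coding=[(9000, 9500)], regulatory=[(4500, 5200)])
        assert target_genes([region()], [g]) == ["G2"]

    def test_blacklisted_excluded_after_intersection(self):
        g = gene("OR_cluster", coding=[(2000, 3000)], blacklisted=True)
        assert target_genes([region()], [g]) == []

    def test_wrong_chromosome_excluded(self):
        g = gene("G3", chrom="chr2", coding=[(2000, 3000)])
        assert target_genes([region()], [g]) == []

    def test_idempotent_and_order_invariant(self):
        genes = [gene("B", coding=[(1500, 1600)]), gene("A", coding=[(2000, 2100)])]
        out = target_genes([region()], genes)
        assert out == ["A", "B"]
        assert target_genes([region()], genes[::-1]) == out


class TestEnrichment:
    def test_published_arithmetic(self):
        expected, prop, z, p = enrichment_test(207, 18, 19_000, 755)
        assert round(100 * prop, 1) == 8.7
        assert round(expected) == 8
        assert 100 * 755 / 19_000 == pytest.approx(4.0, abs=0.03)
        assert z > 0 and p < 0.05

    def test_null_case_z_near_zero(self):
        # hit rate exactly at background
        expected, prop, z, p = enrichment_test(100, 4, 19_000, 760)
        assert abs(z) < 0.15
        assert 0.4 < p < 0.6

    def test_z_sign_follows_direction(self):
        *_, z_hi, _ = enrichment_test(100, 20, 19_000, 760)
        *_, z_lo, _ = enrichment_test(100, 0, 19_000, 760)
        assert z_hi > 0 > z_lo

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(10, 20, 19_000, 755)


class TestFamilialScreen:
    def _gm(self, genos):
        return GenotypeMatrix(list(genos), np.array(list(genos.values()), dtype=np.int8))

    def test_planted_explanatory_variant_reported(self):
        marker_ids = ["v_in", "v_out"]
        gm = self._gm({"a": [1, 0], "b": [2, 0], "c": [1, 0]})
        anns = [variant("v_in", bp=2000), variant("v_out", bp=9000)]
        rep = familial_variant_screen([region()], anns, gm, marker_ids)
        assert rep[0] == ["v_in"]

    def test_variant_outside_region_never_reported(self):
        marker_ids = ["v_out"]
        gm = self._gm({"a": [1], "b": [1], "c": [1]})
        rep = familial_variant_screen(
            [region()], [variant("v_out", bp=9000)], gm, marker_ids
        )
        assert rep[0] == []

    def test_maf_gate_excludes_common(self):
        marker_ids = ["v_common"]
        gm = self._gm({"a": [1], "b": [1], "c": [1]})
        rep = familial_variant_screen(
            [region()], [variant("v_common", bp=2000, ref_maf=0.15)],
            gm, marker_ids,
        )
        assert rep[0] == []

    def test_synonymous_excluded(self):
        marker_ids = ["v_syn"]
        gm = self._gm({"a": [1], "b": [1], "c": [1]})
        rep = familial_variant_screen(
            [region()], [variant("v_syn", bp=2000, consequence="synonymous")],
            gm, marker_ids,
        )
        assert rep[0] == []

    def test_non_carrier_case_breaks_explanation(self):
        marker_ids = ["v"]
        gm = self._gm({"a": [1], "b": [0], "c": [1]})
        rep = familial_variant_screen([region()], [variant("v", bp=2000)],
                                      gm, marker_ids)
        assert rep[0] == []


class TestSelection:
    GENES = [gene("G1", coding=[(1500, 4500)])]

    def test_selection_criteria(self):
        regions = [region()]
        selected = select_assoc_variants(
            [variant("keep", bp=2000, sift="damaging", polyphen="benign")],
            regions, self.GENES,
        )
        assert [v.variant_id for v in selected] == ["keep"]

    @pytest.mark.parametrize("kw", [
        dict(consequence="synonymous"),
        dict(sift="benign", polyphen="benign"),
        dict(ref_maf=0.25),
        dict(bp=4800),  # outside coding interval
    ])
    def test_rejections(self, kw):
        v = variant("rej", **{**dict(bp=2000), **kw})
        assert select_assoc_variants([v], [region()], self.GENES) == []


class TestPopfreqAssociation:
    def test_bonferroni_threshold_published(self):
        assert bonferroni_threshold(0.05, 352) == pytest.approx(1.42e-4, rel=5e-3)

    def test_rare_variant_uses_fisher_and_flags(self):
        # chromosome counts of the SP110 missense variant
        v = variant("rs181058279", ref_maf=0.00006, ref_minor_chroms=4,
                    ref_total_chroms=66_714, case_minor_chroms=5,
                    case_total_chroms=2624)
        res = popfreq_association(v, alpha=0.05, m=352)
        assert res.test == "fisher_exact"
        assert res.p_value < 1.42e-4
        assert res.significant

    def test_common_variant_uses_chisq(self):
        # chromosome counts of the AGBL2 missense variant
        v = variant("rs76215382", ref_maf=0.0148, ref_minor_chroms=986,
                    ref_total_chroms=66_668, case_minor_chroms=65,
                    case_total_chroms=2622)
        res = popfreq_association(v, alpha=0.05, m=352)
        assert res.test == "chi_square"
        assert res.significant

    def test_equal_frequencies_not_significant(self):
        v = variant("null", ref_minor_chroms=600, ref_total_chroms=60_000,
                    case_minor_chroms=26, case_total_chroms=2600)
        res = popfreq_association(v, alpha=0.05, m=352)
        assert res.p_value > 0.5
        assert not res.significant

    def test_fisher_branch_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 250))
            n2 = int(rng.integers(2, 250))
            a = int(rng.integers(0, min(n1, 10)))
            c = int(rng.integers(0, min(n2, 10)))
            v = variant("t", ref_minor_chroms=c, ref_total_chroms=n2,
                        case_minor_chroms=a, case_total_chroms=n1)
            res = popfreq_association(v, m=1)
            assert res.test == "fisher_exact"
            expect = fisher_enumeration(a, n1 - a, c, n2 - c)
            assert res.p_value == pytest.approx(expect, rel=1e-7, abs=1e-12)

    def test_chisq_branch_matches_pearson_closed_form(self):
        v = variant("t", ref_minor_chroms=300, ref_total_chroms=10_000,
                    case_minor_chroms=60, case_total_chroms=1000)
        res = popfreq_association(v, m=1)
        assert res.test == "chi_square"
        table = np.array([[60, 940], [300, 9700]], dtype=float)
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - exp) ** 2 / exp).sum()
        assert res.p_value == pytest.approx(float(sps.chi2.sf(chi2, 1)), rel=1e-10)

    def test_exclusion_of_sharing_cases(self):
        gm = GenotypeMatrix(["a", "b"], np.array([[2], [1]], dtype=np.int8))
        v = variant("v", ref_minor_chroms=10, ref_total_chroms=10_000,
                    case_minor_chroms=8, case_total_chroms=100)
        res = popfreq_association(v, m=1, exclude_cases={"a", "b"}, gm=gm,
                                  marker_ids=["v"])
        assert res.case_minor == 8 - 3
        assert res.case_total == 100 - 4

    def test_zero_group_total_rejected(self):
        v = variant("v", case_minor_chroms=0, case_total_chroms=0)
        with pytest.raises(ValueError):
            popfreq_association(v, m=1)

    def test_bonferroni_false_positive_calibration(self, rng):
        """On null tables the per-experiment count of Bonferroni-significant
        calls is ~alpha (chi-square branch, where the asymptotic p is
        accurate)."""
        alpha, m, n_exp = 0.05, 12, 500
        freq = 0.3
        calls = 0
        for _ in range(n_exp):
            for _ in range(m):
                case_minor = rng.binomial(1200, freq)
                ref_minor = rng.binomial(40_000, freq)
                v = variant("t", ref_minor_chroms=int(ref_minor),
                            ref_total_chroms=40_000,
                            case_minor_chroms=int(case_minor),
                            case_total_chroms=1200)
                calls += popfreq_association(v, alpha=alpha, m=m).significant
        rate = calls / n_exp
        se = np.sqrt(alpha / n_exp)
        assert abs(rate - alpha) <= 3 * se
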