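import numpy as np
import pytest
from scipy import stats as st

from sgskit.multi_family import (
    FamilyEvidence,
    RegionEvidence,
    dedup_cases,
    fisher_combined,
    overlap_regions,
)
from sgskit.pedigree import CaseSubset, Individual, Pedigree
from sgskit.sgs_core import SharedSegment
from sgskit.thresholds import ThresholdPair


def seg(fam, chrom, start, end, p, members=("x", "y", "z")):
    return SharedSegment(
        chromosome=chrom, start_bp=start, end_bp=end, start_index=0,
        end_index=1, n_markers=2,
        subset=CaseSubset(family_id=fam, member_ids=frozenset(members)),
        p_value=p,
    )


def thr(fam, sig=1e-4, sugg=1e-2):
    return ThresholdPair(fam, sig, sugg)


class TestFisherCombined:
    def test_identity_at_k1(self):
        assert fisher_combined([0.05]) == pytest.approx(0.05)

    def test_two_of_one_percent(self):
        # closed form e^{-X/2}(1 + X/2) with X = -2 ln(1e-4) = 18.421
        assert fisher_combined([0.01, 0.01]) == pytest.approx(1.021e-3, rel=1e-3)

    def test_no_evidence_stays_one(self):
        assert fisher_combined([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_scipy_oracle(self, rng):
        for k in (2, 3, 5):
            for _ in range(20):
                ps = rng.uniform(1e-6, 1, size=k)
                expect = st.combine_pvalues(ps, method="fisher").pvalue
                assert fisher_combined(ps) == pytest.approx(expect, rel=1e-9)

    def test_matches_monte_carlo_combination(self, rng):
        # P(prod of k uniforms yields X >= x_obs) estimated by simulation
        for k in (2, 4, 5):
            ps_obs = rng.uniform(0.01, 0.3, size=k)
            x_obs = -2 * np.log(ps_obs).sum()
            u = rng.uniform(size=(1_000_000, k))
            x = -2 * np.log(u).sum(axis=1)
            mc = (x >= x_obs).mean()
            se = np.sqrt(mc * (1 - mc) / 1_000_000)
            assert abs(fisher_combined(ps_obs) - mc) <= 3 * se + 1e-12

    def test_order_invariant(self, rng):
        ps = list(rng.uniform(0.001, 0.9, size=4))
        assert fisher_combined(ps) == pytest.approx(
            fisher_combined(ps[::-1]), rel=1e-12
        )

    def test_adding_uninformative_family_weakens(self):
        base = fisher_combined([0.001, 0.002])
        widened = fisher_combined([0.001, 0.002, 1.0])
        assert widened >= base

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            fisher_combined([0.0, 0.5])


class TestOverlapRegions:
    def test_disjoint_segments_no_multifamily_region(self):
        segs = {"A": [seg("A", "chr1", 100, 500, 1e-3)],
                "B": [seg("B", "chr1", 600, 900, 1e-3)]}
        regions = overlap_regions(segs, {"A": thr("A"), "B": thr("B")})
        assert all(len(r.families) == 1 for r in regions) is True
        assert regions == []  # suggestive-only, no intersection

    def test_interval_intersection(self):
        segs = {"A": [seg("A", "chr1", 100, 500, 1e-3)],
                "B": [seg("B", "chr1", 300, 900, 1e-3)]}
        regions = overlap_regions(segs, {"A": thr("A"), "B": thr("B")})
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (300, 500)
        assert r.family_ids == ["A", "B"]
        assert r.combined_p == pytest.approx(fisher_combined([1e-3, 1e-3]))

    def test_single_family_needs_significant(self):
        segs = {"A": [seg("A", "chr1", 100, 500, 1e-5)],
                "B": [seg("B", "chr2", 100, 500, 1e-3)]}
        regions = overlap_regions(segs, {"A": thr("A"), "B": thr("B")})
        assert len(regions) == 1
        assert regions[0].family_ids == ["A"]
        assert regions[0].families[0].tier == "significant"

    def test_three_family_common_interval(self):
        segs = {
            "A": [seg("A", "chr1", 100, 700, 1e-3)],
            "B": [seg("B", "chr1", 200, 800, 2e-3)],
            "C": [seg("C", "chr1", 300, 900, 3e-3)],
        }
        thrs = {f: thr(f) for f in "ABC"}
        regions = overlap_regions(segs, thrs)
        triple = [r for r in regions if len(r.families) == 3]
        assert len(triple) == 1
        assert (triple[0].start_bp, triple[0].end_bp) == (300, 700)

    def test_above_suggestive_excluded(self):
        segs = {"A": [seg("A", "chr1", 100, 500, 0.5)],
                "B": [seg("B", "chr1", 100, 500, 1e-3)]}
        regions = overlap_regions(segs, {"A": thr("A"), "B": thr("B")})
        assert regions == []


def family_with(fid, members, cases):
    inds = [Individual("F", sex="male"), Individual("M", sex="female")]
    for m in members:
        inds.append(Individual(m, "F", "M", is_case=m in cases,
                               is_genotyped=m in cases))
    return Pedigree(fid, inds)


def region_for(famsubsets):
    return RegionEvidence(
        chrom="chr1", start_bp=100, end_bp=500,
        families=[
            FamilyEvidence(fid, 1e-3, len(subset), frozenset(subset), "suggestive")
            for fid, subset in famsubsets.items()
        ],
    )


class TestDedupCases:
    def test_no_shared_individuals_is_identity(self):
        a = family_with("A", ["a1", "a2", "a3"], {"a1", "a2", "a3"})
        b = family_with("B", ["b1", "b2", "b3"], {"b1", "b2", "b3"})
        region = region_for({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]})
        kept, recompute, excluded = dedup_cases([a, b], region)
        assert kept["A"] == frozenset(["a1", "a2", "a3"])
        assert kept["B"] == frozenset(["b1", "b2", "b3"])
        assert recompute == [] and excluded == []

    def test_removable_case_removed_from_nonessential_family(self):
        # 'x' is in both families but only in B's sharing subset
        a = family_with("A", ["a1", "a2", "a3", "x"], {"a1", "a2", "a3"})
        b = family_with("B", ["b1", "b2", "x"], {"b1", "b2", "x"})
        region = region_for({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "x"]})
        kept, recompute, excluded = dedup_cases([a, b], region)
        assert "x" in kept["B"]
        assert "x" not in kept["A"]
        assert recompute == [] and excluded == []

    def test_essential_to_both_kept_in_larger_family(self):
        a = family_with("A", [f"a{i}" for i in range(6)] + ["x"],
                        {"a1", "a2", "x"})
        b = family_with("B", ["b1", "b2", "x"], {"b1", "b2", "x"})
        region = region_for({"A": ["a1", "a2", "x"], "B": ["b1", "b2", "x"]})
        kept, recompute, excluded = dedup_cases([a, b], region)
        assert "x" in kept["A"]  # larger family keeps the shared case
        assert "x" not in kept["B"]
        assert recompute == ["B"]  # B's p must be recomputed on b1, b2

    def test_family_dropping_below_two_cases_excluded(self):
        a = family_with("A", ["a1", "a2", "x"], {"a1", "a2", "x"})
        b = family_with("B", ["b1", "x"], {"b1", "x"})
        region = region_for({"A": ["a1", "a2", "x"], "B": ["b1", "x"]})
        kept, recompute, excluded = dedup_cases([a, b], region)
        assert excluded == ["B"]
        assert "B" not in kept
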