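import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from sgskit.gene_drop import (
    GeneticMap,
    HaplotypePanel,
    NullDistribution,
    _drop_batch,
    _scan_chunk,
    assign_founder_haplotypes,
    attach_pvalues,
    drop_genes,
    empirical_pvalue,
    read_panel_vcf,
    simulate_null,
)
from sgskit.genoqc import GenotypeMatrix, MarkerMap
from sgskit.pedigree import CaseSubset, Individual, Pedigree
from sgskit.sgs_core import SharedSegment, SubsetScanConfig, subset_scan
from sgskit.synthetic_data import SimConfig, make_panel, write_panel_vcf


def two_marker_setup(cm_gap=10.0):
    mmap = MarkerMap(pd.DataFrame({
        "chrom": ["1", "1"], "id": ["a", "b"], "bp": [1000, 2000],
        "cm": [0.0, cm_gap], "a1": "1", "a2": "2",
    }))
    return mmap, GeneticMap.from_marker_map(mmap)


@pytest.fixture
def small_study(rng):
    cfg = SimConfig(n_chromosomes=2, n_markers_per_chrom=60)
    panel, mmap, gmap = make_panel(cfg, rng)
    return panel, mmap, gmap


class TestFounderAssignment:
    def test_degenerate_single_haplotype_panel(self, sib_pedigree, rng):
        panel = HaplotypePanel(np.array([[0, 1, 1, 0]], dtype=np.int8),
                               np.array(["a", "b", "c", "d"]))
        haps = assign_founder_haplotypes(sib_pedigree, panel, rng)
        for pair in haps.values():
            assert np.array_equal(pair[0], pair[1])
            assert np.array_equal(pair[0], panel.H[0])

    def test_allele_frequencies_converge_to_panel(self, small_study, rng,
                                                  sib_pedigree):
        panel, mmap, _ = small_study
        n_draw = 4000
        total = np.zeros(panel.n_markers)
        for _ in range(n_draw):
            idx = rng.integers(0, panel.n_haplotypes, size=2)
            total += panel.H[idx].sum(axis=0)
        freq = total / (2 * n_draw)
        f = panel.allele_frequencies()
        se = np.sqrt(f * (1 - f) / (2 * n_draw))
        assert np.all(np.abs(freq - f) <= 4 * se + 1e-9)

    def test_complete_ld_pairs_preserved(self, sib_pedigree, rng):
        # panel holds only 00 and 11 haplotypes: no founder may carry 01/10
        panel = HaplotypePanel(
            np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.int8),
            np.array(["a", "b"]),
        )
        for _ in range(200):
            haps = assign_founder_haplotypes(sib_pedigree, panel, rng)
            for pair in haps.values():
                for h in pair:
                    assert h[0] == h[1]

    def test_misaligned_panel_rejected(self, sib_pedigree, rng):
        mmap, _ = two_marker_setup()
        panel = HaplotypePanel(np.zeros((2, 3), dtype=np.int8),
                               np.array(["x", "y", "z"]))
        with pytest.raises(ValueError, match="align"):
            assign_founder_haplotypes(sib_pedigree, panel, rng, mmap)


class TestTransmission:
    def test_zero_cm_chromosome_transmits_intact(self, sib_pedigree, rng):
        mmap, gmap = two_marker_setup(cm_gap=0.0)
        founder_haps = {
            "F": np.array([[0, 0], [1, 1]], dtype=np.int8),
            "M": np.array([[0, 1], [1, 0]], dtype=np.int8),
        }
        for _ in range(100):
            gm = drop_genes(sib_pedigree, founder_haps, mmap, gmap, rng,
                            output_ids=["c1"])
            g = gm.G[0]
            # every gamete is an intact parental haplotype: child genotype is
            # a sum of two unbroken rows
            assert tuple(g) in {(0, 1), (1, 0), (1, 2), (2, 1), (0, 0),
                                (1, 1), (2, 2), (2, 0), (0, 2)} - {(2, 0), (0, 2)}

    def test_homozygous_parent_always_transmits_allele(self, sib_pedigree, rng):
        mmap, gmap = two_marker_setup()
        founder_haps = {
            "F": np.array([[1, 1], [1, 1]], dtype=np.int8),  # hom alt
            "M": np.array([[0, 0], [0, 0]], dtype=np.int8),
        }
        for _ in range(50):
            gm = drop_genes(sib_pedigree, founder_haps, mmap, gmap, rng,
                            output_ids=["c1", "c2"])
            assert np.all(gm.G == 1)

    def test_haldane_recombination_fraction(self, rng):
        # theta for 10 cM = (1 - exp(-0.2)) / 2 = 0.0906
        mmap, gmap = two_marker_setup(cm_gap=10.0)
        ped = Pedigree("f", [
            Individual("F", sex="male"), Individual("M", sex="female"),
            Individual("c", "F", "M", is_genotyped=True),
        ])
        founder_haps = {
            "F": np.array([[0, 0], [1, 1]], dtype=np.int8),
            "M": np.array([[0, 0], [0, 0]], dtype=np.int8),
        }
        n = 60_000
        rec = 0
        for _ in range(n):
            g = drop_genes(ped, founder_haps, mmap, gmap, rng,
                           output_ids=["c"]).G[0]
            rec += g[0] != g[1]
        theta = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(theta * (1 - theta) / n)
        assert abs(rec / n - theta) <= 3 * se

    def test_batched_engine_same_recombination_law(self, rng):
        mmap, gmap = two_marker_setup(cm_gap=10.0)
        ped = Pedigree("f", [
            Individual("F", sex="male"), Individual("M", sex="female"),
            Individual("c", "F", "M", is_genotyped=True),
        ])
        panel = HaplotypePanel(np.array([[0, 0], [1, 1]], dtype=np.int8),
                               np.array(["a", "b"]))
        chrom_cm = [gmap.cm_by_chrom["1"]]
        G = _drop_batch(ped, panel, chrom_cm, ["c"], rng, 60_000)[:, 0, :]
        # founders draw 00/11 pairs uniformly; a gamete changes dosage across
        # the two markers with prob theta/2 (het parent) and direction +-1
        # equally, so the child dosage differs between markers with
        # probability theta - 3 theta^2 / 8
        theta = 0.5 * (1 - np.exp(-0.2))
        p_diff = theta - 3 * theta**2 / 8
        diff = (G[:, 0] != G[:, 1]).mean()
        se = np.sqrt(p_diff * (1 - p_diff) / len(G))
        assert abs(diff - p_diff) <= 3 * se


class TestSimulateNull:
    def _family(self, rng, n_cases=3):
        cfg = SimConfig(case_rule="fixed", n_cases=n_cases)
        from sgskit.synthetic_data import make_pedigree
        ped, _ = make_pedigree(cfg, rng)
        return ped

    def test_fixed_seed_reproducible(self, small_study, rng):
        panel, mmap, gmap = small_study
        ped = self._family(rng)
        cases = [i.id for i in ped.genotyped_cases]
        kw = dict(cfg=SubsetScanConfig(), n_sims=300, seed=5, case_ids=cases,
                  event_sims=200)
        a = simulate_null(ped, panel, mmap, gmap, **kw)
        b = simulate_null(ped, panel, mmap, gmap, **kw)
        for s in a.sorted_cov:
            assert np.array_equal(a.sorted_cov[s], b.sorted_cov[s])
        assert a.events.equals(b.events)

    def test_checkpoint_resume_identical(self, small_study, rng, tmp_path):
        panel, mmap, gmap = small_study
        ped = self._family(rng)
        cases = [i.id for i in ped.genotyped_cases]
        kw = dict(cfg=SubsetScanConfig(), n_sims=500, seed=9, case_ids=cases,
                  chunk_size=100, event_sims=300)
        full = simulate_null(ped, panel, mmap, gmap, **kw)
        # simulate an interruption: run only the first chunks by truncating,
        # then resume from the checkpoint directory
        ck = tmp_path / "ck"
        partial = simulate_null(ped, panel, mmap, gmap, **{**kw, "n_sims": 500},
                                checkpoint_dir=ck, checkpoint_every=100)
        resumed = simulate_null(ped, panel, mmap, gmap, **kw,
                                checkpoint_dir=ck, checkpoint_every=100)
        for s in full.sorted_cov:
            assert np.array_equal(full.sorted_cov[s], resumed.sorted_cov[s])
        assert full.events.equals(resumed.events)

    def test_scan_chunk_numba_matches_numpy(self, rng):
        G = rng.integers(0, 3, size=(40, 5, 50)).astype(np.int8)
        subsets = np.array([[0, 1, 2, 0, 0], [1, 2, 3, 4, 0], [0, 1, 2, 3, 4]])
        ksizes = np.array([3, 4, 5])
        size_idx = np.array([0, 1, 2])
        bp = np.sort(rng.choice(500_000, size=50, replace=False)).astype(np.int64)
        bounds = np.array([0, 25, 50], dtype=np.int64)
        a_cov, a_ev = _scan_chunk(G, subsets, ksizes, size_idx, 3, bp, bounds,
                                  1, 20, use_numba=True)
        b_cov, b_ev = _scan_chunk(G, subsets, ksizes, size_idx, 3, bp, bounds,
                                  1, 20, use_numba=False)
        assert np.array_equal(a_cov, b_cov)
        key = lambda e: e[np.lexsort(e.T[::-1])]
        assert np.array_equal(key(a_ev), key(b_ev))

    def test_sibling_pair_sharing_bounded_by_ibd(self, small_study, rng,
                                                 sib_pedigree):
        # sibs share >= 1 allele IBD with prob 3/4; IBS sharing can only add
        panel, mmap, gmap = small_study
        cfg = SubsetScanConfig(min_subset_size=2)
        null = simulate_null(sib_pedigree, panel, mmap, gmap, cfg, n_sims=2000,
                             seed=3, case_ids=["c1", "c2"], event_sims=100)
        share_frac = np.mean(null.sorted_cov[2][60] >= 0)  # run covers marker
        assert share_frac >= 0.75 - 3 * np.sqrt(0.75 * 0.25 / 2000)

    def test_run_lengths_increase_with_panel_ld(self, rng):
        lengths = {}
        for tag, (block, pool) in {"low": (1, 64), "high": (15, 2)}.items():
            cfg = SimConfig(n_chromosomes=1, n_markers_per_chrom=90,
                            block_n_markers=block, block_pool=pool)
            panel, mmap, gmap = make_panel(cfg, np.random.default_rng(7))
            ped = Pedigree("f", [
                Individual("F", sex="male"), Individual("M", sex="female"),
                Individual("c1", "F", "M", is_case=True, is_genotyped=True),
                Individual("c2", "F", "M", is_case=True, is_genotyped=True),
            ])
            null = simulate_null(ped, panel, mmap, gmap,
                                 SubsetScanConfig(min_subset_size=2),
                                 n_sims=800, seed=11, case_ids=["c1", "c2"],
                                 event_sims=800)
            lengths[tag] = null.events["end_idx"].sub(null.events["start_idx"]).mean()
        assert lengths["high"] > lengths["low"]


class TestEmpiricalPvalue:
    @pytest.fixture
    def null_and_family(self, small_study, rng):
        panel, mmap, gmap = small_study
        cfg = SimConfig(case_rule="fixed", n_cases=3)
        from sgskit.synthetic_data import make_pedigree
        ped, _ = make_pedigree(cfg, rng)
        cases = [i.id for i in ped.genotyped_cases]
        null = simulate_null(ped, panel, mmap, gmap, SubsetScanConfig(),
                             n_sims=2000, seed=21, case_ids=cases,
                             event_sims=500)
        return null, ped, cases, mmap

    def test_trivial_segment_has_p_near_one(self, null_and_family):
        null, ped, cases, mmap = null_and_family
        bp = mmap.df["bp"].to_numpy()
        seg = SharedSegment("chr1", int(bp[5]), int(bp[5]), 5, 5, 1,
                            CaseSubset("fam1", frozenset(cases)))
        assert empirical_pvalue(seg, null) > 0.5

    def test_floor_for_unmatched_segment(self, null_and_family):
        null, ped, cases, mmap = null_and_family
        bp = mmap.df["bp"].to_numpy()
        sl = mmap.chrom_slices()["chr1"]
        seg = SharedSegment("chr1", int(bp[sl.start]), int(bp[sl.stop - 1]),
                            sl.start, sl.stop - 1, sl.stop - sl.start,
                            CaseSubset("fam1", frozenset(cases)))
        # a run spanning a whole chromosome is (almost) never matched
        p = empirical_pvalue(seg, null)
        assert p == pytest.approx(1 / (null.n_sims + 1), rel=0.01) or p < 0.005

    def test_monotone_in_length(self, null_and_family):
        null, ped, cases, mmap = null_and_family
        bp = mmap.df["bp"].to_numpy()
        mid = 30
        ps = []
        for half in (2, 6, 12, 20):
            seg = SharedSegment(
                "chr1", int(bp[mid - half]), int(bp[mid + half]),
                mid - half, mid + half, 2 * half + 1,
                CaseSubset("fam1", frozenset(cases)),
            )
            ps.append(empirical_pvalue(seg, null))
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_uncovered_chromosome_rejected(self, null_and_family):
        null, ped, cases, mmap = null_and_family
        seg = SharedSegment("chr9", 100, 200, 0, 1, 2,
                            CaseSubset("fam1", frozenset(cases)))
        with pytest.raises(ValueError, match="chr9"):
            empirical_pvalue(seg, null)

    def test_fixed_locus_pvalues_superuniform(self, small_study, rng):
        """For a fixed subset and locus, the empirical p of observed sharing
        across replicate null genomes must not be anti-conservative."""
        panel, mmap, gmap = small_study
        cfg = SimConfig(case_rule="fixed", n_cases=3)
        from sgskit.synthetic_data import make_pedigree
        ped, _ = make_pedigree(cfg, rng)
        cases = sorted(i.id for i in ped.genotyped_cases)
        null = simulate_null(ped, panel, mmap, gmap, SubsetScanConfig(),
                             n_sims=3000, seed=33, case_ids=cases, event_sims=10)
        chrom_cm = [gmap.cm_by_chrom[c] for c in mmap.chrom_slices()]
        G = _drop_batch(ped, panel, chrom_cm, cases, rng, 200)
        locus = 30
        pvals = []
        for i in range(200):
            gmi = GenotypeMatrix(cases, G[i])
            segs = subset_scan(gmi, mmap, ped.family_id, cases)
            cover = [s for s in segs if s.start_index <= locus <= s.end_index]
            length = max((s.length_bp for s in cover), default=-1)
            c = null.tail_count(3, locus, length)
            pvals.append((c + 1) / (null.n_sims + 1))
        ks = st.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestPanelIO:
    def test_vcf_round_trip(self, small_study, tmp_path):
        panel, mmap, _ = small_study
        path = tmp_path / "panel.vcf"
        write_panel_vcf(panel, mmap, path)
        back = read_panel_vcf(path, mmap)
        assert np.array_equal(back.H, panel.H)

    def test_null_persistence_round_trip(self, small_study, rng, tmp_path):
        panel, mmap, gmap = small_study
        cfg = SimConfig(case_rule="fixed", n_cases=3)
        from sgskit.synthetic_data import make_pedigree
        ped, _ = make_pedigree(cfg, rng)
        cases = [i.id for i in ped.genotyped_cases]
        null = simulate_null(ped, panel, mmap, gmap, SubsetScanConfig(),
                             n_sims=100, seed=2, case_ids=cases, event_sims=50)
        null.save(tmp_path / "null")
        back = NullDistribution.load(tmp_path / "null")
        assert back.n_sims == null.n_sims
        for s in null.sorted_cov:
            assert np.array_equal(back.sorted_cov[s], null.sorted_cov[s])
        pd.testing.assert_frame_equal(
            back.events, null.events, check_dtype=False
        )
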