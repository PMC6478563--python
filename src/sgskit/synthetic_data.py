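"""Synthetic study generator.

Produces every input the pipeline consumes — multi-generation high-risk
pedigrees, an LD-structured phased haplotype panel with genetic map,
genotypes produced by a true gene drop through each pedigree (optionally
with a founder segment forced through a chosen carrier lineage), stratified
incidence rates, gene models, a variant annotation table with planted
explanatory and associated variants, and a literature gene list — together
with a ground-truth manifest.  All randomness flows from a single seed, so
bundles are bit-identical across runs.

LD is modeled by block-pool concatenation: haplotypes are built by drawing,
for each marker block, one of a small pool of block haplotypes.  This gives
strong within-block and weak between-block correlation — enough to exercise
run-length statistics and whole-haplotype founder resampling — without a
coalescent simulator.  Planted segments are forced by overriding the
transmission choice along the carrier lineage inside the planted interval,
rather than by rejection sampling.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fsir import Stratum, StratumRates, write_rates
from .gene_drop import GeneticMap, HaplotypePanel, _drop_batch
from .genoqc import MISSING, GenotypeMatrix, MarkerMap, write_ped_map
from .pedigree import Individual, Pedigree, write_pedigree

__all__ = [
    "SimConfig",
    "StudyBundle",
    "make_pedigree",
    "make_panel",
    "make_rates",
    "make_gene_models",
    "make_population",
    "make_population_genotypes",
    "plant_missingness",
    "plant_hwe_failure",
    "simulate_study",
]


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the study conditions at
    desk scale (extended high-risk pedigrees averaging ~6 cases
    and ~30 meioses between cases, an LD-structured European-like panel, and
    a follow-up cohort of ~1300 cases)."""

    # pedigree
    n_generations: int = 7
    mean_sibship: float = 2.0
    max_sibship: int = 6
    fixed_sibship: int | None = None  # overrides the Poisson sibship draw
    case_rule: str = "random"  # random | fixed | carrier
    case_rate: float = 0.065
    min_case_generation: int = 6  # status unknown in upper generations
    n_cases: int = 7  # for case_rule="fixed"
    carrier_penetrance: float = 1.0  # for case_rule="carrier"
    # genome / panel
    n_chromosomes: int = 2
    n_markers_per_chrom: int = 150
    markers_per_cm: float = 10.0
    mean_bp_per_marker: int = 10_000
    panel_haplotypes: int = 200
    block_n_markers: int = 5
    block_pool: int = 8
    maf_lo: float = 0.25
    maf_hi: float = 0.75
    # planted segment
    plant_segment: bool = False
    planted_chrom_index: int = 0
    planted_cm_span: float = 3.0
    planted_cm_start: float | None = None  # default: centered
    n_carriers: int = 5
    # study composition
    n_families: int = 1
    missing_rate: float = 0.0
    # annotations / follow-up cohort
    n_annotated: int = 60
    frac_missense: float = 0.45
    frac_frameshift: float = 0.05
    frac_damaging: float = 0.5
    ref_total_chroms: int = 66_000
    case_total_chroms: int = 2_600
    plant_explanatory: bool = False
    n_assoc_planted: int = 1
    assoc_ref_freq: float = 0.00007
    assoc_case_freq: float = 0.009
    # genes
    genes_per_chrom: int = 12
    n_blacklisted: int = 1
    literature_fraction: float = 0.04
    n_genome_genes: int = 500  # notional genome-wide gene count for enrichment


# -- pedigree ----------------------------------------------------------------

def make_pedigree(cfg: SimConfig, rng: np.random.Generator,
                  family_id: str = "fam1") -> tuple[Pedigree, dict]:
    """Single-founder-couple extended pedigree expanded by sibship draws.

    Members marry in unrelated founder spouses; the last generation has no
    children.  Cases are flagged per ``cfg.case_rule`` and genotyped cases
    are the cases (emulating 'cases with DNA').  Returns the pedigree and a
    ground-truth record (generation of each member, descendants, carriers).
    """
    if cfg.n_generations < 2:
        raise ValueError("need at least two generations")
    counter = [0]

    def fresh(prefix):
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    inds: dict[str, Individual] = {}
    generation: dict[str, int] = {}

    f0, m0 = fresh("f"), fresh("f")
    inds[f0] = Individual(f0, sex="male")
    inds[m0] = Individual(m0, sex="female")
    generation[f0] = generation[m0] = 0
    couples = [(f0, m0)]
    descendants: list[str] = []

    for gen in range(1, cfg.n_generations):
        next_couples = []
        for father, mother in couples:
            if cfg.fixed_sibship is not None:
                k = cfg.fixed_sibship
            else:
                k = int(np.clip(rng.poisson(cfg.mean_sibship), 1, cfg.max_sibship))
            for _ in range(k):
                child = fresh("d")
                sex = "male" if rng.random() < 0.5 else "female"
                inds[child] = Individual(child, father, mother, sex=sex)
                generation[child] = gen
                descendants.append(child)
                if gen < cfg.n_generations - 1:
                    spouse = fresh("s")
                    ssex = "female" if sex == "male" else "male"
                    inds[spouse] = Individual(spouse, sex=ssex)
                    generation[spouse] = gen
                    pair = (child, spouse) if sex == "male" else (spouse, child)
                    next_couples.append(pair)
        couples = next_couples

    eligible = [
        d for d in descendants
        if generation[d] >= min(cfg.min_case_generation, cfg.n_generations - 1)
    ]
    carriers: list[str] = []
    if cfg.case_rule == "random":
        cases = [d for d in eligible if rng.random() < cfg.case_rate]
    elif cfg.case_rule == "fixed":
        n = min(cfg.n_cases, len(eligible))
        cases = list(rng.choice(eligible, size=n, replace=False))
    elif cfg.case_rule == "carrier":
        n = min(cfg.n_carriers, len(eligible))
        carriers = list(rng.choice(eligible, size=n, replace=False))
        cases = [c for c in carriers if rng.random() < cfg.carrier_penetrance]
        cases += [
            d for d in eligible
            if d not in carriers and rng.random() < cfg.case_rate
        ]
    else:
        raise ValueError(f"unknown case_rule {cfg.case_rule!r}")

    case_set = set(cases)
    ped = Pedigree(
        family_id,
        [
            Individual(
                i.id, i.father_id, i.mother_id, i.sex,
                is_case=i.id in case_set, is_genotyped=i.id in case_set,
            )
            for i in inds.values()
        ],
    )
    truth = {
        "generation": generation,
        "descendants": descendants,
        "founder_couple": (f0, m0),
        "carriers": carriers,
    }
    return ped, truth


# -- panel / maps ------------------------------------------------------------

def make_panel(cfg: SimConfig, rng: np.random.Generator):
    """LD-structured panel plus marker and genetic maps.

    Returns (HaplotypePanel, MarkerMap, GeneticMap).  Monomorphic marker
    columns are rejected and resampled so the panel is polymorphic at every
    retained marker.
    """
    n_hap, m = cfg.panel_haplotypes, cfg.n_markers_per_chrom
    chrom_blocks = []
    map_rows = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        H = np.empty((n_hap, m), dtype=np.int8)
        j = 0
        while j < m:
            width = min(cfg.block_n_markers, m - j)
            for _ in range(100):
                freqs = rng.uniform(cfg.maf_lo, cfg.maf_hi, size=width)
                pool = (rng.random((cfg.block_pool, width)) < freqs).astype(np.int8)
                # every marker must vary within the pool, else the panel
                # could not be polymorphic there
                const = pool.min(axis=0) == pool.max(axis=0)
                for col in np.nonzero(const)[0]:
                    pool[rng.integers(0, cfg.block_pool), col] ^= 1
                choice = rng.integers(0, cfg.block_pool, size=n_hap)
                block = pool[choice]
                f = block.mean(axis=0)
                if np.all((f > 0) & (f < 1)):
                    break
            else:  # pragma: no cover - resampling essentially never fails
                raise RuntimeError("could not generate polymorphic block")
            H[:, j : j + width] = block
            j += width
        chrom_blocks.append(H)
        bp = np.cumsum(
            rng.integers(
                int(0.5 * cfg.mean_bp_per_marker),
                int(1.5 * cfg.mean_bp_per_marker),
                size=m,
            )
        )
        cm = np.arange(m) / cfg.markers_per_cm
        for k in range(m):
            map_rows.append(
                {
                    "chrom": chrom,
                    "id": f"{chrom}_m{k + 1}",
                    "bp": int(bp[k]),
                    "cm": float(cm[k]),
                    "a1": "1",
                    "a2": "2",
                }
            )
    mmap = MarkerMap(pd.DataFrame(map_rows))
    panel = HaplotypePanel(np.concatenate(chrom_blocks, axis=1), mmap.marker_ids)
    return panel, mmap, GeneticMap.from_marker_map(mmap)


# -- rates / population ------------------------------------------------------

def make_rates() -> StratumRates:
    """Plausible sex- and age-stratified cumulative suicide incidence
    (cases per person), male rates several-fold the female rates."""
    bands = [(0, 20), (20, 40), (40, 60), (60, 120)]
    male = [0.0004, 0.004, 0.005, 0.004]
    female = [0.0001, 0.001, 0.0012, 0.0008]
    strata = [
        Stratum("male", a, b, r) for (a, b), r in zip(bands, male)
    ] + [Stratum("female", a, b, r) for (a, b), r in zip(bands, female)]
    return StratumRates(strata)


def make_population(
    n_families: int,
    family_size: int,
    rates: StratumRates,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Families with random membership and stratum-rate case labels (no
    familial clustering): the null model for familial-risk calibration."""
    rows = []
    for f in range(n_families):
        for i in range(family_size):
            sex = "male" if rng.random() < 0.5 else "female"
            age = float(rng.uniform(10, 90))
            rate = rates.rate_for(sex, age)
            rows.append(
                {
                    "family_id": f"pop{f}",
                    "person_id": f"pop{f}_{i}",
                    "sex": sex,
                    "age": age,
                    "is_case": bool(rng.random() < rate),
                }
            )
    return pd.DataFrame(rows)


def make_population_genotypes(
    panel: HaplotypePanel, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Unrelated individuals formed by random union of panel haplotypes
    (random mating, so Hardy-Weinberg-consistent at panel frequencies)."""
    idx = rng.integers(0, panel.n_haplotypes, size=(n, 2))
    G = (panel.H[idx[:, 0]] + panel.H[idx[:, 1]]).astype(np.int8)
    return GenotypeMatrix([f"ind{i}" for i in range(n)], G)


def plant_missingness(gm: GenotypeMatrix, markers, frac: float,
                      rng: np.random.Generator) -> GenotypeMatrix:
    """Set > ``frac`` of entries missing at the given marker columns."""
    G = gm.G.copy()
    n = gm.n_samples
    k = int(np.floor(frac * n)) + 1
    for j in markers:
        rows = rng.choice(n, size=k, replace=False)
        G[rows, j] = MISSING
    return GenotypeMatrix(gm.sample_ids, G)


def plant_hwe_failure(gm: GenotypeMatrix, markers) -> GenotypeMatrix:
    """Make the given markers uniformly heterozygous (extreme HWE failure
    for any reasonable sample size)."""
    G = gm.G.copy()
    G[:, list(markers)] = 1
    return GenotypeMatrix(gm.sample_ids, G)


# -- genes / annotations -----------------------------------------------------

def make_gene_models(cfg: SimConfig, mmap: MarkerMap, rng: np.random.Generator):
    """Tile each chromosome with gene models (coding body plus a regulatory
    flank); the first ``n_blacklisted`` genes drawn are flagged blacklisted."""
    from .followup import GeneModel

    genes = []
    slices = mmap.chrom_slices()
    bp = mmap.df["bp"].to_numpy()
    gi = 0
    for chrom, sl in slices.items():
        lo, hi = int(bp[sl.start]), int(bp[sl.stop - 1])
        edges = np.linspace(lo, hi, cfg.genes_per_chrom + 1).astype(int)
        for a, b in zip(edges, edges[1:]):
            gi += 1
            span = b - a
            cod_lo = a + span // 4
            cod_hi = b - span // 4
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gi}",
                    chrom=chrom,
                    coding=[(cod_lo, cod_hi)],
                    regulatory=[(a, cod_lo - 1), (cod_hi + 1, b)],
                    blacklisted=False,
                )
            )
    for g in rng.choice(len(genes), size=min(cfg.n_blacklisted, len(genes)),
                        replace=False):
        genes[g].blacklisted = True
    return genes


def _gene_for(bp_pos, chrom, genes):
    for g in genes:
        if str(g.chrom) != str(chrom):
            continue
        for s, e, _ in g.intervals():
            if s <= bp_pos <= e:
                return g.gene_id
    return genes[0].gene_id


# -- the full bundle ---------------------------------------------------------

@dataclass
class StudyBundle:
    config: SimConfig
    seed: int
    panel: HaplotypePanel
    mmap: MarkerMap
    gmap: GeneticMap
    pedigrees: list
    genotypes: dict  # family_id -> GenotypeMatrix (genotyped cases)
    rates: StratumRates
    membership: pd.DataFrame
    genes: list
    annotations: list
    literature_genes: list
    manifest: dict

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        # pedigrees (LINKAGE text, one file with all families)
        with open(os.path.join(outdir, "families.ped"), "w") as fh:
            pass
        for ped in self.pedigrees:
            tmp = os.path.join(outdir, f"_{ped.family_id}.ped")
            write_pedigree(ped, tmp)
            with open(tmp) as src, open(
                os.path.join(outdir, "families.ped"), "a"
            ) as dst:
                dst.write(src.read())
            os.remove(tmp)
        # genotypes per family as PLINK text
        for ped in self.pedigrees:
            gm = self.genotypes[ped.family_id]
            fam = pd.DataFrame(
                {
                    "fid": ped.family_id,
                    "iid": gm.sample_ids,
                    "pat": "0",
                    "mat": "0",
                    "sex": "0",
                    "pheno": "2",
                }
            )
            write_ped_map(
                gm, self.mmap, fam, os.path.join(outdir, f"geno_{ped.family_id}")
            )
        write_panel_vcf(self.panel, self.mmap,
                        os.path.join(outdir, "panel.vcf"))
        self.mmap.df.to_csv(
            os.path.join(outdir, "markers.tsv"), sep="\t", index=False
        )
        write_rates(self.rates, os.path.join(outdir, "rates.tsv"))
        self.membership.to_csv(
            os.path.join(outdir, "membership.tsv"), sep="\t", index=False
        )
        gene_rows = []
        for g in self.genes:
            for s, e, kind in g.intervals():
                gene_rows.append(
                    {
                        "gene": g.gene_id,
                        "chrom": g.chrom,
                        "start": s,
                        "end": e,
                        "kind": kind,
                        "blacklisted": int(g.blacklisted),
                    }
                )
        pd.DataFrame(gene_rows).to_csv(
            os.path.join(outdir, "genes.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "variant_id": v.variant_id,
                    "chrom": v.chrom,
                    "pos": v.bp,
                    "gene": v.gene_id,
                    "consequence": v.consequence,
                    "sift_call": v.sift,
                    "polyphen_call": v.polyphen,
                    "ref_maf": v.ref_maf,
                    "ref_minor_chroms": v.ref_minor_chroms,
                    "ref_total_chroms": v.ref_total_chroms,
                    "case_minor_chroms": v.case_minor_chroms,
                    "case_total_chroms": v.case_total_chroms,
                }
                for v in self.annotations
            ]
        ).to_csv(os.path.join(outdir, "annotations.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "literature_genes.txt"), "w") as fh:
            fh.write("\n".join(self.literature_genes) + "\n")
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def write_panel_vcf(panel: HaplotypePanel, mmap: MarkerMap, path) -> None:
    """Phased haplotype panel as a minimal VCF (GT only)."""
    n_samp = panel.n_haplotypes // 2
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, sl in mmap.chrom_slices().items():
            fh.write(f"##contig=<ID={c}>\n")
        samples = "\t".join(f"H{i}" for i in range(n_samp))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n"
        )
        for j, r in enumerate(mmap.df.itertuples()):
            gts = "\t".join(
                f"{panel.H[2 * i, j]}|{panel.H[2 * i + 1, j]}"
                for i in range(n_samp)
            )
            fh.write(
                f"{r.chrom}\t{r.bp}\t{r.id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _carrier_forcing(ped: Pedigree, truth: dict, carriers, interval_slice):
    """Forced-transmission map for the planted founder segment.

    The top male founder's first haplotype is the carried segment; along the
    descent path from the founder couple to each carrier, every transmission
    inside the interval passes the carried haplotype on.
    """
    from .pedigree import _paths_to_couple

    f0, m0 = truth["founder_couple"]
    couple = (f0, m0)
    forced = {}
    carrying_idx = {f0: 0}  # founder: haplotype A carries the segment
    memo: dict = {}
    edges = set()
    for c in carriers:
        paths = _paths_to_couple(ped, c, couple, memo)
        if not paths:
            raise ValueError(f"carrier {c} does not descend from the founder couple")
        best = min(paths, key=len)
        edges |= set(best)
    # order edges top-down so parent's carrying index is known
    remaining = set(edges)
    while remaining:
        progressed = False
        for (pcouple, child) in sorted(remaining):
            father, mother = pcouple
            parent = father if father in carrying_idx else (
                mother if mother in carrying_idx else None
            )
            if parent is None:
                continue
            forced[(child, parent)] = (interval_slice, carrying_idx[parent])
            # child's carrying gamete: father-gamete is slot 0, mother's slot 1
            carrying_idx[child] = 0 if parent == father else 1
            remaining.discard((pcouple, child))
            progressed = True
        if not progressed:
            raise RuntimeError("carrier lineage is not connected to the founder")
    return forced


def planted_interval_slice(cfg: SimConfig, mmap: MarkerMap, gmap: GeneticMap):
    """Marker slice (within the planted chromosome) of the planted segment."""
    chrom = mmap.chromosomes()[cfg.planted_chrom_index]
    sl = mmap.chrom_slices()[chrom]
    cm = gmap.cm_by_chrom[chrom]
    span = cm[-1] - cm[0]
    start_cm = (
        cfg.planted_cm_start
        if cfg.planted_cm_start is not None
        else cm[0] + (span - cfg.planted_cm_span) / 2
    )
    a = int(np.searchsorted(cm, start_cm, side="left"))
    b = int(np.searchsorted(cm, start_cm + cfg.planted_cm_span, side="right")) - 1
    if b <= a:
        raise ValueError("planted interval covers fewer than two markers")
    return chrom, slice(sl.start + a, sl.start + b + 1)


def simulate_study(cfg: SimConfig, seed: int) -> StudyBundle:
    """Generate the full input bundle with ground-truth manifest."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    panel, mmap, gmap = make_panel(cfg, rng)
    chrom_cm = [gmap.cm_by_chrom[c] for c in mmap.chrom_slices()]
    bp = mmap.df["bp"].to_numpy()

    interval = None
    if cfg.plant_segment:
        chrom, isl = planted_interval_slice(cfg, mmap, gmap)
        interval = {
            "chrom": chrom,
            "slice": isl,
            "start_bp": int(bp[isl.start]),
            "end_bp": int(bp[isl.stop - 1]),
        }

    pedigrees, genotypes = [], {}
    carriers_by_family = {}
    membership_rows = []
    for fi in range(cfg.n_families):
        fid = f"fam{fi + 1}"
        ped, truth = make_pedigree(cfg, rng, family_id=fid)
        gcases = sorted(i.id for i in ped.genotyped_cases)
        forced = None
        carriers: list[str] = []
        if interval is not None and gcases:
            n = min(cfg.n_carriers, len(gcases))
            carriers = sorted(rng.choice(gcases, size=n, replace=False))
            # forcing operates on within-chromosome haplotype state; the
            # interval slice is global but contiguous, which is what
            # _drop_batch expects
            local = interval["slice"]
            forced = _carrier_forcing(ped, truth, carriers, local)
        G = _drop_batch(ped, panel, chrom_cm, gcases, rng, 1, forced=forced)[0]
        if cfg.missing_rate > 0:
            mask = rng.random(G.shape) < cfg.missing_rate
            G = np.where(mask, np.int8(MISSING), G)
        pedigrees.append(ped)
        genotypes[fid] = GenotypeMatrix(gcases, G)
        carriers_by_family[fid] = carriers
        for ind in ped.individuals.values():
            membership_rows.append(
                {
                    "family_id": fid,
                    "person_id": ind.id,
                    "sex": ind.sex if ind.sex != "unknown" else "male",
                    "age": float(np.clip(rng.normal(50, 15), 10, 90)),
                    "is_case": ind.is_case,
                }
            )

    rates = make_rates()
    genes = make_gene_models(cfg, mmap, rng)
    non_blacklisted = [g.gene_id for g in genes if not g.blacklisted]
    n_lit = max(1, int(round(cfg.literature_fraction * len(non_blacklisted))))
    literature = sorted(rng.choice(non_blacklisted, size=n_lit, replace=False))

    annotations, planted_expl, planted_assoc = _make_annotations(
        cfg, rng, mmap, panel, genes, interval, carriers_by_family, genotypes
    )

    manifest = {
        "seed": seed,
        "planted_interval": (
            {
                "chrom": interval["chrom"],
                "start_bp": interval["start_bp"],
                "end_bp": interval["end_bp"],
                "start_idx": interval["slice"].start,
                "end_idx": interval["slice"].stop - 1,
            }
            if interval
            else None
        ),
        "carriers": carriers_by_family if interval else {},
        "explanatory_variants": planted_expl,
        "associated_variants": planted_assoc,
    }
    return StudyBundle(
        config=cfg,
        seed=seed,
        panel=panel,
        mmap=mmap,
        gmap=gmap,
        pedigrees=pedigrees,
        genotypes=genotypes,
        rates=rates,
        membership=pd.DataFrame(membership_rows),
        genes=genes,
        annotations=annotations,
        literature_genes=list(literature),
        manifest=manifest,
    )


def _make_annotations(cfg, rng, mmap, panel, genes, interval,
                      carriers_by_family, genotypes):
    from .followup import VariantAnnotation

    bp = mmap.df["bp"].to_numpy()
    chroms = mmap.df["chrom"].to_numpy()
    ids = mmap.marker_ids
    freqs = panel.allele_frequencies()
    m = mmap.n_markers
    chosen = sorted(
        rng.choice(m, size=min(cfg.n_annotated, m), replace=False).tolist()
    )
    planted_expl: list[str] = []

    if cfg.plant_explanatory and interval is not None:
        # a variant inside the planted interval where the carried founder
        # haplotype holds the allele-2 copy: every carrier inherits it
        isl = interval["slice"]
        fid0 = next(iter(carriers_by_family))
        carriers = carriers_by_family[fid0]
        gm = genotypes[fid0]
        cand = []
        for j in range(isl.start, isl.stop):
            if all(gm.row(c)[j] >= 1 for c in carriers):
                cand.append(j)
        if cand:
            j = cand[len(cand) // 2]
            planted_expl.append(str(ids[j]))
            if j not in chosen:
                chosen.append(j)

    out = []
    assoc_planted: dict[str, dict] = {}
    n_assoc_left = cfg.n_assoc_planted
    for j in sorted(chosen):
        vid = str(ids[j])
        maf = float(min(freqs[j], 1 - freqs[j]))
        u = rng.random()
        if vid in planted_expl:
            consequence, maf = "missense", float(rng.uniform(0.005, 0.05))
        elif u < cfg.frac_missense:
            consequence = "missense"
        elif u < cfg.frac_missense + cfg.frac_frameshift:
            consequence = "frameshift"
        elif u < cfg.frac_missense + cfg.frac_frameshift + 0.3:
            consequence = "synonymous"
        else:
            consequence = "other"
        damaging = rng.random() < cfg.frac_damaging
        sift = "damaging" if damaging and rng.random() < 0.7 else "benign"
        polyphen = "damaging" if damaging and sift != "damaging" else (
            "damaging" if damaging and rng.random() < 0.5 else "benign"
        )
        if rng.random() < 0.1:
            polyphen = "NA"
        plant_assoc = (
            n_assoc_left > 0
            and consequence in ("missense", "frameshift")
            and damaging
            and interval is not None
            and interval["start_bp"] <= bp[j] <= interval["end_bp"]
            and vid not in planted_expl
        )
        if plant_assoc:
            n_assoc_left -= 1
            ref_freq, case_freq = cfg.assoc_ref_freq, cfg.assoc_case_freq
            maf = ref_freq
        else:
            ref_freq = case_freq = min(maf, 0.49)
        ref_minor = int(rng.binomial(cfg.ref_total_chroms, ref_freq))
        case_minor = int(rng.binomial(cfg.case_total_chroms, case_freq))
        v = VariantAnnotation(
            variant_id=vid,
            chrom=str(chroms[j]),
            bp=int(bp[j]),
            gene_id=_gene_for(int(bp[j]), chroms[j], genes),
            consequence=consequence,
            sift=sift,
            polyphen=polyphen,
            ref_maf=float(min(maf, 0.5)),
            ref_minor_chroms=ref_minor,
            ref_total_chroms=cfg.ref_total_chroms,
            case_minor_chroms=case_minor,
            case_total_chroms=cfg.case_total_chroms,
        )
        out.append(v)
        if plant_assoc:
            assoc_planted[vid] = {
                "ref_freq": ref_freq,
                "case_freq": case_freq,
            }
    return out, planted_expl, assoc_planted
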