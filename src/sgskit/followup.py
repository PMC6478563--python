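"""Follow-up of significant shared regions.

Three phases: (1) genes whose coding or regulatory sequence intersects a
region become follow-up targets (known false-positive-prone genes are
blacklisted after intersection); a literature gene set provides an
enrichment comparison of the targeted genes against the genome background;
(2) a within-family screen asks whether any rare (reference MAF < 10%)
non-synonymous array variant strictly inside a region is carried by every
case of the sharing subset, i.e. could by itself explain the sharing;
(3) damaging rare variants (MAF < 20%) in target-gene coding sequence are
tested for allele-frequency elevation in an independent case cohort against
reference-population counts, Fisher's exact test (two-sided) or Pearson
chi-square when both groups show more than ``min_chroms_chi`` minor-allele
chromosomes, under Bonferroni multiplicity control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .genoqc import MISSING, GenotypeMatrix, MarkerMap
from .multi_family import RegionEvidence
from .stats import bonferroni_threshold

__all__ = [
    "GeneModel",
    "VariantAnnotation",
    "AssocResult",
    "target_genes",
    "enrichment_test",
    "familial_variant_screen",
    "select_assoc_variants",
    "popfreq_association",
    "read_annotations",
    "read_gene_models",
]

NONSYNONYMOUS = {"missense", "frameshift"}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    coding: list  # list of (start_bp, end_bp), inclusive
    regulatory: list
    blacklisted: bool = False

    def intervals(self):
        return [(s, e, "coding") for s, e in self.coding] + [
            (s, e, "regulatory") for s, e in self.regulatory
        ]


@dataclass
class VariantAnnotation:
    variant_id: str
    chrom: str
    bp: int
    gene_id: str
    consequence: str  # synonymous | missense | frameshift | other
    sift: str  # damaging | benign | NA
    polyphen: str
    ref_maf: float
    ref_minor_chroms: int = 0
    ref_total_chroms: int = 0
    case_minor_chroms: int = 0
    case_total_chroms: int = 0

    def __post_init__(self):
        if not 0 <= self.ref_maf <= 0.5:
            raise ValueError(f"{self.variant_id}: MAF must be in [0, 0.5]")
        for minor, total in (
            (self.ref_minor_chroms, self.ref_total_chroms),
            (self.case_minor_chroms, self.case_total_chroms),
        ):
            if minor < 0 or total < 0 or minor > total:
                raise ValueError(f"{self.variant_id}: invalid chromosome counts")

    @property
    def damaging(self) -> bool:
        """Damaging by either predictor (OR over non-NA calls)."""
        return "damaging" in (self.sift, self.polyphen)


@dataclass
class AssocResult:
    variant_id: str
    test: str  # fisher_exact | chi_square
    p_value: float
    odds_ratio: float
    case_minor: int
    case_total: int
    ref_minor: int
    ref_total: int
    significant: bool
    threshold: float


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def target_genes(regions, genes) -> list[str]:
    """Gene ids with any coding or regulatory interval intersecting any
    region; blacklisted genes removed after intersection; sorted, unique."""
    hit = set()
    for g in genes:
        for r in regions:
            if str(g.chrom) != str(r.chrom):
                continue
            if any(
                _overlaps(s, e, r.start_bp, r.end_bp) for s, e, _ in g.intervals()
            ):
                hit.add(g.gene_id)
                break
    blacklist = {g.gene_id for g in genes if g.blacklisted}
    return sorted(hit - blacklist)


def enrichment_test(n_target: int, n_hit: int, n_genome: int, n_literature: int):
    """Are literature-supported genes over-represented among targeted genes?

    Returns (expected hits under the genome background, observed proportion,
    one-sided two-proportion z without continuity correction, upper-tail p).
    """
    if min(n_target, n_genome, n_literature) <= 0:
        raise ValueError("counts must be positive")
    if not (0 <= n_hit <= n_target <= n_genome and n_literature <= n_genome):
        raise ValueError("inconsistent counts")
    background = n_literature / n_genome
    expected = n_target * background
    proportion = n_hit / n_target
    pooled = (n_hit + n_literature) / (n_target + n_genome)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_target + 1 / n_genome))
    z = (proportion - background) / se
    p = float(_st.norm.sf(z))
    return float(expected), float(proportion), float(z), p


def familial_variant_screen(
    regions,
    annotations,
    gm: GenotypeMatrix,
    marker_ids,
    maf_cutoff: float = 0.10,
) -> dict:
    """Per-region list of rare non-synonymous variants strictly within the
    region that every case of the sharing subset carries (>= 1 minor allele).

    An empty list means no available array variant explains the sharing.
    ``marker_ids`` aligns annotation variant ids with genotype columns.
    """
    col_of = {mid: j for j, mid in enumerate(marker_ids)}
    have = set(gm.sample_ids)
    out = {}
    for ri, region in enumerate(regions):
        explained = []
        # only subsets fully genotyped in this matrix (i.e. this family's)
        subsets = [
            e.subset_ids for e in region.families if set(e.subset_ids) <= have
        ]
        for v in annotations:
            if v.consequence not in NONSYNONYMOUS:
                continue
            if v.ref_maf >= maf_cutoff:
                continue
            if str(v.chrom) != str(region.chrom):
                continue
            if not (region.start_bp <= v.bp <= region.end_bp):
                continue  # strictly within region boundaries
            j = col_of.get(v.variant_id)
            if j is None:
                continue
            for subset in subsets:
                carried = all(
                    gm.row(iid)[j] >= 1 and gm.row(iid)[j] != MISSING
                    for iid in subset
                )
                if carried:
                    explained.append(v.variant_id)
                    break
        out[ri] = sorted(set(explained))
    return out


def select_assoc_variants(
    annotations,
    regions,
    genes,
    maf_cutoff: float = 0.20,
) -> list[VariantAnnotation]:
    """Variant selection for the population association screen: coding
    sequence of a targeted gene, non-synonymous, damaging by either
    predictor, reference MAF below the cutoff."""
    targets = set(target_genes(regions, genes))
    coding_by_gene = {g.gene_id: g.coding for g in genes}
    chrom_by_gene = {g.gene_id: str(g.chrom) for g in genes}
    out = []
    for v in annotations:
        if v.gene_id not in targets:
            continue
        if v.consequence not in NONSYNONYMOUS:
            continue
        if not v.damaging:
            continue
        if v.ref_maf >= maf_cutoff:
            continue
        in_coding = str(v.chrom) == chrom_by_gene.get(v.gene_id) and any(
            s <= v.bp <= e for s, e in coding_by_gene.get(v.gene_id, [])
        )
        if in_coding:
            out.append(v)
    return out


def popfreq_association(
    v: VariantAnnotation,
    alpha: float = 0.05,
    m: int = 1,
    min_chroms_chi: int = 10,
    exclude_cases=None,
    gm: GenotypeMatrix | None = None,
    marker_ids=None,
) -> AssocResult:
    """Case vs reference-population allele-count association for one variant.

    Builds the 2x2 minor/major chromosome table; uses Pearson chi-square
    (no continuity correction) when both groups have more than
    ``min_chroms_chi`` minor-allele chromosomes, else Fisher's exact test
    (two-sided).  ``exclude_cases`` (with ``gm``/``marker_ids``) removes the
    cases responsible for the original sharing evidence from the case counts
    before testing.
    """
    case_minor, case_total = v.case_minor_chroms, v.case_total_chroms
    if exclude_cases:
        if gm is None or marker_ids is None:
            raise ValueError("exclude_cases requires gm and marker_ids")
        cols = {mid: j for j, mid in enumerate(marker_ids)}
        j = cols.get(v.variant_id)
        if j is None:
            raise KeyError(f"variant {v.variant_id!r} not in genotype matrix")
        for iid in exclude_cases:
            if iid not in gm.sample_ids:
                continue
            g = int(gm.row(iid)[j])
            if g == MISSING:
                continue
            case_minor -= g
            case_total -= 2
    if case_total <= 0 or v.ref_total_chroms <= 0:
        raise ValueError(f"{v.variant_id}: zero total chromosomes in a group")
    if case_minor < 0:
        raise ValueError(f"{v.variant_id}: exclusions exceed case minor count")
    table = np.array(
        [
            [case_minor, case_total - case_minor],
            [v.ref_minor_chroms, v.ref_total_chroms - v.ref_minor_chroms],
        ]
    )
    use_chi = case_minor > min_chroms_chi and v.ref_minor_chroms > min_chroms_chi
    if use_chi:
        stat, p, _, _ = _st.chi2_contingency(table, correction=False)
        test = "chi_square"
    else:
        _, p = _st.fisher_exact(table, alternative="two-sided")
        test = "fisher_exact"
    a, b = table[0]
    c, d = table[1]
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    thr = bonferroni_threshold(alpha, m)
    return AssocResult(
        variant_id=v.variant_id,
        test=test,
        p_value=float(p),
        odds_ratio=float(odds),
        case_minor=int(case_minor),
        case_total=int(case_total),
        ref_minor=int(v.ref_minor_chroms),
        ref_total=int(v.ref_total_chroms),
        significant=bool(p < thr),
        threshold=thr,
    )


# -- I/O --------------------------------------------------------------------

def read_annotations(path) -> list[VariantAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            VariantAnnotation(
                variant_id=r.variant_id,
                chrom=str(r.chrom),
                bp=int(r.pos),
                gene_id=str(r.gene),
                consequence=r.consequence,
                sift=str(r.sift_call),
                polyphen=str(r.polyphen_call),
                ref_maf=float(r.ref_maf),
                ref_minor_chroms=int(r.ref_minor_chroms),
                ref_total_chroms=int(r.ref_total_chroms),
                case_minor_chroms=int(getattr(r, "case_minor_chroms", 0)),
                case_total_chroms=int(getattr(r, "case_total_chroms", 0)),
            )
        )
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Gene models from a BED-like TSV: gene, chrom, start, end, kind
    (coding|regulatory), blacklisted (0/1)."""
    df = pd.read_csv(path, sep="\t")
    genes: dict[str, GeneModel] = {}
    for r in df.itertuples():
        g = genes.setdefault(
            str(r.gene),
            GeneModel(str(r.gene), str(r.chrom), [], [], bool(int(r.blacklisted))),
        )
        iv = (int(r.start), int(r.end))
        (g.coding if r.kind == "coding" else g.regulatory).append(iv)
        g.blacklisted = g.blacklisted or bool(int(r.blacklisted))
    return list(genes.values())


def assoc_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "test": r.test,
                "case_freq": r.case_minor / r.case_total,
                "case_chroms": f"{r.case_minor}/{r.case_total}",
                "ref_freq": r.ref_minor / r.ref_total,
                "ref_chroms": f"{r.ref_minor}/{r.ref_total}",
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
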