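"""Cross-family region overlap and combined evidence.

Regions are reported when a single family reaches its genome-wide
significant threshold, or when segments from two or more families, each at
least genome-wide suggestive for its own family, intersect in bp
coordinates; the reported interval is the intersection.  Multi-family
p-values are combined with Fisher's method (-2 sum ln p against chi-square
with 2k df), which requires the families to be independent: an individual
appearing in two contributing families must first be removed from all but
one of them (``dedup_cases``), after which the affected families' p-values
and thresholds are recomputed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .pedigree import Pedigree
from .sgs_core import SharedSegment
from .thresholds import ThresholdPair

__all__ = [
    "RegionEvidence",
    "overlap_regions",
    "fisher_combined",
    "dedup_cases",
    "regions_to_frame",
]


@dataclass
class FamilyEvidence:
    family_id: str
    p_value: float
    subset_size: int
    subset_ids: frozenset
    tier: str  # significant | suggestive


@dataclass
class RegionEvidence:
    chrom: str
    start_bp: int
    end_bp: int
    families: list  # list[FamilyEvidence]
    combined_p: float | None = None
    flags: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def family_ids(self) -> list:
        return [f.family_id for f in self.families]


def fisher_combined(pvals) -> float:
    """Fisher's combined probability: X = -2 sum ln p_i ~ chi2(2k)."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]; use the estimator floor")
    x = -2.0 * np.log(pvals).sum()
    return float(_st.chi2.sf(x, 2 * pvals.size))


def _best_segment(segments):
    return min(segments, key=lambda s: (s.p_value, -s.subset.size))


def overlap_regions(
    segments_by_family: dict,
    thresholds_by_family: dict,
    combine: bool = True,
) -> list[RegionEvidence]:
    """Single-family significant regions plus multi-family intersections of
    suggestive-or-better segments.

    ``segments_by_family`` maps family_id -> list of SharedSegment with
    p-values attached; ``thresholds_by_family`` maps family_id ->
    ThresholdPair.
    """
    out: list[RegionEvidence] = []

    # single-family genome-wide significant segments
    for fid, segs in sorted(segments_by_family.items()):
        thr = thresholds_by_family[fid]
        for s in segs:
            if s.p_value is None:
                raise ValueError(f"segment without p-value in family {fid}")
            if s.p_value <= thr.significant:
                out.append(
                    RegionEvidence(
                        chrom=s.chromosome,
                        start_bp=s.start_bp,
                        end_bp=s.end_bp,
                        families=[
                            FamilyEvidence(
                                fid, s.p_value, s.subset.size,
                                frozenset(s.subset.member_ids), "significant",
                            )
                        ],
                    )
                )

    # multi-family: sweep atomic intervals of suggestive-or-better segments
    sugg: list[tuple[str, SharedSegment]] = []
    for fid, segs in sorted(segments_by_family.items()):
        thr = thresholds_by_family[fid]
        sugg.extend((fid, s) for s in segs if s.p_value <= thr.suggestive)
    chroms = sorted({s.chromosome for _, s in sugg}, key=str)
    for chrom in chroms:
        here = [(fid, s) for fid, s in sugg if s.chromosome == chrom]
        cuts = sorted({s.start_bp for _, s in here} | {s.end_bp for _, s in here})
        pieces = []  # (lo, hi, frozenset of family ids)
        for lo, hi in zip(cuts, cuts[1:]):
            fams = frozenset(
                fid for fid, s in here if s.start_bp <= lo and hi <= s.end_bp
            )
            if len(fams) >= 2:
                pieces.append([lo, hi, fams])
        # merge adjacent atomic pieces with the identical family set
        merged = []
        for lo, hi, fams in pieces:
            if merged and merged[-1][1] == lo and merged[-1][2] == fams:
                merged[-1][1] = hi
            else:
                merged.append([lo, hi, fams])
        for lo, hi, fams in merged:
            evid = []
            for fid in sorted(fams, key=str):
                cand = [
                    s for f, s in here
                    if f == fid and s.start_bp <= lo and hi <= s.end_bp
                ]
                best = _best_segment(cand)
                thr = thresholds_by_family[fid]
                evid.append(
                    FamilyEvidence(
                        fid, best.p_value, best.subset.size,
                        frozenset(best.subset.member_ids), thr.tier(best.p_value),
                    )
                )
            region = RegionEvidence(chrom=chrom, start_bp=lo, end_bp=hi, families=evid)
            if combine:
                region.combined_p = fisher_combined([e.p_value for e in evid])
            out.append(region)

    out.sort(key=lambda r: (str(r.chrom), r.start_bp, r.end_bp))
    return out


def dedup_cases(families: list[Pedigree], region: RegionEvidence):
    """Independence repair for individuals appearing in several contributing
    families.

    Each such individual is kept in exactly one family: preferentially a
    family whose sharing subset does not contain them (removal elsewhere is
    then harmless); if they are essential to several subsets, the largest
    family keeps them.  Families whose subset drops below two sharing cases
    are excluded from the combination.  Returns (adjusted subsets by family,
    families flagged for p/threshold recomputation, excluded families).
    """
    by_fid = {p.family_id: p for p in families}
    evid_by_fid = {e.family_id: e for e in region.families}
    subsets = {fid: set(e.subset_ids) for fid, e in evid_by_fid.items()}
    shared: dict[str, list[str]] = {}
    for fid, ped in by_fid.items():
        if fid not in evid_by_fid:
            continue
        for iid in ped.individuals:
            shared.setdefault(iid, []).append(fid)
    recompute: set[str] = set()
    for iid, fids in sorted(shared.items()):
        if len(fids) < 2:
            continue
        in_subset = [f for f in fids if iid in subsets[f]]
        if not in_subset:
            keep = max(fids, key=lambda f: (len(by_fid[f].individuals), str(f)))
        elif len(in_subset) == 1:
            keep = in_subset[0]
        else:
            keep = max(in_subset, key=lambda f: (len(by_fid[f].individuals), str(f)))
        for f in fids:
            if f == keep:
                continue
            if iid in subsets[f]:
                subsets[f].discard(iid)
                recompute.add(f)
    excluded = {f for f, s in subsets.items() if len(s) < 2}
    kept = {f: frozenset(s) for f, s in subsets.items() if f not in excluded}
    return kept, sorted(recompute - excluded), sorted(excluded)


def regions_to_frame(regions) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length_bp,
                "families": ",".join(str(f) for f in r.family_ids),
                "n_sharing_cases": ",".join(
                    str(e.subset_size) for e in r.families
                ),
                "p_values": ",".join(f"{e.p_value:.3g}" for e in r.families),
                "combined_p": r.combined_p,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
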