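"""Shared Genomic Segments: observed sharing-run detection.

A shared segment for a set of cases is a maximal run of consecutive markers
at which every case carries at least one copy of a common allele
(identity-by-state).  With biallelic genotypes coded as allele2 dosage,
sharing fails at a marker exactly when both homozygote classes (0 and 2)
appear among the cases; long IBS runs in distant relatives are the signature
of an identical-by-descent segment.  Segment coordinates are the bp of the
first and last sharing marker, and length = end - start.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .genoqc import MISSING, GenotypeMatrix, MarkerMap
from .pedigree import CaseSubset

__all__ = [
    "SharedSegment",
    "SubsetScanConfig",
    "sharing_indicator",
    "maximal_shared_segments",
    "subset_scan",
    "segments_to_frame",
    "write_segments_bed",
]


@dataclass(frozen=True)
class SubsetScanConfig:
    """Configuration for the all-subsets sharing scan.

    ``missing_policy``: 'compatible' treats a missing genotype as compatible
    with any shared allele (missingness does not break a true IBD run);
    'break' ends runs at missing genotypes (sensitivity analysis).
    """

    min_subset_size: int = 3
    min_markers_per_run: int = 1
    missing_policy: str = "compatible"
    max_subsets: int = 5000

    def __post_init__(self):
        if self.min_subset_size < 2:
            raise ValueError("min_subset_size must be >= 2")
        if self.missing_policy not in ("compatible", "break"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class SharedSegment:
    chromosome: str
    start_bp: int
    end_bp: int
    start_index: int  # global marker indices, inclusive
    end_index: int
    n_markers: int
    subset: CaseSubset
    p_value: float | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)

    def contains(self, chrom, bp) -> bool:
        return chrom == self.chromosome and self.start_bp <= bp <= self.end_bp


def sharing_indicator(genotypes_at_marker, missing_policy: str = "compatible") -> bool:
    """True iff one allele can be carried by every individual at the marker."""
    g = np.asarray(genotypes_at_marker)
    if g.size == 0:
        raise ValueError("empty genotype list")
    miss = g == MISSING
    if missing_policy == "break" and miss.any():
        return False
    g = g[~miss]
    if g.size == 0:
        return True  # all missing: compatible with anything
    return not ((g == 0).any() and (g == 2).any())


def _share_vector(G: np.ndarray, missing_policy: str) -> np.ndarray:
    """Vectorized sharing indicator for a cases x markers matrix."""
    miss = G == MISSING
    any0 = ((G == 0) & ~miss).any(axis=0)
    any2 = (G == 2).any(axis=0)
    share = ~(any0 & any2)
    if missing_policy == "break":
        share &= ~miss.any(axis=0)
    return share


def maximal_shared_segments(
    gm: GenotypeMatrix,
    mmap: MarkerMap,
    subset: CaseSubset,
    cfg: SubsetScanConfig = SubsetScanConfig(),
) -> list[SharedSegment]:
    """Maximal sharing runs of ``subset`` over every chromosome, sorted by
    position."""
    members = sorted(subset.member_ids)
    try:
        rows = np.array([gm.sample_ids.index(m) for m in members])
    except ValueError:
        missing = [m for m in members if m not in gm.sample_ids]
        raise KeyError(
            f"subset members absent from genotype matrix: {missing}"
        ) from None
    G = gm.G[rows]
    share = _share_vector(G, cfg.missing_policy)
    bp = mmap.df["bp"].to_numpy()
    out: list[SharedSegment] = []
    for chrom, sl in mmap.chrom_slices().items():
        s = share[sl]
        if not s.any():
            continue
        padded = np.concatenate([[False], s, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0] - 1  # inclusive
        for a, b in zip(starts, ends):
            if b - a + 1 < cfg.min_markers_per_run:
                continue
            ga, gb = sl.start + a, sl.start + b
            out.append(
                SharedSegment(
                    chromosome=chrom,
                    start_bp=int(bp[ga]),
                    end_bp=int(bp[gb]),
                    start_index=int(ga),
                    end_index=int(gb),
                    n_markers=int(b - a + 1),
                    subset=subset,
                )
            )
    out.sort(key=lambda seg: (str(seg.chromosome), seg.start_bp))
    return out


def iter_case_subsets(case_ids, min_size: int, max_subsets: int | None = None):
    """All subsets of the genotyped cases with size >= ``min_size``."""
    case_ids = sorted(case_ids)
    n = len(case_ids)
    total = sum(comb(n, k) for k in range(min_size, n + 1))
    if max_subsets is not None and total > max_subsets:
        raise ValueError(
            f"subset scan would enumerate {total} subsets "
            f"(> cap {max_subsets}); raise max_subsets deliberately"
        )
    for k in range(min_size, n + 1):
        yield from itertools.combinations(case_ids, k)


def subset_scan(
    gm: GenotypeMatrix,
    mmap: MarkerMap,
    family_id: str,
    case_ids,
    cfg: SubsetScanConfig = SubsetScanConfig(),
) -> list[SharedSegment]:
    """Sharing runs for every case subset of size >= min_subset_size.

    Overlapping segments from nested subsets are all retained: when a larger
    subset shares a run, each of its sub-subsets shares a (containing) run.
    """
    case_ids = sorted(set(case_ids))
    if len(case_ids) < cfg.min_subset_size:
        raise ValueError(
            f"need at least {cfg.min_subset_size} genotyped cases, got {len(case_ids)}"
        )
    out: list[SharedSegment] = []
    for members in iter_case_subsets(case_ids, cfg.min_subset_size, cfg.max_subsets):
        subset = CaseSubset(family_id=family_id, member_ids=frozenset(members))
        out.extend(maximal_shared_segments(gm, mmap, subset, cfg))
    out.sort(
        key=lambda s: (str(s.chromosome), s.start_bp, -s.subset.size,
                       tuple(sorted(s.subset.member_ids)))
    )
    return out


# -- output -----------------------------------------------------------------

def segments_to_frame(segments) -> pd.DataFrame:
    rows = []
    for s in segments:
        rows.append(
            {
                "family_id": s.subset.family_id,
                "chrom": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "length_bp": s.length_bp,
                "n_markers": s.n_markers,
                "subset_size": s.subset.size,
                "subset": ",".join(sorted(s.subset.member_ids)),
                "p_value": s.p_value,
            }
        )
    return pd.DataFrame(rows)


def write_segments_bed(segments, path) -> None:
    """BED (half-open) with name=family:subset and score=-log10 p."""
    with open(path, "w") as fh:
        for s in segments:
            score = 0.0 if s.p_value is None else -np.log10(s.p_value)
            name = f"{s.subset.family_id}:{'|'.join(sorted(s.subset.member_ids))}"
            fh.write(
                f"{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t{name}\t{score:.4g}\n"
            )
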