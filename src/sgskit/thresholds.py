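"""Family-specific genome-wide significance thresholds.

The gene-drop null yields, for any candidate p cutoff t, the expected number
E(t) of distinct sharing segments per simulated genome with empirical
p <= t.  The genome-wide *significant* threshold is the cutoff where E(t)
equals 0.5 false positives per genome per family; the *suggestive* threshold
corresponds to E(t) = 1.  E(t) is estimated on a cutoff grid from the
recorded null segments and summarized by a monotone log-log linear fit in
the decision-relevant tail, which also extrapolates below the resolution
1/(n_sims+1) of the empirical p estimator.

Because the null distributions may contain a small number of true positives
when real data are analyzed, the resulting thresholds carry a slight
conservative bias; this is documented, not corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_drop import NullDistribution

__all__ = [
    "NullModelFit",
    "ThresholdPair",
    "fit_null_model",
    "genomewide_thresholds",
    "event_pvalues",
]


class FitDegeneracyError(ValueError):
    """Too few usable grid points to fit the exceedance curve."""


@dataclass
class NullModelFit:
    """Fitted exceedance curve E(t) = expected segments per genome with
    empirical p <= t."""

    family_id: str
    cutoffs: np.ndarray
    counts: np.ndarray  # empirical E(t) on the grid
    slope: float
    intercept: float  # log10 E = intercept + slope * log10 t
    fit_lo: float  # cutoff range used for the fit
    fit_hi: float
    n_sims: int
    n_event_sims: int
    max_rel_err: float  # worst in-window relative error of the fit
    mean_segments_per_genome: float

    def expected_count(self, t) -> np.ndarray:
        """Fitted E(t)."""
        t = np.asarray(t, dtype=float)
        return 10 ** (self.intercept + self.slope * np.log10(t))

    def invert(self, target: float) -> float:
        """Cutoff t with fitted E(t) = target."""
        return float(10 ** ((np.log10(target) - self.intercept) / self.slope))


@dataclass
class ThresholdPair:
    family_id: str
    significant: float
    suggestive: float
    target_fp_significant: float = 0.5
    target_fp_suggestive: float = 1.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.significant <= self.suggestive < 1:
            raise ValueError(
                f"thresholds must satisfy 0 < significant <= suggestive < 1, "
                f"got {self.significant} / {self.suggestive}"
            )

    def tier(self, p: float) -> str:
        if p <= self.significant:
            return "significant"
        if p <= self.suggestive:
            return "suggestive"
        return "none"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "family_id": self.family_id,
                    "significant": self.significant,
                    "suggestive": self.suggestive,
                    "target_fp_significant": self.target_fp_significant,
                    "target_fp_suggestive": self.target_fp_suggestive,
                    "diagnostics": self.diagnostics,
                },
                fh,
                indent=2,
            )


def event_pvalues(null: NullDistribution) -> np.ndarray:
    """Empirical p of every recorded null segment, against the full null."""
    ev = null.events
    if ev.empty:
        return np.empty(0)
    p = np.empty(len(ev))
    size = ev["size"].to_numpy(dtype=int)
    mid = ev["mid_idx"].to_numpy(dtype=int)
    length = ev["length_bp"].to_numpy()
    for s in np.unique(size):
        sel = np.nonzero(size == s)[0]
        cov = null.sorted_cov[null._clamp_size(int(s))]
        for m in np.unique(mid[sel]):
            msel = sel[mid[sel] == m]
            col = cov[m]
            c = null.n_sims - np.searchsorted(col, length[msel], side="left")
            p[msel] = (c + 1) / (null.n_sims + 1)
    return p


def fit_null_model(
    null: NullDistribution,
    grid: np.ndarray | None = None,
    fit_window: tuple[float, float] = (0.05, 5.0),
    min_points: int = 3,
) -> NullModelFit:
    """Estimate and fit the exceedance curve from the recorded null segments.

    ``fit_window`` bounds (in expected-count units) the grid points entering
    the log-log linear fit; the window brackets the 0.5/1.0 false-positive
    targets so the fit is local to the decision region.
    """
    if null.n_sims < 1000:
        raise ValueError("need at least 1,000 simulations to fit thresholds")
    if null.events.empty:
        raise FitDegeneracyError("null distribution recorded no segments")
    p = event_pvalues(null)
    if grid is None:
        lo = 1.0 / (null.n_sims + 1)
        grid = np.logspace(np.log10(lo), 0.0, 40)
        grid[-1] = 1.0
    counts = np.array(
        [np.count_nonzero(p <= t) / null.n_event_sims for t in grid]
    )
    usable = counts > 0
    in_window = usable & (counts >= fit_window[0]) & (counts <= fit_window[1])
    if in_window.sum() < min_points:
        # widen to all nonzero points before declaring degeneracy
        in_window = usable
    if in_window.sum() < min_points:
        raise FitDegeneracyError(
            f"only {int(in_window.sum())} grid points with nonzero counts"
        )
    x = np.log10(grid[in_window])
    y = np.log10(counts[in_window])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise FitDegeneracyError("exceedance curve is not increasing in t")
    fitted = 10 ** (intercept + slope * x)
    max_rel_err = float(np.max(np.abs(fitted - counts[in_window]) / counts[in_window]))
    return NullModelFit(
        family_id=null.family_id,
        cutoffs=grid,
        counts=counts,
        slope=float(slope),
        intercept=float(intercept),
        fit_lo=float(grid[in_window].min()),
        fit_hi=float(grid[in_window].max()),
        n_sims=null.n_sims,
        n_event_sims=null.n_event_sims,
        max_rel_err=max_rel_err,
        mean_segments_per_genome=float(counts[-1]),
    )


def genomewide_thresholds(
    fit: NullModelFit, targets: tuple[float, float] = (0.5, 1.0)
) -> ThresholdPair:
    """Invert the fitted exceedance curve at the false-positive targets."""
    t_sig, t_sug = sorted(targets)
    sig = fit.invert(t_sig)
    sug = fit.invert(t_sug)
    warnings = []
    p_floor = 1.0 / (fit.n_sims + 1)
    for name, t in (("significant", sig), ("suggestive", sug)):
        if t < p_floor:
            warnings.append(
                f"{name} threshold {t:.3g} extrapolates below the empirical "
                f"p floor {p_floor:.3g}"
            )
        if not (fit.fit_lo / 10 <= t <= fit.fit_hi * 10):
            warnings.append(
                f"{name} threshold {t:.3g} lies more than a decade outside "
                f"the fitted cutoff range [{fit.fit_lo:.3g}, {fit.fit_hi:.3g}]"
            )
    sig = min(sig, sug)
    return ThresholdPair(
        family_id=fit.family_id,
        significant=sig,
        suggestive=sug,
        target_fp_significant=t_sig,
        target_fp_suggestive=t_sug,
        diagnostics={
            "slope": fit.slope,
            "intercept": fit.intercept,
            "max_rel_err": fit.max_rel_err,
            "fit_range": [fit.fit_lo, fit.fit_hi],
            "mean_segments_per_genome": fit.mean_segments_per_genome,
            "warnings": warnings,
        },
    )


def thresholds_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": t.family_id,
                "thr_significant": t.significant,
                "thr_suggestive": t.suggestive,
            }
            for t in pairs
        ]
    )


def count_significant(segments, threshold: float) -> int:
    """Distinct (subset size, interval) segments at or below ``threshold``.

    Matches the de-duplication used when recording null segments, so observed
    counts are comparable with the null expected-count calibration.
    """
    seen = set()
    for s in segments:
        if s.p_value is not None and s.p_value <= threshold:
            seen.add((s.subset.size, s.chromosome, s.start_bp, s.end_bp))
    return len(seen)
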