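"""Familial Standardized Incidence Ratio (FSIR).

A family's suicide burden is compared with the expectation under sex- and
age-stratified population incidence: E is the sum of each member's stratum
rate, FSIR = O/E, and significance is the one-sided Poisson tail
P(X >= O | lambda = E).  Expected counts use per-person stratum
probabilities (cross-sectional rates), not person-years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as _st

__all__ = [
    "StratumRates",
    "FamilyCounts",
    "expected_count",
    "fsir_statistic",
    "fsir_pvalue",
    "family_counts",
    "fsir_table",
    "read_rates",
    "write_rates",
]


class StratumError(ValueError):
    """A member falls outside every configured stratum."""


@dataclass(frozen=True)
class Stratum:
    sex: str
    age_min: float
    age_max: float  # exclusive upper bound (inclusive on the oldest band)
    rate: float


class StratumRates:
    """Sex x age-band incidence rates (cases per person).

    Bands are half-open [age_min, age_max), inclusive of age_max on the
    oldest band per sex; bands must be non-overlapping per sex and rates in
    [0, 1].
    """

    def __init__(self, strata: Iterable[Stratum]):
        self.strata = list(strata)
        for s in self.strata:
            if not 0.0 <= s.rate <= 1.0:
                raise ValueError(f"rate out of [0,1] in stratum {s}")
            if s.age_min >= s.age_max:
                raise ValueError(f"inverted age band in stratum {s}")
        self._by_sex: dict[str, list[Stratum]] = {}
        for s in self.strata:
            self._by_sex.setdefault(s.sex, []).append(s)
        for sex, ss in self._by_sex.items():
            ss.sort(key=lambda s: s.age_min)
            for a, b in zip(ss, ss[1:]):
                if b.age_min < a.age_max:
                    raise ValueError(f"overlapping age bands for sex {sex!r}")

    def rate_for(self, sex: str, age: float) -> float:
        ss = self._by_sex.get(sex, [])
        for s in ss:
            if s.age_min <= age < s.age_max:
                return s.rate
        if ss and age == ss[-1].age_max:
            return ss[-1].rate
        raise StratumError(f"no stratum covers sex={sex!r}, age={age}")


@dataclass
class FamilyCounts:
    family_id: str
    observed: int
    expected: float
    fsir: float
    p_value: float


def expected_count(members: Sequence[tuple[str, float]], rates: StratumRates) -> float:
    """E = sum over members of their (sex, age-at-censoring) stratum rate."""
    return float(sum(rates.rate_for(sex, age) for sex, age in members))


def fsir_statistic(observed: int, expected: float) -> float:
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return observed / expected


def fsir_pvalue(observed: int, expected: float) -> float:
    """One-sided Poisson tail P(X >= observed | lambda = expected)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    return float(_st.poisson.sf(observed - 1, expected))


def family_counts(family_id: str, observed: int, expected: float) -> FamilyCounts:
    return FamilyCounts(
        family_id=family_id,
        observed=observed,
        expected=expected,
        fsir=fsir_statistic(observed, expected),
        p_value=fsir_pvalue(observed, expected),
    )


def fsir_table(membership: pd.DataFrame, rates: StratumRates) -> pd.DataFrame:
    """Per-family O, E, FSIR, and Poisson p.

    ``membership`` columns: family_id, person_id, sex, age, is_case.
    """
    rows = []
    for fid, grp in membership.groupby("family_id", sort=True):
        e = expected_count(list(zip(grp["sex"], grp["age"])), rates)
        o = int(grp["is_case"].sum())
        if e <= 0:
            raise ValueError(f"family {fid}: zero expected count")
        rows.append(
            {
                "family_id": fid,
                "n_obs": o,
                "n_exp": e,
                "fsir": fsir_statistic(o, e),
                "fsir_p": fsir_pvalue(o, e),
            }
        )
    return pd.DataFrame(rows)


def read_rates(path) -> StratumRates:
    df = pd.read_csv(path, sep="\t")
    return StratumRates(
        Stratum(r.sex, float(r.age_min), float(r.age_max), float(r.rate))
        for r in df.itertuples()
    )


def write_rates(rates: StratumRates, path) -> None:
    pd.DataFrame(
        [
            {"sex": s.sex, "age_min": s.age_min, "age_max": s.age_max, "rate": s.rate}
            for s in rates.strata
        ]
    ).to_csv(path, sep="\t", index=False)
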