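"""Denominator disaggregation and age-standardised incidence rates.

The person-years at risk (women diagnosed with HIV) are available from
an epidemic model only at the provincial level, by age group and year.
They are disaggregated to municipalities with weights proportional to
observed diagnosed counts per (municipality, age group, year) stratum,
conserving the provincial totals exactly.

Age standardisation weights the posterior draws of the age-specific
rates by a standard population, by default the WHO World Standard
(2000-2025) proportions restricted to the 14 adult age bands in scope
and renormalised to sum to one; any other standard can be supplied as
an (age group, weight) table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardPopulation",
    "WHO_WORLD_STANDARD_15PLUS",
    "disaggregate",
    "age_standardize",
    "crude_rate_from_draws",
]

# WHO World Standard population (Ahmad et al. age-standardisation
# weights), percent shares of the bands 15-19 ... 75-79 and 80+ (80-84
# plus 85+ pooled), before renormalisation over the adult range.
_WHO_SHARES = {
    "15-19": 8.47, "20-24": 8.22, "25-29": 7.93, "30-34": 7.61,
    "35-39": 7.15, "40-44": 6.59, "45-49": 6.04, "50-54": 5.37,
    "55-59": 4.55, "60-64": 3.72, "65-69": 2.96, "70-74": 2.21,
    "75-79": 1.52, "80+": 1.54,
}


@dataclass(frozen=True)
class StandardPopulation:
    """Standard-population weights over the panel's age groups;
    normalised to sum to one over the included groups."""

    age_groups: tuple
    weights: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if len(w) != len(self.age_groups):
            raise ValueError("weights must match age groups")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        object.__setattr__(self, "age_groups", tuple(self.age_groups))
        object.__setattr__(self, "weights", tuple(float(x) for x in w / w.sum()))

    @property
    def w(self) -> np.ndarray:
        return np.asarray(self.weights)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StandardPopulation":
        return cls(tuple(frame["age_group"]), tuple(frame["weight"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_group": self.age_groups, "weight": self.weights})

    @classmethod
    def who_world(cls, age_groups=tuple(_WHO_SHARES)) -> "StandardPopulation":
        missing = [g for g in age_groups if g not in _WHO_SHARES]
        if missing:
            raise ValueError(f"no WHO standard share for age groups {missing}")
        return cls(tuple(age_groups), tuple(_WHO_SHARES[g] for g in age_groups))


WHO_WORLD_STANDARD_15PLUS = StandardPopulation.who_world()


def disaggregate(provincial: pd.DataFrame, area_counts: pd.DataFrame) -> pd.DataFrame:
    """Split provincial person-years onto areas with per-stratum weights
    w_{m,a,t} = count_{m,a,t} / sum over the province's areas.

    ``provincial`` columns: province_id, age_group, year, py_total.
    ``area_counts`` columns: area_id, province_id, age_group, year, count.
    Strata whose counts are all zero get uniform weights (warned).
    Provincial totals are conserved exactly.
    """
    ac = area_counts.copy()
    if (ac["count"] < 0).any():
        raise ValueError("weight counts must be non-negative")
    prov_of = ac.groupby("area_id")["province_id"].nunique()
    if (prov_of > 1).any():
        raise ValueError("each area must map to exactly one province")

    key = ["province_id", "age_group", "year"]
    totals = ac.groupby(key)["count"].transform("sum")
    n_in_stratum = ac.groupby(key)["count"].transform("size")
    if (totals == 0).any():
        warnings.warn("strata with all-zero counts get uniform weights")
    ac["weight"] = np.where(
        totals > 0, ac["count"] / totals.replace(0, 1), 1.0 / n_in_stratum
    )

    merged = ac.merge(provincial, on=key, validate="many_to_one")
    merged["py"] = merged["weight"] * merged["py_total"]
    return merged[["area_id", "province_id", "age_group", "year", "py"]]


def age_standardize(
    rate_draws: np.ndarray,
    age_groups: tuple,
    years: tuple,
    std: StandardPopulation,
) -> pd.DataFrame:
    """Age-standardised rate per year from posterior rate draws.

    ``rate_draws`` has shape (S, n_ages, n_years) on the
    per-100,000-person-years scale; per draw ASR_t = sum_a std_a *
    rate_{a,t}. Returns a frame with the posterior median and
    equal-tailed 95% CrI per year.
    """
    rate_draws = np.asarray(rate_draws, float)
    if rate_draws.ndim != 3 or rate_draws.shape[1] != len(age_groups):
        raise ValueError("rate draws must be (draws, age groups, years)")
    if tuple(age_groups) != tuple(std.age_groups):
        raise ValueError("age groups of the rates and the standard do not match")
    asr = np.einsum("sat,a->st", rate_draws, std.w)
    lo, hi = np.quantile(asr, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "year": list(years),
            "median": np.median(asr, axis=0),
            "lo95": lo,
            "hi95": hi,
        }
    )


def crude_rate_from_draws(rate_draws: np.ndarray, py_by_age_year: np.ndarray) -> np.ndarray:
    """Per-draw crude rate: person-year-weighted mean of the age-year
    rates (same scale as the input rates)."""
    w = py_by_age_year / py_by_age_year.sum()
    return np.einsum("sat,at->s", np.asarray(rate_draws, float), w)
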