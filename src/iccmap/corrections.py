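"""Case-eligibility exclusions and incidence under-ascertainment
corrections.

A pathology-based cancer registry linked probabilistically to HIV
laboratory records under-ascertains incidence in three ways: cases
whose HIV care happened in the private sector never enter the
laboratory database; linkage itself misses true matches; and some
records fail eligibility (bad geocodes, cancer diagnosed long before
the first HIV test, regions with incomplete laboratory coverage).

This module implements, on a case-level registry table:

* the ordered exclusion cascade that defines the analytic case set;
* correction I — oversampling linked private-sector cases to stand in
  for private-sector cases that could never link, replicated M times
  and later pooled by Bayesian model averaging;
* correction II — a per-area multiplicative inflation of the observed
  counts by the odds of being an unlinked non-private case, estimated
  from a sentinel cancer that is assumed to occur only in the
  HIV-positive population (a Kaposi-sarcoma analogue);
* the full correction, summing the additional cases of I and II;
* equal-weight pooling of posterior draws across correction replicates.

Correction II produces non-integer expected counts by design; the
Poisson likelihood accepts them through its continuous extension. A
round-to-nearest mode is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PanelData

__all__ = [
    "DEFAULT_RULES",
    "ExclusionReport",
    "CorrectionResult",
    "apply_exclusions",
    "linked_fraction",
    "oversample_count",
    "correction_one",
    "correction_two",
    "full_correction",
    "sentinel_inflation",
    "bma_pool",
]

#: two-year eligibility rule: cancer diagnosed >= 730 days before the
#: first HIV test (offset below -730) is excluded
TWO_YEAR_RULE_DAYS = -730.0

DEFAULT_RULES = ("unlinked", "geocode", "early_diagnosis", "excluded_region")


@dataclass(frozen=True)
class ExclusionReport:
    """Ordered per-rule removal counts; ``remaining`` after each rule."""

    steps: tuple  # of (rule, removed, remaining)
    initial: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "removed", "remaining"])

    @property
    def final(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial


def _rule_mask(df: pd.DataFrame, rule: str) -> pd.Series:
    """True = keep."""
    if rule == "unlinked":
        return df["linked"].astype(bool)
    if rule == "geocode":
        return df["geocode_valid"].astype(bool)
    if rule == "early_diagnosis":
        off = df["diagnosis_offset_days"]
        return ~(off.notna() & (off < TWO_YEAR_RULE_DAYS))
    if rule == "excluded_region":
        return ~df["excluded_region"].astype(bool)
    raise ValueError(f"unknown exclusion rule {rule!r}")


def apply_exclusions(
    registry: pd.DataFrame, rules: tuple = DEFAULT_RULES
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the eligibility rules in order and report per-rule counts.

    The default order matches the study's selection flow: drop cases
    not linked to an HIV record, then missing/imprecise geocodes, then
    cancers diagnosed two years or more before the first HIV test, then
    cases resident in an excluded region. The survivor set is
    order-invariant; the per-rule counts are not.
    """
    out = registry
    steps = []
    for rule in rules:
        keep = _rule_mask(out, rule)
        removed = int((~keep).sum())
        out = out[keep]
        steps.append((rule, removed, int(len(out))))
    return out, ExclusionReport(steps=tuple(steps), initial=int(len(registry)))


def linked_fraction(registry: pd.DataFrame) -> float:
    """Share of all registry cases that linked to an HIV record:
    (N_total - N_unlinked) / N_total."""
    n_total = len(registry)
    n_unlinked = int((~registry["linked"].astype(bool)).sum())
    return (n_total - n_unlinked) / n_total


def oversample_count(registry: pd.DataFrame) -> int:
    """Correction-I oversample size: floor(n_unlinked_private * f) with
    the linked fraction f rounded to two decimals first (the rounding
    the published worked example uses: 5,077 x 0.43 = 2,183)."""
    n_up = int(
        ((~registry["linked"].astype(bool)) & registry["private"].astype(bool)).sum()
    )
    return int(np.floor(n_up * round(linked_fraction(registry), 2)))


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected per-cell counts for one method (and one replicate for
    the resampling-based corrections)."""

    method: str
    counts: np.ndarray
    additions: np.ndarray
    replicate: int = 0
    n_oversampled: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.additions) < -1e-9):
            raise ValueError("corrected counts must not fall below observed")


def _cases_to_counts(cases: pd.DataFrame, panel: PanelData) -> np.ndarray:
    counts = np.zeros(panel.shape)
    a_idx = {v: i for i, v in enumerate(panel.areas)}
    g_idx = {v: i for i, v in enumerate(panel.age_groups)}
    t_idx = {v: i for i, v in enumerate(panel.years)}
    for area, age, year in zip(cases["area_id"], cases["age_group"], cases["year"]):
        counts[a_idx[area], g_idx[age], t_idx[int(year)]] += 1
    return counts


def correction_one(
    registry: pd.DataFrame,
    panel: PanelData,
    m_replicates: int = 100,
    seed: int = 0,
    rules: tuple = DEFAULT_RULES,
) -> list[CorrectionResult]:
    """Private-sector HIV-diagnosis correction.

    The linked fraction f = (N_total - N_unlinked)/N_total of the
    unlinked private-sector cases is assumed HIV related; n_over =
    floor(n_unlinked_private * f) cases are resampled with replacement
    from the *linked private-sector* cases, passed through the
    exclusion cascade, and the survivors added to the analytic panel —
    repeated ``m_replicates`` times to carry the sampling uncertainty
    into the posterior (via :func:`bma_pool`).
    """
    n_over = oversample_count(registry)
    pool = registry[
        registry["linked"].astype(bool) & registry["private"].astype(bool)
    ]
    if n_over > 0 and len(pool) == 0:
        raise ValueError("no linked private-sector cases to oversample from")
    rng = np.random.default_rng(seed)
    out = []
    for m in range(m_replicates):
        if n_over == 0:
            additions = np.zeros(panel.shape)
        else:
            take = pool.iloc[rng.integers(0, len(pool), size=n_over)]
            survivors, _ = apply_exclusions(take, rules)
            additions = _cases_to_counts(survivors, panel)
        out.append(
            CorrectionResult(
                method="I",
                counts=panel.y + additions,
                additions=additions,
                replicate=m,
                n_oversampled=n_over,
            )
        )
    return out


def sentinel_inflation(sentinel: pd.DataFrame, areas: tuple) -> tuple[np.ndarray, float]:
    """Per-area inflation q_m = (unlinked non-private)/(linked) from the
    sentinel-cancer registry, with the national ratio as fallback for
    areas with no linked sentinel cases. Returns (q per area, national q)."""
    linked = sentinel["linked"].astype(bool)
    private = sentinel["private"].astype(bool)
    unl_np = (~linked) & (~private)
    nat_linked = int(linked.sum())
    if nat_linked == 0:
        raise ValueError("sentinel registry has no linked cases")
    q_nat = float(unl_np.sum() / nat_linked)
    grp = sentinel.assign(unl_np=unl_np, linked=linked).groupby("area_id")
    by_area = grp.agg(unl_np=("unl_np", "sum"), linked=("linked", "sum"))
    q = np.full(len(areas), q_nat)
    fallback = 0
    for i, area in enumerate(areas):
        if area in by_area.index:
            row = by_area.loc[area]
            if row["linked"] > 0:
                q[i] = row["unl_np"] / row["linked"]
            else:
                fallback += 1
        else:
            fallback += 1
    if fallback:
        warnings.warn(
            f"{fallback} areas without linked sentinel cases fall back to the national ratio"
        )
    return q, q_nat


def correction_two(
    panel: PanelData, sentinel: pd.DataFrame, round_counts: bool = False
) -> CorrectionResult:
    """Linkage under-ascertainment correction: corrected counts_m =
    observed_m * (1 + q_m), the per-area inflation spread over age and
    year proportionally to the observed cells (a per-area scalar
    multiplier). Non-integer corrected counts are kept as expected
    counts unless ``round_counts``."""
    q, _ = sentinel_inflation(sentinel, panel.areas)
    counts = panel.y * (1.0 + q)[:, None, None]
    if round_counts:
        counts = np.round(counts)
    additions = counts - panel.y
    return CorrectionResult(method="II", counts=counts, additions=additions)


def full_correction(
    corr1: list[CorrectionResult], corr2: CorrectionResult
) -> list[CorrectionResult]:
    """Combine corrections by summing their additional cases, per
    correction-I replicate."""
    out = []
    for c1 in corr1:
        if c1.additions.shape != corr2.additions.shape:
            raise ValueError("correction panels have mismatched dimensions")
        additions = c1.additions + corr2.additions
        observed = c1.counts - c1.additions
        out.append(
            CorrectionResult(
                method="full",
                counts=observed + additions,
                additions=additions,
                replicate=c1.replicate,
                n_oversampled=c1.n_oversampled,
            )
        )
    return out


def bma_pool(replicate_draws: list):
    """Equal-weight Bayesian model average of posterior draws across
    correction replicates: the pooled posterior is the mixture obtained
    by concatenating the draws. Replicates with unequal draw counts are
    subsampled to the minimum count with a warning."""
    from .inference import PosteriorDraws  # local import to avoid a cycle

    if not replicate_draws:
        raise ValueError("need at least one replicate")
    if len(replicate_draws) == 1:
        return replicate_draws[0]
    counts = [d.n_draws for d in replicate_draws]
    s_min = min(counts)
    if len(set(counts)) > 1:
        warnings.warn("unequal draw counts across replicates; subsampling to the minimum")
    rng = np.random.default_rng(replicate_draws[0].seed)
    pieces = []
    for d in replicate_draws:
        if d.n_draws > s_min:
            idx = np.sort(rng.choice(d.n_draws, size=s_min, replace=False))
        else:
            idx = np.arange(s_min)
        pieces.append((d, idx))

    def cat(attr):
        return np.concatenate([getattr(d, attr)[idx] for d, idx in pieces], axis=0)

    first = replicate_draws[0]
    hyper = {
        nm: np.concatenate([d.hyper[nm][idx] for d, idx in pieces])
        for nm in first.hyper
    }
    eta = cat("eta")
    return PosteriorDraws(
        spec=first.spec,
        areas=first.areas,
        age_groups=first.age_groups,
        years=first.years,
        beta_names=first.beta_names,
        alpha=cat("alpha"),
        beta=cat("beta"),
        u=cat("u"),
        v=cat("v"),
        b=cat("b"),
        gamma=cat("gamma"),
        delta=cat("delta"),
        theta=cat("theta"),
        hyper=hyper,
        eta=eta,
        loglik=cat("loglik"),
        eta_mean=eta.mean(axis=0),
        log_offset=first.log_offset,
        diagnostics={"pooled_replicates": len(replicate_draws)},
        flagged=any(d.flagged for d in replicate_draws),
        seed=first.seed,
    )
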