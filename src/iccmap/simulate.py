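"""Synthetic areal panels, latent fields, case registries and provincial
denominators with the statistical structure the analysis assumes.

The generator emulates the shape of a national HIV/cancer linkage
study: ~200 municipalities observed over 11 calendar years and 14
five-year age groups (15-19 ... 75-79, 80+), Poisson case counts with
person-year offsets, a BYM2 spatial field, RW1 year and age effects, an
iid space-time interaction, decile-coded deprivation and
health-facility covariates, and a case registry carrying the
linkage/sector/geocode flags that drive the exclusion cascade and the
under-ascertainment corrections. Everything is reproducible bit-for-bit
under a fixed seed.

Default parameter values are anchored to the magnitudes a national
cervical-cancer-in-HIV analysis reports: a spatial field sd of 0.5
(relative rates spanning roughly 0.3-4), mixing fraction 0.75 (strong
spatial structure), a gentle year trend, a steep age gradient, and
linkage proportions of 43% linked, 16% of unlinked cases private, and
a sentinel (Kaposi-sarcoma-like) cancer with 70% linkage out of 23,046
cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import SpatialGraph, bym2_field, sample_scaled_icar
from .model import PanelData

__all__ = [
    "SimulationConfig",
    "LinkageConfig",
    "LatentFields",
    "simulate_latent_fields",
    "simulate_covariates",
    "simulate_panel",
    "simulate_registry",
    "RegistryBundle",
    "simulate_provincial_denominators",
    "DEFAULT_AGE_GROUPS",
]

DEFAULT_AGE_GROUPS = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

# Young-skewed age distribution of person-years, emulating the age
# profile of women diagnosed with HIV (mass concentrated at 25-44).
_DEFAULT_AGE_SHARES = np.array(
    [0.055, 0.115, 0.16, 0.17, 0.145, 0.105, 0.075,
     0.05, 0.04, 0.03, 0.022, 0.015, 0.011, 0.007]
)

_DEFAULT_HYPERS = {
    "sigma_b": 0.5,
    "phi": 0.75,
    "sigma_gamma": 0.1,
    "sigma_delta": 0.5,
    "sigma_theta": 0.2,
}


def _default_beta() -> dict:
    """Covariate log relative rates per design level (reference level
    dropped): a monotone ramp over deprivation deciles up to RR ~ 3.2
    for the least deprived, a ramp up to RR ~ 1.5 for the best-served
    facility decile, and a mild negative urban effect."""
    dep = np.log(3.2) * np.arange(1, 10) / 9.0
    fac = np.log(1.5) * np.arange(1, 10) / 9.0
    urb = np.array([np.log(0.85)])
    return {"deprivation": dep, "facilities": fac, "urbanicity": urb}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative counterparts of the model's alpha, beta, sigma, phi."""

    n_rows: int = 10
    n_cols: int = 10
    n_years: int = 11
    age_groups: tuple = DEFAULT_AGE_GROUPS
    true_hyperparameters: dict = field(default_factory=lambda: dict(_DEFAULT_HYPERS))
    true_beta: dict = field(default_factory=_default_beta)
    # reference-cell rate (decile 1, rural, zero latent effects); with the
    # default covariate ramps and field variances the national crude rate
    # lands near 300 cases per 100,000 person-years
    baseline_log_rate: float = float(np.log(55e-5))
    py_scale: float = 750.0
    first_year: int = 2004
    n_provinces: int = 9
    area_size_sd: float = 0.5
    year_growth: float = 0.08
    age_shares: tuple | None = None
    p_urban: float = 0.11
    # neighbour-averaging passes for the covariate surfaces: 0 gives iid
    # surfaces (covariate effects cleanly identified from the spatial
    # field), larger values give spatially smooth covariates that
    # partially alias with the BYM2 field (realistic confounding)
    covariate_smoothing_passes: int = 3
    seed: int = 0

    def __post_init__(self):
        h = self.true_hyperparameters
        if not 0.0 <= h.get("phi", 0.0) <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        for k, val in h.items():
            if k != "phi" and val < 0:
                raise ValueError(f"{k} must be >= 0")
        if self.n_rows * self.n_cols < 4:
            raise ValueError("need at least 4 areas")
        if self.py_scale <= 0:
            raise ValueError("py_scale must be > 0")
        object.__setattr__(self, "age_groups", tuple(self.age_groups))

    @property
    def years(self) -> tuple:
        return tuple(self.first_year + t for t in range(self.n_years))

    def resolved_age_shares(self) -> np.ndarray:
        if self.age_shares is None:
            a = len(self.age_groups)
            if a == len(_DEFAULT_AGE_SHARES):
                shares = _DEFAULT_AGE_SHARES.copy()
            else:
                # aggregate the default 14-group profile onto fewer groups
                chunks = np.array_split(_DEFAULT_AGE_SHARES, a)
                shares = np.array([c.sum() for c in chunks])
        else:
            shares = np.asarray(self.age_shares, float)
            if len(shares) != len(self.age_groups):
                raise ValueError("age_shares length must match age_groups")
        return shares / shares.sum()


@dataclass
class LatentFields:
    """One realisation of all latent effects (truth of a simulation)."""

    b: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    theta: np.ndarray


def _rw1_draw(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Sum-to-zero RW1 path: cumulative sum of N(0, sigma^2) increments,
    centred. sigma = 0 degenerates to the zero path."""
    if n < 2 or sigma == 0.0:
        return np.zeros(n)
    x = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, sigma, n - 1))])
    return x - x.mean()


def simulate_latent_fields(graph: SpatialGraph, config: SimulationConfig) -> LatentFields:
    """Draw the BYM2 field, RW1 year and age paths and the iid
    space-time interaction from the generative model."""
    if graph.n != config.n_rows * config.n_cols:
        raise ValueError("graph size does not match the configured lattice")
    h = config.true_hyperparameters
    rng = np.random.default_rng(config.seed)
    u = sample_scaled_icar(graph, rng)
    v = rng.standard_normal(graph.n)
    b = bym2_field(u, v, h["sigma_b"], h["phi"])
    gamma = _rw1_draw(config.n_years, h["sigma_gamma"], rng)
    delta = _rw1_draw(len(config.age_groups), h["sigma_delta"], rng)
    theta = rng.normal(0.0, h["sigma_theta"], (graph.n, config.n_years))
    return LatentFields(b=b, u=u, v=v, gamma=gamma, delta=delta, theta=theta)


def _smooth_surface(graph: SpatialGraph, rng: np.random.Generator, passes: int = 3) -> np.ndarray:
    """Spatially smooth continuous surface: iid noise averaged with
    neighbour means a few times. Used to mimic spatially autocorrelated
    covariates such as a deprivation index."""
    x = rng.standard_normal(graph.n)
    idx = graph.index
    deg = np.maximum(graph.degrees(), 1)
    for _ in range(passes):
        acc = np.zeros(graph.n)
        for a, c in graph.edges:
            i, j = idx[a], idx[c]
            acc[i] += x[j]
            acc[j] += x[i]
        x = 0.5 * x + 0.5 * acc / deg
    return x


def _deciles(x: np.ndarray) -> np.ndarray:
    """Rank-based decile codes 1..10 (1 = lowest values)."""
    ranks = np.argsort(np.argsort(x))
    return 1 + (10 * ranks) // len(x)


def simulate_covariates(
    graph: SpatialGraph, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Area-level covariates: deprivation decile (1 = most deprived)
    from a ranked smooth surface, facility-count decile likewise, and a
    binary urbanicity flag on the top share of the facility surface."""
    dep = _smooth_surface(graph, rng, passes=config.covariate_smoothing_passes)
    fac = _smooth_surface(graph, rng, passes=config.covariate_smoothing_passes)
    urban_cut = np.quantile(fac, 1.0 - config.p_urban)
    provinces = np.zeros(graph.n, dtype=int)
    for p, chunk in enumerate(np.array_split(np.arange(graph.n), config.n_provinces)):
        provinces[chunk] = p
    return pd.DataFrame(
        {
            "deprivation_decile": _deciles(dep),
            "facility_decile": _deciles(fac),
            "urban": (fac > urban_cut).astype(int),
            "province_id": provinces,
        },
        index=list(graph.node_ids),
    )


def _beta_effect(covariates: pd.DataFrame, true_beta: dict) -> np.ndarray:
    """Per-area covariate contribution x_i' beta with decile levels
    coded against decile 1 and rural as references."""
    n = len(covariates)
    eff = np.zeros(n)
    for name, vals in true_beta.items():
        vals = np.asarray(vals, float)
        if name == "deprivation":
            lev = covariates["deprivation_decile"].to_numpy()
            eff += np.where(lev >= 2, vals[np.clip(lev - 2, 0, 8)], 0.0)
        elif name == "facilities":
            lev = covariates["facility_decile"].to_numpy()
            eff += np.where(lev >= 2, vals[np.clip(lev - 2, 0, 8)], 0.0)
        elif name == "urbanicity":
            eff += vals[0] * covariates["urban"].to_numpy()
        else:
            raise ValueError(f"unknown covariate block {name!r}")
    return eff


def simulate_panel(
    graph: SpatialGraph, fields: LatentFields, config: SimulationConfig
) -> PanelData:
    """Poisson panel y_iat ~ Poisson(E_iat exp(alpha + x_i'beta + b_i +
    gamma_t + delta_a + theta_it)).

    Person-years combine a lognormal area size, the (young-skewed) age
    distribution and a geometric year growth, normalised so the mean
    cell holds ``py_scale`` person-years.
    """
    n = graph.n
    a = len(config.age_groups)
    t = config.n_years
    if fields.b.shape != (n,) or fields.theta.shape != (n, t):
        raise ValueError("latent fields are not dimensioned to the panel")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    covariates = simulate_covariates(graph, config, rng)

    area_size = (
        np.exp(rng.normal(0.0, config.area_size_sd, n))
        if config.area_size_sd > 0
        else np.ones(n)
    )
    age_shares = config.resolved_age_shares()
    year_factor = (1.0 + config.year_growth) ** np.arange(t)
    E = area_size[:, None, None] * age_shares[None, :, None] * year_factor[None, None, :]
    E *= config.py_scale * n * a * t / E.sum()

    eta = (
        np.log(E)
        + config.baseline_log_rate
        + _beta_effect(covariates, config.true_beta)[:, None, None]
        + fields.b[:, None, None]
        + fields.gamma[None, None, :]
        + fields.delta[None, :, None]
        + fields.theta[:, None, :]
    )
    y = rng.poisson(np.exp(eta))
    return PanelData(
        y=y,
        E=E,
        areas=tuple(graph.node_ids),
        age_groups=config.age_groups,
        years=config.years,
        covariates=covariates,
    )


@dataclass(frozen=True)
class LinkageConfig:
    """Probabilities governing the case registry's linkage and sector
    flags, plus the sentinel-cancer stream used by correction II.

    Defaults reproduce the national proportions of the study setting:
    43% of cancer cases link to an HIV record, 16% of unlinked cases
    are private-sector, and the sentinel cancer has 23,046 cases of
    which 70% link and 27.3% of the unlinked are private-sector (so the
    unlinked non-private share is 30% - 8.2% = 21.8% of all sentinel
    cases).
    """

    p_linked: float = 0.43
    p_private_given_unlinked: float = 0.16
    p_private_given_linked: float = 0.16
    sentinel_n: int = 23046
    sentinel_p_linked: float = 0.70
    sentinel_p_private_given_unlinked: float = 0.273
    p_early_diagnosis: float = 0.158
    p_geocode_missing: float = 0.065
    excluded_area_ids: tuple = ()
    seed: int = 0

    def __post_init__(self):
        for name in (
            "p_linked",
            "p_private_given_unlinked",
            "p_private_given_linked",
            "sentinel_p_linked",
            "sentinel_p_private_given_unlinked",
            "p_early_diagnosis",
            "p_geocode_missing",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        object.__setattr__(self, "excluded_area_ids", tuple(self.excluded_area_ids))


@dataclass
class RegistryBundle:
    """Case-level registries: the cancer stream under study (``icc``)
    and the sentinel cancer stream (``sentinel``)."""

    icc: pd.DataFrame
    sentinel: pd.DataFrame


_REGISTRY_COLUMNS = [
    "case_id", "area_id", "age_group", "year", "linked", "private",
    "diagnosis_offset_days", "geocode_valid", "excluded_region",
]


def simulate_registry(panel: PanelData, link_config: LinkageConfig) -> RegistryBundle:
    """Expand the panel's counts into one record per case with linkage,
    sector, diagnosis-offset, geocode-validity and excluded-region
    flags; also draw the per-area sentinel-cancer registry.

    The diagnosis offset is in days from the first HIV test to the
    cancer diagnosis (negative = cancer diagnosed before the test); a
    mixture places a tunable fraction below -730 days, violating the
    two-year eligibility rule. Offsets exist for linked cases only.
    """
    rng = np.random.default_rng(link_config.seed)
    n, a, t = panel.shape
    counts = panel.y
    total = int(counts.sum())
    ai, gi, ti = np.unravel_index(np.arange(panel.n_cells), counts.shape)
    reps = counts.ravel()
    area = np.repeat(np.asarray(panel.areas, object)[ai], reps)
    age = np.repeat(np.asarray(panel.age_groups, object)[gi], reps)
    year = np.repeat(np.asarray(panel.years)[ti], reps)

    linked = rng.random(total) < link_config.p_linked
    p_priv = np.where(
        linked, link_config.p_private_given_linked, link_config.p_private_given_unlinked
    )
    private = rng.random(total) < p_priv
    early = rng.random(total) < link_config.p_early_diagnosis
    offset = np.where(
        early,
        -731.0 - rng.exponential(500.0, total),
        rng.normal(250.0, 350.0, total).clip(min=-730.0),
    )
    offset = np.where(linked, np.round(offset), np.nan)
    geocode_valid = rng.random(total) >= link_config.p_geocode_missing
    excluded = np.isin(area, np.asarray(link_config.excluded_area_ids, object))

    icc = pd.DataFrame(
        {
            "case_id": np.arange(total),
            "area_id": area,
            "age_group": age,
            "year": year,
            "linked": linked,
            "private": private,
            "diagnosis_offset_days": offset,
            "geocode_valid": geocode_valid,
            "excluded_region": excluded,
        }
    )

    area_totals = counts.sum(axis=(1, 2)).astype(float)
    probs = area_totals / area_totals.sum()
    s_area_idx = rng.choice(n, size=link_config.sentinel_n, p=probs)
    s_linked = rng.random(link_config.sentinel_n) < link_config.sentinel_p_linked
    s_p_priv = np.where(
        s_linked,
        link_config.p_private_given_linked,
        link_config.sentinel_p_private_given_unlinked,
    )
    s_private = rng.random(link_config.sentinel_n) < s_p_priv
    sentinel = pd.DataFrame(
        {
            "case_id": np.arange(link_config.sentinel_n),
            "area_id": np.asarray(panel.areas, object)[s_area_idx],
            "linked": s_linked,
            "private": s_private,
        }
    )
    return RegistryBundle(icc=icc, sentinel=sentinel)


def simulate_provincial_denominators(
    panel: PanelData, n_provinces: int, seed: int, count_rate: float = 0.05, noise: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Provincial person-year series plus area-level diagnosed-count
    weights for the disaggregation step.

    Areas are partitioned into ``n_provinces`` contiguous index bands.
    The provincial series is the exact sum of the panel's true municipal
    person-years by age group and year. The diagnosed counts are
    Poisson draws with mean ``count_rate * E`` (``noise=0`` returns the
    exact person-years as counts, so disaggregation round-trips the
    truth).
    """
    if n_provinces < 1:
        raise ValueError("n_provinces must be >= 1")
    n = len(panel.areas)
    if n_provinces > n:
        raise ValueError("more provinces than areas")
    rng = np.random.default_rng(seed)
    province = np.zeros(n, dtype=int)
    for p, chunk in enumerate(np.array_split(np.arange(n), n_provinces)):
        province[chunk] = p

    rows = []
    ai, gi, ti = np.meshgrid(np.arange(n), np.arange(len(panel.age_groups)),
                             np.arange(len(panel.years)), indexing="ij")
    long = pd.DataFrame(
        {
            "area_id": np.asarray(panel.areas, object)[ai.ravel()],
            "province_id": province[ai.ravel()],
            "age_group": np.asarray(panel.age_groups, object)[gi.ravel()],
            "year": np.asarray(panel.years)[ti.ravel()],
            "py": panel.E.ravel(),
        }
    )
    provincial = (
        long.groupby(["province_id", "age_group", "year"], sort=False, as_index=False)["py"]
        .sum()
        .rename(columns={"py": "py_total"})
    )
    if noise == 0:
        cnt = long["py"].to_numpy()
    else:
        cnt = rng.poisson(count_rate * long["py"].to_numpy()).astype(float)
    area_counts = long.assign(count=cnt).drop(columns="py")
    del rows
    return provincial, area_counts
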