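"""Poisson log-linear disease-mapping model: data containers, linear
predictor, likelihood, latent-state prior, and the candidate-model grid.

The observation model for counts indexed by (area i, age group a,
year t) with person-year offsets E is

    y_iat ~ Poisson( E_iat * exp(eta_iat) )
    eta_iat = alpha + x_i' beta + b_i + gamma_t + delta_a + theta_it

where b is a BYM2 spatial field, gamma and delta are first-order
random walks (sum-to-zero) over calendar year and age group, and theta
is an exchangeable iid space-time interaction (type I: unstructured x
unstructured). Decile-coded covariates enter as categorical levels with
decile 1 (most deprived / fewest facilities) as the reference, and
rural as the urbanicity reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graphs import SpatialGraph, scaled_icar_precision
from .priors import PriorConfig, pc_sd_logdensity

__all__ = [
    "PanelData",
    "ModelSpec",
    "LatentState",
    "COVARIATES",
    "covariate_design",
    "linear_predictor",
    "log_likelihood",
    "poisson_loglik_cells",
    "rw1_logdensity",
    "log_prior",
    "enumerate_candidates",
]

#: covariate blocks the model knows about, in design order
COVARIATES = ("deprivation", "facilities", "urbanicity")


@dataclass(frozen=True)
class PanelData:
    """Areal panel of counts and person-years.

    ``y`` and ``E`` are arrays of shape (n_areas, n_ages, n_years),
    fully aligned with no missing cells (structural zeros are explicit
    zero counts). ``covariates`` is an area-level frame indexed like
    ``areas`` with columns ``deprivation_decile``, ``facility_decile``
    (1..10, decile 1 = most deprived / fewest facilities), ``urban``
    (0/1) and ``province_id``.
    """

    y: np.ndarray
    E: np.ndarray
    areas: tuple
    age_groups: tuple
    years: tuple
    covariates: pd.DataFrame

    def __post_init__(self):
        y = np.asarray(self.y)
        E = np.asarray(self.E, float)
        shape = (len(self.areas), len(self.age_groups), len(self.years))
        if y.shape != shape or E.shape != shape:
            raise ValueError(f"y/E must have shape {shape}")
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        if np.any(~(E > 0)):
            raise ValueError("person-years must be strictly positive")
        if list(self.covariates.index) != list(self.areas):
            raise ValueError("covariate frame must be indexed by the panel areas")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "areas", tuple(self.areas))
        object.__setattr__(self, "age_groups", tuple(self.age_groups))
        object.__setattr__(self, "years", tuple(int(t) for t in self.years))

    @property
    def shape(self):
        return self.y.shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.y.shape))

    def with_counts(self, y: np.ndarray) -> "PanelData":
        return replace(self, y=np.asarray(y))


@dataclass(frozen=True)
class ModelSpec:
    """Which random-effect blocks and covariates are active.

    The type-I space-time interaction is an exchangeable iid effect
    over area-year cells (unstructured space x unstructured time); it
    presupposes a spatial dimension in the model, so it may only be
    switched on together with the spatial main effect.
    """

    include_age: bool = True
    include_time: bool = True
    include_space: bool = True
    include_interaction: bool = True
    covariates: tuple = ()

    def __post_init__(self):
        if self.include_interaction and not self.include_space:
            raise ValueError("the space-time interaction requires the spatial effect")
        bad = set(self.covariates) - set(COVARIATES)
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def label(self) -> str:
        parts = [
            name
            for flag, name in [
                (self.include_age, "age"),
                (self.include_time, "time"),
                (self.include_space, "space"),
                (self.include_interaction, "interaction"),
            ]
            if flag
        ]
        return "+".join(parts) if parts else "intercept-only"

    @property
    def hyperparameters(self) -> tuple:
        """Active hyperparameter names, in canonical order."""
        names = []
        if self.include_space:
            names += ["sigma_b", "phi"]
        if self.include_time:
            names.append("sigma_gamma")
        if self.include_age:
            names.append("sigma_delta")
        if self.include_interaction:
            names.append("sigma_theta")
        return tuple(names)


@dataclass
class LatentState:
    """One configuration of all latent effects and hyperparameters.

    Inactive blocks are zero-length or zero arrays; constraints
    (sum-to-zero for gamma, delta and per-component u) are the caller's
    responsibility and are checked by :func:`log_prior`.
    """

    alpha: float
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    theta: np.ndarray
    hyper: dict = field(default_factory=dict)

    @property
    def b(self) -> np.ndarray:
        sigma_b = self.hyper.get("sigma_b", 0.0)
        phi = self.hyper.get("phi", 0.0)
        if len(self.u) == 0:
            return np.zeros(0)
        return sigma_b * (np.sqrt(phi) * self.u + np.sqrt(1 - phi) * self.v)


def covariate_design(data: PanelData, covariates: tuple) -> tuple[np.ndarray, list]:
    """Area-level design matrix for the requested covariate blocks.

    Deciles become 9 indicator columns each (levels 2..10, decile 1 as
    reference); urbanicity one indicator (urban vs rural reference).
    Returns (X of shape (n_areas, k), column names).
    """
    cols, names = [], []
    cov = data.covariates
    for name in covariates:
        if name == "deprivation":
            for lev in range(2, 11):
                cols.append((cov["deprivation_decile"].to_numpy() == lev).astype(float))
                names.append(f"deprivation_decile_{lev}")
        elif name == "facilities":
            for lev in range(2, 11):
                cols.append((cov["facility_decile"].to_numpy() == lev).astype(float))
                names.append(f"facility_decile_{lev}")
        elif name == "urbanicity":
            cols.append(cov["urban"].to_numpy().astype(float))
            names.append("urban")
    x = np.column_stack(cols) if cols else np.zeros((len(data.areas), 0))
    return x, names


def linear_predictor(
    state: LatentState, data: PanelData, spec: ModelSpec
) -> np.ndarray:
    """Per-cell log mean eta_iat, including the log person-year offset."""
    n, a, t = data.shape
    x, _ = covariate_design(data, spec.covariates)
    if x.shape[1] != len(state.beta):
        raise ValueError("beta length does not match the covariate design")
    eta = np.log(data.E) + state.alpha
    eta += (x @ np.asarray(state.beta, float))[:, None, None]
    if spec.include_space:
        b = state.b
        if len(b) != n:
            raise ValueError("spatial field length does not match areas")
        eta += b[:, None, None]
    if spec.include_time:
        if len(state.gamma) != t:
            raise ValueError("gamma length does not match years")
        eta += np.asarray(state.gamma)[None, None, :]
    if spec.include_age:
        if len(state.delta) != a:
            raise ValueError("delta length does not match age groups")
        eta += np.asarray(state.delta)[None, :, None]
    if spec.include_interaction:
        theta = np.asarray(state.theta)
        if theta.shape != (n, t):
            raise ValueError("theta must have shape (areas, years)")
        eta += theta[:, None, :]
    return eta


def poisson_loglik_cells(y, eta) -> np.ndarray:
    """Per-cell Poisson log likelihood y*eta - exp(eta) - ln(y!).

    Accepts non-integer y (expected counts from the incidence
    corrections) via the continuous extension with ln Gamma(y+1).
    """
    y = np.asarray(y, float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    eta = np.asarray(eta, float)
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def log_likelihood(y, eta) -> float:
    """Total Poisson log likelihood over all cells."""
    return float(poisson_loglik_cells(y, eta).sum())


def rw1_logdensity(x: np.ndarray, sigma: float) -> float:
    """Sum-to-zero first-order random-walk log density via its
    increment representation: the n-1 increments are iid N(0, sigma^2).
    The overall level is not penalised (it is fixed by the constraint);
    the intercept carries the level of the predictor."""
    x = np.asarray(x, float)
    if len(x) < 2:
        return 0.0
    inc = np.diff(x)
    m = len(inc)
    return float(
        -0.5 * m * np.log(2 * np.pi * sigma**2) - np.sum(inc**2) / (2 * sigma**2)
    )


_CONSTRAINT_TOL = 1e-6


def log_prior(
    state: LatentState,
    spec: ModelSpec,
    graph: SpatialGraph | None,
    priors: PriorConfig,
) -> float:
    """Joint log prior of the latent state under the hierarchical model.

    BYM2 on (u, v) given (sigma_b, phi) with the scaled-ICAR structure;
    sum-to-zero RW1 on gamma and delta; iid normal on theta; PC priors
    on all sd hyperparameters and on phi (the phi prior needs the graph
    and is added by the inference layer where its eigenvalues are
    cached — here the sd priors and the Gaussian field densities are
    summed); weakly-informative normals on alpha and beta.
    """
    lp = 0.0
    fe_var = priors.fixed_effect_sd**2
    lp += -0.5 * np.log(2 * np.pi * fe_var) - state.alpha**2 / (2 * fe_var)
    beta = np.asarray(state.beta, float)
    lp += float(
        -0.5 * len(beta) * np.log(2 * np.pi * fe_var) - np.sum(beta**2) / (2 * fe_var)
    )
    if spec.include_space:
        if graph is None:
            raise ValueError("spatial model needs a contiguity graph")
        u = np.asarray(state.u, float)
        for comp in graph.components():
            if len(comp) >= 2 and abs(u[comp].sum()) > _CONSTRAINT_TOL:
                raise ValueError("u violates the per-component sum-to-zero constraint")
        q = scaled_icar_precision(graph)
        # improper density on the constrained subspace: quadratic form only
        lp += float(-0.5 * u @ q @ u)
        v = np.asarray(state.v, float)
        lp += float(-0.5 * len(v) * np.log(2 * np.pi) - 0.5 * np.sum(v**2))
        lp += float(pc_sd_logdensity(state.hyper["sigma_b"], priors.sd))
    if spec.include_time:
        if abs(np.sum(state.gamma)) > _CONSTRAINT_TOL:
            raise ValueError("gamma violates the sum-to-zero constraint")
        lp += rw1_logdensity(state.gamma, state.hyper["sigma_gamma"])
        lp += float(pc_sd_logdensity(state.hyper["sigma_gamma"], priors.sd))
    if spec.include_age:
        if abs(np.sum(state.delta)) > _CONSTRAINT_TOL:
            raise ValueError("delta violates the sum-to-zero constraint")
        lp += rw1_logdensity(state.delta, state.hyper["sigma_delta"])
        lp += float(pc_sd_logdensity(state.hyper["sigma_delta"], priors.sd))
    if spec.include_interaction:
        sig = state.hyper["sigma_theta"]
        th = np.asarray(state.theta, float)
        lp += float(
            -0.5 * th.size * np.log(2 * np.pi * sig**2) - np.sum(th**2) / (2 * sig**2)
        )
        lp += float(pc_sd_logdensity(sig, priors.sd))
    return float(lp)


def enumerate_candidates() -> list[ModelSpec]:
    """All covariate-free candidate structures for model selection:
    the 8 subsets of {age, time, space} plus a type-I interaction added
    to each subset containing the spatial effect — 12 specs total.
    Selection precedes covariates (candidates carry none)."""
    out = []
    for age, time, space in itertools.product([False, True], repeat=3):
        out.append(
            ModelSpec(
                include_age=age,
                include_time=time,
                include_space=space,
                include_interaction=False,
            )
        )
        if space:
            out.append(
                ModelSpec(
                    include_age=age,
                    include_time=time,
                    include_space=space,
                    include_interaction=True,
                )
            )
    return out
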