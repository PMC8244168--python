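"""Penalised-complexity (PC) priors for the model's hyperparameters.

Two priors are implemented, the two the hierarchical model needs:

* PC prior for a precision ``tau`` of a Gaussian random effect (the
  type-2 Gumbel), calibrated by ``P(sigma > U) = alpha`` where
  ``sigma = tau**-0.5``; equivalently sigma ~ Exponential(lambda) with
  ``lambda = -ln(alpha) / U``.
* PC prior for the BYM2 mixing fraction ``phi``, built from the
  Kullback-Leibler distance between the BYM2 field at ``phi`` and the
  pure-overdispersion base model at ``phi = 0``, calibrated by
  ``P(phi < U_phi) = alpha_phi``. The distance depends on the contiguity
  graph through the eigenvalues of the scaled-ICAR generalised
  covariance.

Densities are exact up to quadrature tolerance; the mixing prior's rate
is found by root-finding on its calibration equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .graphs import ZERO_EIG_RTOL, SpatialGraph, icar_precision, scaling_factor

__all__ = [
    "PcPrecisionSpec",
    "PcMixingSpec",
    "PriorConfig",
    "pc_prec_logdensity",
    "pc_sd_logdensity",
    "pc_mixing_logdensity",
    "mixing_kld",
    "mixing_distance",
    "scaled_icar_covariance_eigenvalues",
]


@dataclass(frozen=True)
class PcPrecisionSpec:
    """Encodes P(sigma > U) = alpha for a random-effect sd sigma."""

    U: float = 1.0
    alpha: float = 0.01

    def __post_init__(self):
        if not self.U > 0:
            raise ValueError("U must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def rate(self) -> float:
        """Exponential rate on the sd scale: lambda = -ln(alpha)/U."""
        return -np.log(self.alpha) / self.U


def pc_prec_logdensity(tau, spec: PcPrecisionSpec):
    """Log density of the PC (type-2 Gumbel) prior on a precision:
    pi(tau) = (lambda/2) tau^(-3/2) exp(-lambda tau^(-1/2))."""
    tau = np.asarray(tau, float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    lam = spec.rate
    return np.log(lam / 2.0) - 1.5 * np.log(tau) - lam / np.sqrt(tau)


def pc_sd_logdensity(sigma, spec: PcPrecisionSpec):
    """Induced density on sigma = tau^(-1/2): Exponential(lambda)."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    lam = spec.rate
    return np.log(lam) - lam * sigma


def scaled_icar_covariance_eigenvalues(graph: SpatialGraph) -> np.ndarray:
    """Non-null eigenvalues of the scaled-ICAR generalised covariance.

    Per connected component of >= 2 nodes: eigen-decompose the scaled
    structure matrix and invert the non-zero eigenvalues. Islands
    contribute nothing (their structured effect is pinned at zero).
    """
    q = icar_precision(graph)
    eigs = []
    for comp, s in zip(graph.components(), scaling_factor(graph).values()):
        if s is None:
            continue
        w = np.linalg.eigvalsh(s * q[np.ix_(comp, comp)])
        nz = w > ZERO_EIG_RTOL * w.max()
        eigs.append(1.0 / w[nz])
    if not eigs:
        raise ValueError("graph has no component with >= 2 nodes")
    return np.concatenate(eigs)


def mixing_kld(phi, gamma_eigs: np.ndarray):
    """KLD( BYM2(phi) || base model phi=0 ) on the constrained subspace:
    0.5 * [ phi (sum(gamma) - n) - sum ln(1 - phi + phi gamma) ]
    with gamma the scaled-ICAR generalised-covariance eigenvalues."""
    phi = np.asarray(phi, float)
    g = np.asarray(gamma_eigs, float)
    n = g.size
    mix = 1.0 - phi[..., None] + phi[..., None] * g
    return 0.5 * (phi * (g.sum() - n) - np.log(mix).sum(axis=-1))


def mixing_distance(phi, gamma_eigs: np.ndarray):
    """d(phi) = sqrt(2 KLD(phi)); d(0) = 0 and d is increasing."""
    return np.sqrt(np.maximum(2.0 * mixing_kld(phi, gamma_eigs), 0.0))


@dataclass(frozen=True)
class PcMixingSpec:
    """Encodes P(phi < U_phi) = alpha_phi for the BYM2 mixing fraction,
    with the graph entering through cached covariance eigenvalues."""

    graph_eigenvalues: tuple
    U_phi: float = 0.5
    alpha_phi: float = 2.0 / 3.0
    _rate: float = field(init=False, default=None, repr=False, compare=False)

    def __post_init__(self):
        if not 0.0 < self.U_phi < 1.0:
            raise ValueError("U_phi must lie in (0, 1)")
        if not 0.0 < self.alpha_phi < 1.0:
            raise ValueError("alpha_phi must lie in (0, 1)")
        object.__setattr__(
            self, "graph_eigenvalues", tuple(float(g) for g in self.graph_eigenvalues)
        )

    @classmethod
    def for_graph(cls, graph: SpatialGraph, U_phi=0.5, alpha_phi=2.0 / 3.0):
        return cls(
            graph_eigenvalues=tuple(scaled_icar_covariance_eigenvalues(graph)),
            U_phi=U_phi,
            alpha_phi=alpha_phi,
        )

    @property
    def eigs(self) -> np.ndarray:
        return np.asarray(self.graph_eigenvalues)

    @property
    def rate(self) -> float:
        """Rate lambda_phi solving P(phi < U_phi) = alpha_phi.

        The truncated-exponential CDF in distance space gives
        P(phi < U) = (1 - exp(-lam d(U))) / (1 - exp(-lam d(1-eps)));
        the root is found by bracketing + brentq and cached.
        """
        if self._rate is not None:
            return self._rate
        d_u = float(mixing_distance(np.array(self.U_phi), self.eigs))
        d_1 = float(mixing_distance(np.array(1.0 - 1e-12), self.eigs))

        def calib(lam):
            return np.expm1(-lam * d_u) / np.expm1(-lam * d_1) - self.alpha_phi

        # As lam -> 0 the CDF ratio -> d_u/d_1; as lam -> inf it -> 1.
        lo, hi = 1e-8, 1.0
        f_lo = calib(lo)
        if f_lo >= 0:
            # need smaller ratio: no positive root; push toward 0 fails
            raise ValueError(
                "PC mixing calibration cannot be satisfied: "
                f"alpha_phi={self.alpha_phi} <= limiting mass d(U)/d(1)={d_u / d_1:.4f}"
            )
        while calib(hi) < 0:
            hi *= 2.0
            if hi > 1e8:
                raise ValueError("PC mixing calibration root not bracketable")
        lam = optimize.brentq(calib, lo, hi, xtol=1e-12, rtol=1e-12)
        object.__setattr__(self, "_rate", float(lam))
        return self._rate


_FD_STEP = 1e-6  # central-difference step for d'(phi)


def pc_mixing_logdensity(phi, spec: PcMixingSpec):
    """Log density of the PC prior on the BYM2 mixing fraction:
    pi(phi) = lam exp(-lam d(phi)) |d'(phi)| / (1 - exp(-lam d(1))),
    with d'(phi) by central finite differences."""
    phi = np.asarray(phi, float)
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise ValueError("phi must lie in (0, 1)")
    g = spec.eigs
    lam = spec.rate
    lo = np.clip(phi - _FD_STEP, 1e-14, None)
    hi = np.clip(phi + _FD_STEP, None, 1.0 - 1e-14)
    dprime = (mixing_distance(hi, g) - mixing_distance(lo, g)) / (hi - lo)
    d = mixing_distance(phi, g)
    d1 = float(mixing_distance(np.array(1.0 - 1e-12), g))
    return (
        np.log(lam)
        - lam * d
        + np.log(np.abs(dprime))
        - np.log(-np.expm1(-lam * d1))
    )


@dataclass(frozen=True)
class PriorConfig:
    """All prior settings of the model in one place.

    ``sd`` applies to every random-effect standard deviation
    (spatial field, year RW1, age RW1, space-time interaction);
    ``phi`` to the BYM2 mixing fraction; ``fixed_effect_sd`` is the sd
    of the weakly-informative normal prior on the intercept and the
    covariate log relative rates.
    """

    sd: PcPrecisionSpec = field(default_factory=PcPrecisionSpec)
    phi_U: float = 0.5
    phi_alpha: float = 2.0 / 3.0
    fixed_effect_sd: float = 10.0

    def mixing_spec(self, graph: SpatialGraph) -> PcMixingSpec:
        return PcMixingSpec.for_graph(graph, self.phi_U, self.phi_alpha)
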