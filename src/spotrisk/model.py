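"""Log-likelihood and log-priors for the spatio-temporal Poisson families.

Five model families share one Poisson likelihood with offset e_it:

* ``RR_SPACE_TIME``   log mu_it = log e_it + alpha + phi_i + nu_i + delta_t
* ``GROWTH_UNIFORM``  log mu_it = log e_it + alpha + phi_i + gamma * t
* ``GROWTH_EXCH``     log mu_it = log e_it + alpha + phi_i + gamma_i * t,
  gamma_i ~ Normal(mu_gamma, sigma_gamma^2)
* ``GROWTH_CAR``      as GROWTH_EXCH but the gamma_i deviations follow an
  intrinsic CAR prior around mu_gamma
* ``ECO_REGRESSION``  RR_SPACE_TIME plus a covariate slope beta * x_it

phi_i is an exchangeable Normal(0, sigma_phi^2) heterogeneity effect; nu_i
is an intrinsic CAR (ICAR) spatially structured effect kept on the
sum-to-zero subspace; delta_t is an unstructured year effect with
delta_1 = 0 as the baseline; alpha has a flat prior.  Precisions carry
Gamma hyperpriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .adjacency import AdjacencyGraph
from .panel import AreaYearPanel, CovariatePanel

__all__ = [
    "FAMILIES",
    "HyperPriors",
    "ModelSpec",
    "ParameterState",
    "time_scores",
    "linear_predictor",
    "log_likelihood",
    "log_prior_icar",
    "relative_risk_surface",
]

FAMILIES = ("RR_SPACE_TIME", "GROWTH_UNIFORM", "GROWTH_EXCH", "GROWTH_CAR",
            "ECO_REGRESSION")

# keep exp() in the likelihood finite; fits with larger linear predictors
# indicate a mis-scaled model rather than a numerical problem
ETA_MAX = 50.0


@dataclass
class HyperPriors:
    """Hyperprior settings for variance components and the slope.

    Precisions tau = 1/sigma^2 get Gamma(shape, rate) priors; the default
    Gamma(0.5, 0.0005) is the vague GeoBUGS convention for disease-mapping
    variance components.  The covariate slope gets a Normal(0, sd^2) prior
    and the overall growth mean a Normal(mean, sd^2) prior.
    """

    precision_shape: float = 0.5
    precision_rate: float = 0.0005
    slope_prior_sd: float = 100.0
    mu_gamma_prior_mean: float = 0.0
    mu_gamma_prior_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("Gamma hyperprior shape/rate must be positive")
        if self.slope_prior_sd <= 0 or self.mu_gamma_prior_sd <= 0:
            raise ValueError("prior sds must be positive")


@dataclass
class ModelSpec:
    """Which effects are active and under what priors."""

    family: str = "RR_SPACE_TIME"
    include_phi: bool = True
    include_nu: bool = True
    include_delta: bool = True
    covariate: CovariatePanel | None = None
    hyperpriors: HyperPriors = field(default_factory=HyperPriors)
    time_coding: str = "centered"  # or "raw" (t = 1..T)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.time_coding not in ("raw", "centered"):
            raise ValueError("time_coding must be 'raw' or 'centered'")
        if self.family == "ECO_REGRESSION" and self.covariate is None:
            raise ValueError("ECO_REGRESSION requires a covariate")
        if self.family in ("GROWTH_UNIFORM", "GROWTH_EXCH", "GROWTH_CAR"):
            # the growth families drop the structured spatial and the
            # unstructured temporal effect; phi stays
            self.include_nu = False
            self.include_delta = False

    @property
    def has_gamma_vector(self) -> bool:
        return self.family in ("GROWTH_EXCH", "GROWTH_CAR")

    @property
    def has_beta(self) -> bool:
        return self.family == "ECO_REGRESSION"

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "include_phi": self.include_phi,
            "include_nu": self.include_nu,
            "include_delta": self.include_delta,
            "time_coding": self.time_coding,
            "hyperpriors": asdict(self.hyperpriors),
            "covariate": None if self.covariate is None else self.covariate.name,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict,
                  covariates: list | None = None) -> "ModelSpec":
        d = dict(d)
        hp = HyperPriors(**d.pop("hyperpriors", {}))
        cov_name = d.pop("covariate", None)
        cov = None
        if cov_name is not None:
            lookup = {c.name: c for c in (covariates or [])}
            if cov_name not in lookup:
                raise ValueError(f"covariate {cov_name!r} not supplied")
            cov = lookup[cov_name]
        return cls(hyperpriors=hp, covariate=cov, **d)


@dataclass
class ParameterState:
    """Current values of every latent parameter.

    ``gamma`` is a scalar for GROWTH_UNIFORM and a length-I vector for the
    area-specific growth families; unused components stay at their zero
    defaults.
    """

    alpha: float = 0.0
    phi: np.ndarray | None = None
    nu: np.ndarray | None = None
    delta: np.ndarray | None = None
    gamma: float | np.ndarray = 0.0
    mu_gamma: float = 0.0
    beta: float = 0.0
    tau_phi: float = 100.0
    tau_nu: float = 100.0
    tau_delta: float = 100.0
    tau_gamma: float = 100.0

    @classmethod
    def initial(cls, spec: ModelSpec, n_areas: int, n_years: int) -> "ParameterState":
        st = cls(
            phi=np.zeros(n_areas),
            nu=np.zeros(n_areas),
            delta=np.zeros(n_years),
        )
        if spec.has_gamma_vector:
            st.gamma = np.zeros(n_areas)
        return st

    def validate(self) -> None:
        for name in ("tau_phi", "tau_nu", "tau_delta", "tau_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta is not None and self.delta[0] != 0.0:
            raise ValueError("delta_1 must be 0 (baseline year)")


def time_scores(n_years: int, coding: str) -> np.ndarray:
    """Per-year time covariate for the growth trend.

    raw: t = 1..T as in the trend equation written literally; centered:
    t - (T+1)/2, which decorrelates the growth rate from the intercept
    without changing the per-period growth factor exp(gamma).
    """
    t = np.arange(1, n_years + 1, dtype=float)
    if coding == "centered":
        t = t - t.mean()
    return t


def linear_predictor(state: ParameterState, spec: ModelSpec,
                     n_areas: int, n_years: int) -> np.ndarray:
    """I x T matrix of log relative risks eta_it (offset excluded)."""
    eta = np.full((n_areas, n_years), state.alpha, dtype=float)
    if spec.include_phi and state.phi is not None:
        eta += state.phi[:, None]
    if spec.include_nu and state.nu is not None:
        eta += state.nu[:, None]
    if spec.include_delta and state.delta is not None:
        eta += state.delta[None, :]
    if spec.family in ("GROWTH_UNIFORM", "GROWTH_EXCH", "GROWTH_CAR"):
        t = time_scores(n_years, spec.time_coding)
        g = np.asarray(state.gamma, dtype=float)
        eta += (g[:, None] * t[None, :]) if g.ndim == 1 else g * t[None, :]
    if spec.has_beta:
        eta += state.beta * spec.covariate.values
    return eta


def log_likelihood(state: ParameterState, spec: ModelSpec,
                   panel: AreaYearPanel) -> float:
    """Poisson log-likelihood up to the log(y!) constant.

    sum_it [ y_it * (log e_it + eta_it) - e_it * exp(eta_it) ].  The offset
    term y*log(e) is constant in the parameters and omitted.
    """
    if panel.expected is None:
        raise ValueError("expected counts not computed")
    eta = linear_predictor(state, spec, panel.n_areas, panel.n_years)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    if np.any(eta > ETA_MAX):
        raise FloatingPointError("linear predictor overflow (eta > 50)")
    return float(np.sum(panel.counts * eta - panel.expected * np.exp(eta)))


def log_prior_icar(nu: np.ndarray, tau_nu: float,
                   graph: AdjacencyGraph) -> float:
    """Improper ICAR log-density on the sum-to-zero subspace.

    -(tau/2) * sum_{i~j, i<j} (nu_i - nu_j)^2 + ((I-1)/2) log tau; the
    second term is the normalizing contribution of the rank I-1 precision.
    """
    edges = graph.edge_list()
    if len(edges):
        diffs = nu[edges[:, 0]] - nu[edges[:, 1]]
        pairwise = -0.5 * tau_nu * float(np.sum(diffs ** 2))
    else:
        pairwise = 0.0
    return pairwise + 0.5 * (graph.n_areas - 1) * np.log(tau_nu)


def relative_risk_surface(state: ParameterState, spec: ModelSpec,
                          n_areas: int, n_years: int) -> np.ndarray:
    """rho_it = exp(eta_it): the relative-risk surface without the offset."""
    return np.exp(linear_predictor(state, spec, n_areas, n_years))
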