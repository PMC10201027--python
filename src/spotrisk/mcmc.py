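"""Metropolis-within-Gibbs sampler for the spatio-temporal Poisson models.

Precisions get conjugate Gamma full-conditional (Gibbs) updates and the
exchangeable growth mean a conjugate Normal update; everything else —
intercept, exchangeable effects, ICAR effects, year effects, growth rates
and the covariate slope — moves by adaptive random-walk Metropolis on
scalar components.  Conditionally independent components (the phi_i, the
delta_t, exchangeable gamma_i, and ICAR components within one graph-colour
class) are proposed and accepted in vectorised blocks, which is what makes
the pure-NumPy sampler fast enough for replicate experiments.

Adaptation targets an acceptance rate of ~0.44 per scalar (optimal for
one-dimensional random-walk Metropolis) and is frozen at the end of
burn-in, so the kept draws come from a fixed, valid Markov kernel.  The
ICAR field is recentred to sum to zero after every sweep, with the removed
mean absorbed into the flat intercept — a move that leaves the posterior
density unchanged.

When both spatial effects are present, each sweep ends with an exact Gibbs
reallocation step that shifts mass between the intercept, the exchangeable
field and the ICAR field while keeping their sum (and so the likelihood)
fixed; this decorrelates the two precisions, whose variance split is only
weakly identified and otherwise mixes very slowly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .adjacency import AdjacencyGraph
from .model import ModelSpec, ParameterState, time_scores
from .panel import AreaYearPanel

__all__ = [
    "PosteriorDraws",
    "run_chains",
    "gelman_rubin",
    "tail_probability",
    "summarize",
]

TARGET_ACCEPT = 0.44
QUANTILE_METHOD = "median_unbiased"

_INDEXED = re.compile(r"^(\w+)\[(\d+)\]$")


@dataclass
class PosteriorDraws:
    """Post burn-in parameter trajectories from one or more chains.

    ``params`` maps a parameter name to an array of shape
    (n_chains, n_keep) for scalars or (n_chains, n_keep, dim) for vectors.
    Derived names ``sigma_phi``, ``sigma_nu``, ``sigma_delta``,
    ``sigma_gamma`` (1/sqrt of the stored precisions) are resolved on the
    fly, as are indexed components like ``"phi[3]"``.
    """

    params: dict
    n_burn: int
    n_keep: int
    seeds: list
    spec: ModelSpec
    area_ids: list = field(default_factory=list)
    years: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")
        lengths = {v.shape[:2] for v in self.params.values()}
        if len(lengths) > 1:
            raise ValueError("chains differ in length across parameters")

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    def names(self) -> list:
        return sorted(self.params)

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws for a (possibly derived or indexed) parameter."""
        m = _INDEXED.match(name)
        if m:
            base, idx = m.group(1), int(m.group(2))
            return self.get(base)[:, :, idx]
        if name in self.params:
            return self.params[name]
        if name.startswith("sigma_"):
            tau = "tau_" + name[len("sigma_"):]
            if tau in self.params:
                return self.params[tau] ** -0.5
        raise KeyError(f"unknown parameter {name!r}")

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains (first axis flattened)."""
        x = self.get(name)
        return x.reshape(-1, *x.shape[2:])

    def to_frame(self):
        """Flat pandas frame (chain, iteration, scalar columns)."""
        import pandas as pd

        nc, nk = self.n_chains, self.n_keep
        data = {
            "chain": np.repeat(np.arange(nc), nk),
            "iteration": np.tile(np.arange(nk), nc),
        }
        for name in self.names():
            x = self.params[name]
            if x.ndim == 2:
                data[name] = x.reshape(-1)
            else:
                for j in range(x.shape[2]):
                    data[f"{name}[{j}]"] = x[:, :, j].reshape(-1)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# sampler internals


class _Chain:
    """State, caches and adaptive scales for a single MCMC chain."""

    def __init__(self, spec: ModelSpec, panel: AreaYearPanel,
                 graph: AdjacencyGraph | None, rng: np.random.Generator):
        if panel.expected is None:
            raise ValueError("panel has no expected counts; "
                             "run compute_expected first")
        self.spec = spec
        self.rng = rng
        self.y = panel.counts.astype(float)
        self.e = panel.expected
        self.I, self.T = panel.n_areas, panel.n_years
        self.t = time_scores(self.T, spec.time_coding)
        self.x = spec.covariate.values if spec.has_beta else None
        hp = spec.hyperpriors
        self.a0, self.b0 = hp.precision_shape, hp.precision_rate

        self.use_phi = spec.include_phi
        self.use_nu = spec.include_nu
        self.use_delta = spec.include_delta and self.T > 1
        self.use_gamma = spec.family in ("GROWTH_UNIFORM", "GROWTH_EXCH",
                                         "GROWTH_CAR")
        self.gamma_vector = spec.has_gamma_vector
        self.use_beta = spec.has_beta

        if self.use_nu or spec.family == "GROWTH_CAR":
            if graph is None:
                raise ValueError("this model family requires an adjacency graph")
            if list(map(str, graph.area_ids)) != list(map(str, panel.area_ids)):
                raise ValueError("graph and panel area orderings differ")
            if np.any(graph.n_i == 0):
                raise ValueError("ICAR prior undefined for islands (n_i = 0); "
                                 "drop them or disable the structured effect")
            if not graph.connected:
                raise ValueError("ICAR prior requires a connected graph")
            self.graph = graph
            self.A = graph.adjacency_matrix()
            self.n_i = graph.n_i.astype(float)
            self.edges = graph.edge_list()
            self.colours = graph.colouring()
            if self.use_phi and self.use_nu:
                lam, vecs = np.linalg.eigh(
                    np.asarray(graph.laplacian(), dtype=float))
                keep = lam > 1e-9
                self.lam = lam[keep]
                self.H = vecs[:, keep]

        st = ParameterState.initial(spec, self.I, self.T)
        self.alpha = float(np.log(self.y.sum() / self.e.sum() + 1e-12))
        self.phi = st.phi
        self.nu = st.nu
        self.delta = st.delta
        self.gamma = np.zeros(self.I) if self.gamma_vector else 0.0
        self.u = np.zeros(self.I)  # ICAR deviations for GROWTH_CAR
        self.mu_gamma = 0.0
        self.beta = 0.0
        self.tau_phi = self.tau_nu = self.tau_delta = self.tau_gamma = 100.0

        # log step sizes per scalar component, adapted during burn-in
        self.ls_alpha = np.log(0.1)
        self.ls_phi = np.full(self.I, np.log(0.1))
        self.ls_nu = np.full(self.I, np.log(0.1))
        self.ls_delta = np.full(self.T, np.log(0.1))
        self.ls_gamma = (np.full(self.I, np.log(0.05)) if self.gamma_vector
                         else np.log(0.05))
        self.ls_mu_gamma = np.log(0.05)
        self.ls_beta = np.log(0.05)
        self.adapting = True
        self.sweep = 0

        self.y_rows = self.y.sum(axis=1)
        self.y_cols = self.y.sum(axis=0)
        self.y_tot = self.y.sum()
        self.yt_rows = self.y @ self.t
        if self.use_beta:
            self.yx = float(np.sum(self.y * self.x))
        self._refresh_mu()

    # -- caches ------------------------------------------------------------

    def _eta(self) -> np.ndarray:
        eta = np.full((self.I, self.T), self.alpha)
        if self.use_phi:
            eta += self.phi[:, None]
        if self.use_nu:
            eta += self.nu[:, None]
        if self.use_delta:
            eta += self.delta[None, :]
        if self.use_gamma:
            g = self.gamma if self.gamma_vector else np.full(self.I, self.gamma)
            eta += g[:, None] * self.t[None, :]
        if self.use_beta:
            eta += self.beta * self.x
        return eta

    def _refresh_mu(self) -> None:
        self.mu = self.e * np.exp(self._eta())
        if not np.all(np.isfinite(self.mu)):
            raise FloatingPointError(
                f"non-finite posterior state at sweep {self.sweep}")

    def _adapt_scalar(self, ls: float, accepted: bool) -> float:
        if not self.adapting:
            return ls
        step = min(0.25, 2.0 / np.sqrt(self.sweep + 1.0))
        return ls + step * ((1.0 if accepted else 0.0) - TARGET_ACCEPT)

    def _adapt_vector(self, ls: np.ndarray, idx: np.ndarray,
                      accepted: np.ndarray) -> None:
        if not self.adapting:
            return
        step = min(0.25, 2.0 / np.sqrt(self.sweep + 1.0))
        ls[idx] += step * (accepted.astype(float) - TARGET_ACCEPT)

    # -- block updates -----------------------------------------------------

    def _update_alpha(self) -> None:
        d = np.exp(self.ls_alpha) * self.rng.standard_normal()
        dll = self.y_tot * d - np.expm1(d) * self.mu.sum()
        acc = np.log(self.rng.uniform()) < dll  # flat prior on alpha
        if acc:
            self.alpha += d
            self.mu *= np.exp(d)
        self.ls_alpha = self._adapt_scalar(self.ls_alpha, acc)

    def _row_block(self, values: np.ndarray, ls: np.ndarray,
                   idx: np.ndarray, dlp_fn) -> None:
        """Vectorised per-area update adding d_i to every cell of row i."""
        d = np.exp(ls[idx]) * self.rng.standard_normal(len(idx))
        mu_rows = self.mu[idx].sum(axis=1)
        dll = self.y_rows[idx] * d - np.expm1(d) * mu_rows
        dlp = dlp_fn(d)
        acc = np.log(self.rng.uniform(size=len(idx))) < dll + dlp
        if acc.any():
            sel = idx[acc]
            values[sel] += d[acc]
            self.mu[sel] *= np.exp(d[acc])[:, None]
        self._adapt_vector(ls, idx, acc)

    def _update_phi(self) -> None:
        idx = np.arange(self.I)

        def dlp(d):
            p = self.phi[idx]
            return -0.5 * self.tau_phi * ((p + d) ** 2 - p ** 2)

        self._row_block(self.phi, self.ls_phi, idx, dlp)

    def _update_nu(self) -> None:
        for idx in self.colours:
            S = np.asarray(self.A[idx] @ self.nu).ravel()

            def dlp(d, idx=idx, S=S):
                v = self.nu[idx]
                return -0.5 * self.tau_nu * (
                    self.n_i[idx] * ((v + d) ** 2 - v ** 2) - 2.0 * d * S)

            self._row_block(self.nu, self.ls_nu, idx, dlp)
        # recentre; the flat intercept absorbs the mean, posterior unchanged
        m = self.nu.mean()
        self.nu -= m
        self.alpha += m

    def _update_delta(self) -> None:
        d = np.zeros(self.T)
        d[1:] = np.exp(self.ls_delta[1:]) * self.rng.standard_normal(self.T - 1)
        mu_cols = self.mu.sum(axis=0)
        dll = self.y_cols[1:] * d[1:] - np.expm1(d[1:]) * mu_cols[1:]
        dl = self.delta[1:]
        dlp = -0.5 * self.tau_delta * ((dl + d[1:]) ** 2 - dl ** 2)
        acc = np.log(self.rng.uniform(size=self.T - 1)) < dll + dlp
        if acc.any():
            cols = np.flatnonzero(acc) + 1
            self.delta[cols] += d[cols]
            self.mu[:, cols] *= np.exp(d[cols])[None, :]
        self._adapt_vector(self.ls_delta, np.arange(1, self.T), acc)

    def _update_gamma_scalar(self) -> None:
        d = np.exp(self.ls_gamma) * self.rng.standard_normal()
        grow = np.expm1(d * self.t)
        dll = d * self.yt_rows.sum() - float(np.sum(self.mu * grow[None, :]))
        g = self.gamma
        dlp = -0.5 * self.tau_gamma * ((g + d) ** 2 - g ** 2)
        acc = np.log(self.rng.uniform()) < dll + dlp
        if acc:
            self.gamma += d
            self.mu *= np.exp(d * self.t)[None, :]
        self.ls_gamma = self._adapt_scalar(self.ls_gamma, acc)

    def _gamma_row_block(self, idx: np.ndarray, d: np.ndarray,
                         dlp: np.ndarray) -> np.ndarray:
        """Accept/reject per-area growth proposals gamma_i += d_i."""
        grow = np.expm1(np.outer(d, self.t))
        dll = d * self.yt_rows[idx] - np.sum(self.mu[idx] * grow, axis=1)
        acc = np.log(self.rng.uniform(size=len(idx))) < dll + dlp
        if acc.any():
            sel = idx[acc]
            self.gamma[sel] += d[acc]
            self.mu[sel] *= np.exp(np.outer(d[acc], self.t))
        return acc

    def _update_gamma_exch(self) -> None:
        idx = np.arange(self.I)
        d = np.exp(self.ls_gamma) * self.rng.standard_normal(self.I)
        g = self.gamma - self.mu_gamma
        dlp = -0.5 * self.tau_gamma * ((g + d) ** 2 - g ** 2)
        acc = self._gamma_row_block(idx, d, dlp)
        self._adapt_vector(self.ls_gamma, idx, acc)
        # conjugate Normal update for the overall growth mean
        hp = self.spec.hyperpriors
        prior_prec = hp.mu_gamma_prior_sd ** -2
        prec = prior_prec + self.I * self.tau_gamma
        mean = (hp.mu_gamma_prior_mean * prior_prec
                + self.tau_gamma * self.gamma.sum()) / prec
        self.mu_gamma = mean + self.rng.standard_normal() / np.sqrt(prec)

    def _update_gamma_car(self) -> None:
        # gamma_i = mu_gamma + u_i with ICAR(u); pairwise prior terms depend
        # only on differences, so deltas mirror the nu update
        for idx in self.colours:
            S = np.asarray(self.A[idx] @ self.gamma).ravel()
            d = np.exp(self.ls_gamma[idx]) * self.rng.standard_normal(len(idx))
            g = self.gamma[idx]
            dlp = -0.5 * self.tau_gamma * (
                self.n_i[idx] * ((g + d) ** 2 - g ** 2) - 2.0 * d * S)
            acc = self._gamma_row_block(idx, d, dlp)
            self._adapt_vector(self.ls_gamma, idx, acc)
        # recentring move: shift the deviation mean into mu_gamma; gamma_i
        # (hence the likelihood and the ICAR prior) is unchanged, so only
        # the mu_gamma prior enters the Metropolis ratio
        hp = self.spec.hyperpriors
        m = self.gamma.mean() - self.mu_gamma
        sd0, m0 = hp.mu_gamma_prior_sd, hp.mu_gamma_prior_mean
        new = self.mu_gamma + m
        dlp = -0.5 * ((new - m0) ** 2 - (self.mu_gamma - m0) ** 2) / sd0 ** 2
        if np.log(self.rng.uniform()) < dlp:
            self.mu_gamma = new
        self.u = self.gamma - self.mu_gamma
        # random-walk move for mu_gamma along the likelihood ridge
        d = np.exp(self.ls_mu_gamma) * self.rng.standard_normal()
        grow = np.expm1(d * self.t)
        dll = d * self.yt_rows.sum() - float(np.sum(self.mu * grow[None, :]))
        dlp = -0.5 * (((self.mu_gamma + d) - m0) ** 2
                      - (self.mu_gamma - m0) ** 2) / sd0 ** 2
        acc = np.log(self.rng.uniform()) < dll + dlp
        if acc:
            self.mu_gamma += d
            self.gamma = self.gamma + d
            self.mu *= np.exp(d * self.t)[None, :]
        self.ls_mu_gamma = self._adapt_scalar(self.ls_mu_gamma, acc)

    def _update_beta(self) -> None:
        d = np.exp(self.ls_beta) * self.rng.standard_normal()
        dll = d * self.yx - float(np.sum(self.mu * np.expm1(d * self.x)))
        sd = self.spec.hyperpriors.slope_prior_sd
        b = self.beta
        dlp = -0.5 * ((b + d) ** 2 - b ** 2) / sd ** 2
        acc = np.log(self.rng.uniform()) < dll + dlp
        if acc:
            self.beta += d
            self.mu *= np.exp(d * self.x)
        self.ls_beta = self._adapt_scalar(self.ls_beta, acc)

    def _reallocate(self) -> None:
        """Gibbs swaps that leave the linear predictor (hence the
        likelihood and the mu cache) fixed.

        The posterior is flat along the directions where a shift of one
        effect can be offset by another: the intercept against the mean of
        phi, and phi against nu componentwise in the Laplacian eigenbasis.
        Componentwise Metropolis crawls along these ridges, which makes the
        variance split between tau_phi and tau_nu mix very slowly; here the
        full conditional of the shift is Gaussian, so it can be drawn
        exactly and accepted always.
        """
        if self.use_phi:
            # alpha' = alpha + m, phi' = phi - m: flat prior on alpha, so
            # m | rest ~ N(mean(phi), 1 / (I * tau_phi))
            m = self.phi.mean() + (self.rng.standard_normal()
                                   / np.sqrt(self.I * self.tau_phi))
            self.phi -= m
            self.alpha += m
        if self.use_phi and self.use_nu:
            # phi' = phi + H c, nu' = nu - H c with H the non-null Laplacian
            # eigenvectors; the conditional of c separates coordinatewise
            prec = self.tau_phi + self.tau_nu * self.lam
            mean = (self.tau_nu * self.lam * (self.H.T @ self.nu)
                    - self.tau_phi * (self.H.T @ self.phi)) / prec
            c = mean + self.rng.standard_normal(len(prec)) / np.sqrt(prec)
            shift = self.H @ c
            self.phi += shift
            self.nu -= shift

    def _update_precisions(self) -> None:
        a0, b0 = self.a0, self.b0
        g = self.rng.gamma
        if self.use_phi:
            self.tau_phi = g(a0 + 0.5 * self.I,
                             1.0 / (b0 + 0.5 * float(self.phi @ self.phi)))
        if self.use_nu:
            diffs = self.nu[self.edges[:, 0]] - self.nu[self.edges[:, 1]]
            self.tau_nu = g(a0 + 0.5 * (self.I - 1),
                            1.0 / (b0 + 0.5 * float(diffs @ diffs)))
        if self.use_delta:
            ss = float(self.delta[1:] @ self.delta[1:])
            self.tau_delta = g(a0 + 0.5 * (self.T - 1), 1.0 / (b0 + 0.5 * ss))
        if self.use_gamma:
            if self.spec.family == "GROWTH_UNIFORM":
                ss, dof = self.gamma ** 2, 1
            elif self.spec.family == "GROWTH_EXCH":
                dev = self.gamma - self.mu_gamma
                ss, dof = float(dev @ dev), self.I
            else:  # GROWTH_CAR
                dev = self.gamma
                diffs = dev[self.edges[:, 0]] - dev[self.edges[:, 1]]
                ss, dof = float(diffs @ diffs), self.I - 1
            self.tau_gamma = g(a0 + 0.5 * dof, 1.0 / (b0 + 0.5 * ss))

    # -- driver ------------------------------------------------------------

    def run_sweep(self) -> None:
        self._update_alpha()
        if self.use_phi:
            self._update_phi()
        if self.use_nu:
            self._update_nu()
        if self.use_delta:
            self._update_delta()
        if self.use_gamma:
            if self.spec.family == "GROWTH_UNIFORM":
                self._update_gamma_scalar()
            elif self.spec.family == "GROWTH_EXCH":
                self._update_gamma_exch()
            else:
                self._update_gamma_car()
        if self.use_beta:
            self._update_beta()
        self._reallocate()
        self._update_precisions()
        self.sweep += 1
        if self.sweep % 200 == 0:
            self._refresh_mu()  # clear accumulated multiplicative error

    def monitored(self) -> dict:
        out = {"alpha": self.alpha}
        if self.use_phi:
            out["phi"] = self.phi.copy()
            out["tau_phi"] = self.tau_phi
        if self.use_nu:
            out["nu"] = self.nu.copy()
            out["tau_nu"] = self.tau_nu
        if self.use_delta:
            out["delta"] = self.delta.copy()
            out["tau_delta"] = self.tau_delta
        if self.use_gamma:
            out["gamma"] = (self.gamma.copy() if self.gamma_vector
                            else self.gamma)
            out["tau_gamma"] = self.tau_gamma
            if self.gamma_vector:
                out["mu_gamma"] = self.mu_gamma
        if self.use_beta:
            out["beta"] = self.beta
        return out


def run_chains(spec: ModelSpec, panel: AreaYearPanel,
               graph: AdjacencyGraph | None = None, n_chains: int = 2,
               n_burn: int = 1000, n_keep: int = 10000,
               seed: int = 0) -> PosteriorDraws:
    """Sample the posterior of ``spec`` on ``panel``.

    Defaults follow the 1,000 burn-in / 10,000 production-run protocol with
    two chains for convergence diagnostics.  Per-chain seeds are spawned
    deterministically from ``seed``; identical inputs give identical draws.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_keep < 1 or n_burn < 0:
        raise ValueError("invalid chain lengths")
    ss = np.random.SeedSequence(seed)
    child_seqs = ss.spawn(n_chains)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in child_seqs]

    store: dict[str, list] = {}
    for c, seq in enumerate(child_seqs):
        rng = np.random.default_rng(seq)
        chain = _Chain(spec, panel, graph, rng)
        for _ in range(n_burn):
            chain.run_sweep()
        chain.adapting = False
        first = chain.monitored()
        if c == 0:
            for name, val in first.items():
                dim = () if np.isscalar(val) else np.shape(val)
                store[name] = [np.empty((n_chains, n_keep) + dim)]
        for k in range(n_keep):
            chain.run_sweep()
            for name, val in chain.monitored().items():
                store[name][0][c, k] = val
    params = {name: arrs[0] for name, arrs in store.items()}
    return PosteriorDraws(params, n_burn, n_keep, seeds, spec,
                          list(panel.area_ids), list(panel.years))


# --------------------------------------------------------------------------
# diagnostics and summaries


def gelman_rubin(draws: PosteriorDraws, param: str) -> float:
    """Potential scale reduction factor (PSRF) for one scalar parameter.

    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B/n the variance of the chain means; values near 1 indicate the chains
    have mixed.
    """
    x = draws.get(param)
    if x.ndim != 2:
        raise ValueError(f"{param!r} is vector-valued; index a component, "
                         f"e.g. '{param}[0]'")
    m, n = x.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin needs at least 10 kept iterations")
    means = x.mean(axis=1)
    w = float(np.mean(x.var(axis=1, ddof=1)))
    if w == 0:
        raise ValueError("degenerate chains (zero within-chain variance)")
    b_over_n = float(np.var(means, ddof=1))
    v_hat = (n - 1) / n * w + b_over_n
    # estimation noise can push the ratio a hair under 1; floor it there
    return float(max(1.0, np.sqrt(v_hat / w)))


def max_psrf(draws: PosteriorDraws, params: list | None = None) -> float:
    """Largest PSRF over the given (or all scalar-expanded) parameters."""
    if params is None:
        params = []
        for name in draws.names():
            x = draws.params[name]
            if x.ndim == 2:
                params.append(name)
            else:
                params.extend(f"{name}[{j}]" for j in range(x.shape[2]))
    return max(gelman_rubin(draws, p) for p in params)


def tail_probability(draws: PosteriorDraws, param: str, threshold: float = 0.0,
                     side: str = "greater") -> float:
    """Fraction of pooled draws beyond ``threshold`` (a one-sided
    posterior probability, the Monte-Carlo analogue of BUGS's step()).

    Ties at the threshold count as "greater", matching step(x) = 1 at
    x = 0; ``side="less"`` therefore returns the strict complement.
    """
    x = draws.pooled(param)
    if x.ndim != 1:
        raise ValueError("tail_probability needs a scalar parameter")
    p_greater = float(np.mean(x >= threshold))
    if side == "greater":
        return p_greater
    if side == "less":
        return 1.0 - p_greater
    raise ValueError("side must be 'greater' or 'less'")


def summarize(draws: PosteriorDraws, param: str) -> dict:
    """Pooled posterior mean, sd and central 95% interval + median.

    Quantiles use the median-unbiased empirical rule.
    """
    x = draws.pooled(param)
    if x.ndim != 1:
        raise ValueError("summarize needs a scalar parameter")
    q = np.quantile(x, [0.025, 0.5, 0.975], method=QUANTILE_METHOD)
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "q2.5": float(q[0]),
        "q50": float(q[1]),
        "q97.5": float(q[2]),
    }
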