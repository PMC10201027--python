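"""Ecological-regression screen over many area-level covariates.

Each covariate is fitted one-at-a-time in the spatio-temporal model
log mu_it = log e_it + alpha + beta * x_it + phi_i + nu_i + delta_t, and its
slope is tested with a one-sided posterior tail probability
p* = min{P(beta > 0), P(beta < 0)} against a Bonferroni-corrected
threshold alpha_level / m (m = number of covariates screened).  A result
only counts as significant when the fit's convergence diagnostic also
passes (max PSRF < 1.1 over the monitored scalars).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjacency import AdjacencyGraph
from .mcmc import run_chains, gelman_rubin, tail_probability, summarize
from .model import HyperPriors, ModelSpec
from .panel import AreaYearPanel

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "screen", "format_table"]

PSRF_LIMIT = 1.1


@dataclass
class ScreenResult:
    """Posterior summary of one covariate's slope."""

    name: str
    beta_mean: float
    beta_q2_5: float
    beta_q97_5: float
    p_star: float
    threshold: float
    significant: bool
    max_psrf: float

    @property
    def converged(self) -> bool:
        return self.max_psrf < PSRF_LIMIT


def screen(panel: AreaYearPanel, graph: AdjacencyGraph, covariates: list,
           n_chains: int = 2, n_burn: int = 1000, n_keep: int = 10000,
           seed: int = 0, alpha_level: float = 0.05,
           hyperpriors: HyperPriors | None = None,
           n_tests: int | None = None) -> list:
    """Fit one ecological regression per covariate and apply the corrected
    one-sided test.

    ``n_tests`` overrides the Bonferroni divisor (defaults to the number of
    covariates actually screened).  Zero-variance covariates are skipped
    with a warning.  Results are sorted ascending by p*.
    """
    if not covariates:
        raise ValueError("need at least one covariate")
    usable = []
    for cov in covariates:
        if np.ptp(cov.values) == 0:
            logger.warning("covariate %r has zero variance; skipped", cov.name)
            continue
        if cov.values.shape != (panel.n_areas, panel.n_years):
            raise ValueError(f"covariate {cov.name!r} not aligned to panel")
        usable.append(cov)
    m = n_tests if n_tests is not None else len(usable)
    threshold = alpha_level / m if m else alpha_level
    results = []
    for k, cov in enumerate(usable):
        spec = ModelSpec(family="ECO_REGRESSION", covariate=cov,
                         hyperpriors=hyperpriors or HyperPriors())
        draws = run_chains(spec, panel, graph, n_chains=n_chains,
                           n_burn=n_burn, n_keep=n_keep,
                           seed=(seed + k) % (2 ** 31))
        summ = summarize(draws, "beta")
        p_gt = tail_probability(draws, "beta", 0.0, "greater")
        p_star = min(p_gt, 1.0 - p_gt)
        monitored = ["alpha", "beta", "tau_phi", "tau_nu", "tau_delta"]
        psrf = max(gelman_rubin(draws, p) for p in monitored) \
            if n_chains >= 2 else float("nan")
        converged = psrf < PSRF_LIMIT if n_chains >= 2 else True
        results.append(ScreenResult(
            name=cov.name,
            beta_mean=summ["mean"],
            beta_q2_5=summ["q2.5"],
            beta_q97_5=summ["q97.5"],
            p_star=p_star,
            threshold=threshold,
            significant=bool(p_star < threshold and converged),
            max_psrf=psrf,
        ))
    results.sort(key=lambda r: (r.p_star, r.name))
    return results


def format_table(results: list, significant_only: bool = True,
                 markdown: bool = False) -> str:
    """Render screen results as a risk-factor table.

    Columns: risk factor, posterior slope, 95% credible interval.  By
    default only rows passing the corrected test are shown.
    """
    rows = [r for r in results if r.significant] if significant_only else results
    header = ["Risk factor", "Regr. coeff. (beta)", "95%CI"]
    body = [[r.name, f"{r.beta_mean:.3f}",
             f"({r.beta_q2_5:.3f}, {r.beta_q97_5:.3f})"] for r in rows]
    if markdown:
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join("---" for _ in header) + "|"]
        lines += ["| " + " | ".join(r) + " |" for r in body]
        return "\n".join(lines)
    widths = [max(len(h), *(len(r[i]) for r in body)) if body else len(h)
              for i, h in enumerate(header)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    lines += ["  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in body]
    return "\n".join(lines)


def results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
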