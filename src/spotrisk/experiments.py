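"""Canned validation experiments for the sampler and the spot pipeline.

These encode, once, the study conditions used to validate the package:
a conjugate single-cell oracle with a closed-form posterior, an ICAR
sampling check against the Laplacian pseudo-inverse, a replicated
parameter-recovery experiment on a 6x6 lattice, a planted cold-/hot-spot
detection run at 100 areas, and a family-wise error check for the
Bonferroni-corrected covariate screen.  Both the test suite and the
reproduction script call these functions so the reported numbers always
come from the same procedure.
"""

from __future__ import annotations

import numpy as np

from .adjacency import AdjacencyGraph
from .mcmc import run_chains, summarize
from .model import ModelSpec
from .panel import AreaYearPanel
from .screen import screen
from .simulate import SimulationConfig, make_lattice, sample_icar, simulate_panel
from .spots import overlay

__all__ = [
    "conjugate_oracle",
    "icar_covariance_check",
    "recovery_experiment",
    "planted_cluster_experiment",
    "noise_screen_experiment",
]


def _batch_se(x: np.ndarray, n_batches: int = 50) -> float:
    x = np.asarray(x).ravel()
    n = (len(x) // n_batches) * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def conjugate_oracle(seed: int = 0, n_burn: int = 1000,
                     n_keep: int = 10_000) -> dict:
    """Single area, single year, intercept only, y=4, e=2.

    A flat prior on alpha is a 1/lambda prior on lambda = exp(alpha), so the
    exact posterior is Gamma(4, 2) with mean 2.  Returns the sampled
    posterior mean of exp(alpha) and its batch-means Monte-Carlo SE.
    """
    panel = AreaYearPanel(["a"], [2015], np.array([[4]]),
                          np.array([[100.0]]), np.array([[2.0]]))
    spec = ModelSpec(family="RR_SPACE_TIME", include_phi=False,
                     include_nu=False, include_delta=False)
    draws = run_chains(spec, panel, None, n_chains=2, n_burn=n_burn,
                       n_keep=n_keep, seed=seed)
    rr = np.exp(draws.pooled("alpha"))
    return {"mean": float(rr.mean()), "se": _batch_se(rr),
            "exact": 2.0, "n": rr.size}


def icar_covariance_check(seed: int = 0, n_draws: int = 100_000) -> dict:
    """Empirical covariance of ICAR draws on a 3-node path graph versus the
    Laplacian pseudo-inverse, as a max |z| over matrix entries."""
    graph = AdjacencyGraph.from_edges(["a", "b", "c"],
                                      [("a", "b"), ("b", "c")])
    draws = sample_icar(graph, 1.0, seed=seed, size=n_draws)
    target = np.linalg.pinv(graph.laplacian())
    emp = (draws.T @ draws) / n_draws
    se = np.sqrt((np.outer(np.diag(target), np.diag(target)) + target ** 2)
                 / n_draws)
    z = np.abs(emp - target) / se
    return {"max_abs_z": float(z.max()), "n": n_draws}


RECOVERY_TRUTH = {"alpha": 0.0, "sigma_phi": 0.2, "sigma_nu": 0.3,
                  "sigma_delta": 0.1}


def recovery_experiment(seed: int = 0, n_reps: int = 20, n_burn: int = 500,
                        n_keep: int = 2500) -> dict:
    """Replicated recovery of (alpha, sigma_phi, sigma_nu, sigma_delta) on a
    6x6 lattice with 5 years and expected counts of about 250 per cell.

    Returns, per parameter, how many replicate 95% credible intervals cover
    the generating value.
    """
    graph = make_lattice(6, 6, "rook")
    cover = {k: 0 for k in RECOVERY_TRUTH}
    for rep in range(n_reps):
        cfg = SimulationConfig(graph=graph, n_years=5, base_rate=0.025,
                               pop_range=(10_000.0, 10_000.0),
                               alpha=RECOVERY_TRUTH["alpha"],
                               sigma_phi=RECOVERY_TRUTH["sigma_phi"],
                               sigma_nu=RECOVERY_TRUTH["sigma_nu"],
                               sigma_delta=RECOVERY_TRUTH["sigma_delta"],
                               seed=(seed + 17 * rep) % (2 ** 31))
        panel, _, _ = simulate_panel(cfg)
        draws = run_chains(ModelSpec(family="RR_SPACE_TIME"), panel, graph,
                           n_chains=2, n_burn=n_burn, n_keep=n_keep,
                           seed=(seed + 31 * rep + 7) % (2 ** 31))
        for param, truth in RECOVERY_TRUTH.items():
            s = summarize(draws, param)
            cover[param] += int(s["q2.5"] <= truth <= s["q97.5"])
    return {"coverage": cover, "n_reps": n_reps}


def planted_cluster_experiment(seed: int = 0, n_burn: int = 500,
                               n_keep: int = 2500) -> dict:
    """Plant a 3x3 hot block (+0.5 on both nu and gamma) and a 3x3 cold
    block (-0.5 on both) in a 10x10 lattice and check the overlay recovers
    them.

    Null areas carry only mild unstructured noise, so under the 95%-interval
    rule no null area is expected to come out "hot".
    """
    graph = make_lattice(10, 10, "rook")
    n_areas = graph.n_areas
    hot = [r * 10 + c for r in range(3) for c in range(3)]
    cold = [r * 10 + c for r in range(7, 10) for c in range(7, 10)]
    nu_off = np.zeros(n_areas)
    gam_off = np.zeros(n_areas)
    nu_off[hot], nu_off[cold] = 0.5, -0.5
    gam_off[hot], gam_off[cold] = 0.5, -0.5
    cfg = SimulationConfig(graph=graph, n_years=5, base_rate=0.025,
                           pop_range=(10_000.0, 10_000.0), alpha=0.0,
                           sigma_phi=0.05, sigma_nu=0.0, sigma_delta=0.05,
                           include_growth=True, sigma_gamma=0.0,
                           mu_gamma=0.0, nu_offset=nu_off,
                           gamma_offset=gam_off, seed=seed)
    panel, _, _ = simulate_panel(cfg)
    rr = run_chains(ModelSpec(family="RR_SPACE_TIME"), panel, graph,
                    n_chains=2, n_burn=n_burn, n_keep=n_keep,
                    seed=(seed + 1) % (2 ** 31))
    gr = run_chains(ModelSpec(family="GROWTH_EXCH"), panel, graph,
                    n_chains=2, n_burn=n_burn, n_keep=n_keep,
                    seed=(seed + 2) % (2 ** 31))
    spots = overlay(rr, gr)
    labels = np.array(spots.overlap)
    found_hot = set(np.flatnonzero(labels == "hot").tolist())
    found_cold = set(np.flatnonzero(labels == "cold").tolist())
    hits = len(found_hot & set(hot)) + len(found_cold & set(cold))
    return {
        "sensitivity": hits / (len(hot) + len(cold)),
        "false_hot": len(found_hot - set(hot)),
        "false_cold": len(found_cold - set(cold)),
        "n_areas": n_areas,
    }


def noise_screen_experiment(seed: int = 0, n_reps: int = 100,
                            n_burn: int = 300, n_keep: int = 1000) -> dict:
    """Family-wise error of the 64-way Bonferroni gate on pure noise.

    Each replicate simulates a null panel on a 6x6 lattice with one
    standard-normal noise covariate and screens it against the 0.05/64
    threshold; the fraction of replicates flagged significant estimates the
    per-test family-wise error contribution.
    """
    graph = make_lattice(6, 6, "rook")
    flagged = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(graph=graph, n_years=5, base_rate=0.025,
                               pop_range=(10_000.0, 10_000.0),
                               sigma_phi=0.1, sigma_nu=0.1, sigma_delta=0.05,
                               n_covariates=1, covariate_sd=1.0, beta=0.0,
                               seed=(seed + 101 * rep) % (2 ** 31))
        panel, covs, _ = simulate_panel(cfg)
        results = screen(panel, graph, covs, n_chains=2, n_burn=n_burn,
                         n_keep=n_keep,
                         seed=(seed + 13 * rep + 3) % (2 ** 31),
                         n_tests=64)
        flagged += int(results[0].significant)
    return {"false_positive_rate": flagged / n_reps,
            "threshold": 0.05 / 64, "n_reps": n_reps}
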