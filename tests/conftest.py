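import numpy as np
import pytest

from spotrisk import (AreaYearPanel, SimulationConfig, compute_expected,
                      make_lattice, simulate_panel)


def batch_mean_se(x: np.ndarray, n_batches: int = 50) -> float:
    """Monte-Carlo standard error of the mean of a (possibly autocorrelated)
    draw sequence, by non-overlapping batch means."""
    x = np.asarray(x).ravel()
    n = (len(x) // n_batches) * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


@pytest.fixture
def lattice3():
    return make_lattice(3, 3, "rook")


@pytest.fixture
def small_panel():
    """Deterministic 2-area x 2-year panel with expected counts filled."""
    panel = AreaYearPanel(["a", "b"], [2015, 2016],
                          np.array([[3, 4], [0, 1]]),
                          np.array([[100.0, 100.0], [50.0, 50.0]]))
    return compute_expected(panel)


@pytest.fixture
def simulated_fit_inputs():
    """A 6x6 lattice panel with mild spatial structure, plus its truth."""
    graph = make_lattice(6, 6, "rook")
    cfg = SimulationConfig(graph=graph, n_years=5, base_rate=0.025,
                           pop_range=(10_000.0, 10_000.0), alpha=0.0,
                           sigma_phi=0.1, sigma_nu=0.2, sigma_delta=0.05,
                           seed=42)
    panel, covs, truth = simulate_panel(cfg)
    return graph, panel, truth
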