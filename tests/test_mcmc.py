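import numpy as np
import pytest

from conftest import batch_mean_se
from spotrisk import (AreaYearPanel, HyperPriors, ModelSpec, PosteriorDraws,
                      compute_expected, gelman_rubin, run_chains, summarize,
                      tail_probability)


def single_cell_panel(y=4, e=2.0):
    return AreaYearPanel(["a"], [2015], np.array([[y]]),
                         np.array([[100.0]]), np.array([[float(e)]]))


def intercept_spec(**kw):
    return ModelSpec(family="RR_SPACE_TIME", include_phi=False,
                     include_nu=False, include_delta=False, **kw)


def fake_draws(arrays: dict, spec=None) -> PosteriorDraws:
    spec = spec or intercept_spec()
    params = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
    n_keep = next(iter(params.values())).shape[1]
    return PosteriorDraws(params, n_burn=0, n_keep=n_keep, seeds=[0],
                          spec=spec)


class TestConjugateOracle:
    def test_flat_alpha_poisson_matches_gamma(self):
        # with a flat prior on alpha the induced prior on lambda = exp(alpha)
        # is 1/lambda, so the posterior for y=4, e=2 is Gamma(4, 2): mean 2
        draws = run_chains(intercept_spec(), single_cell_panel(), None,
                           n_chains=2, n_burn=500, n_keep=4000, seed=12)
        rr = np.exp(draws.pooled("alpha"))
        se = batch_mean_se(rr)
        assert abs(rr.mean() - 2.0) <= 3 * se
        # Gamma(4,2) sd is 1; loose sanity check on spread
        assert rr.std() == pytest.approx(1.0, rel=0.15)


class TestDeterminism:
    def test_identical_seeds_identical_chains(self, simulated_fit_inputs):
        graph, panel, _ = simulated_fit_inputs
        spec = ModelSpec(family="RR_SPACE_TIME")
        d1 = run_chains(spec, panel, graph, n_chains=2, n_burn=50,
                        n_keep=100, seed=77)
        d2 = run_chains(spec, panel, graph, n_chains=2, n_burn=50,
                        n_keep=100, seed=77)
        for name in d1.names():
            assert np.array_equal(d1.params[name], d2.params[name])


class TestShrinkageLimit:
    def test_degenerate_variances_collapse_to_pooled_smr(self):
        # enormous, tightly pinned precisions force phi, nu, delta to zero,
        # so the posterior RR collapses to the pooled SMR
        rng = np.random.default_rng(8)
        counts = rng.poisson(30.0, size=(4, 3))
        from spotrisk import make_lattice
        graph = make_lattice(2, 2, "rook")
        panel = compute_expected(AreaYearPanel(
            list(graph.area_ids), [2015, 2016, 2017], counts,
            np.full((4, 3), 1000.0)))
        hp = HyperPriors(precision_shape=1e8, precision_rate=1e2)
        spec = ModelSpec(family="RR_SPACE_TIME", hyperpriors=hp)
        draws = run_chains(spec, panel, graph, n_chains=1, n_burn=400,
                           n_keep=2000, seed=5)
        assert np.abs(draws.pooled("phi")).max() < 0.01
        assert np.abs(draws.pooled("nu")).max() < 0.01
        rr = np.exp(draws.pooled("alpha"))
        pooled_smr = panel.counts.sum() / panel.expected.sum()
        assert rr.mean() == pytest.approx(pooled_smr, abs=0.03)


class TestGridOracle:
    def test_two_parameter_posterior_matches_grid_integration(self):
        # intercept + one year effect with its precision pinned at 1: the
        # exact posterior is computable by dense 2-d quadrature
        y = np.array([[5, 7]])
        e = np.array([[4.0, 6.0]])
        panel = AreaYearPanel(["a"], [2015, 2016], y,
                              np.full((1, 2), 100.0), e)
        hp = HyperPriors(precision_shape=1e8, precision_rate=1e8)
        spec = ModelSpec(family="RR_SPACE_TIME", include_phi=False,
                         include_nu=False, include_delta=True,
                         hyperpriors=hp)
        draws = run_chains(spec, panel, None, n_chains=2, n_burn=1000,
                           n_keep=150_000, seed=21)
        alpha = draws.pooled("alpha")
        delta2 = draws.pooled("delta")[:, 1]

        lo, hi, nbin = -2.0, 2.0, 100
        grid = np.linspace(lo, hi, 801)
        aa, dd = np.meshgrid(grid, grid, indexing="ij")
        logp = (5 * aa - 4 * np.exp(aa) + 7 * (aa + dd)
                - 6 * np.exp(aa + dd) - 0.5 * dd ** 2)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        edges = np.linspace(lo, hi, nbin + 1)
        idx = np.clip(np.searchsorted(edges, grid, side="right") - 1,
                      0, nbin - 1)
        for sample, axis in ((alpha, 0), (delta2, 1)):
            marg = p.sum(axis=1 - axis)
            exact = np.bincount(idx, weights=marg, minlength=nbin)
            hist, _ = np.histogram(np.clip(sample, lo, hi - 1e-9),
                                   bins=edges)
            tv = 0.5 * np.abs(hist / hist.sum() - exact).sum()
            assert tv < 0.02


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 5000))
        d = fake_draws({"alpha": x})
        assert 1.0 <= gelman_rubin(d, "alpha") <= 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(4)
        x = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(fake_draws({"alpha": x}), "alpha") > 5.0

    def test_single_chain_rejected(self):
        x = np.random.default_rng(0).normal(size=(1, 100))
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(fake_draws({"alpha": x}), "alpha")

    def test_degenerate_chains_rejected(self):
        x = np.ones((2, 100))
        with pytest.raises(ValueError, match="degenerate"):
            gelman_rubin(fake_draws({"alpha": x}), "alpha")

    def test_vector_component_indexing(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 500, 3))
        d = fake_draws({"phi": x})
        assert gelman_rubin(d, "phi[1]") < 1.2
        with pytest.raises(ValueError, match="component"):
            gelman_rubin(d, "phi")


class TestTailProbability:
    def test_counting_rule(self):
        x = np.array([[0.1, -0.2, 0.3, 0.4]])
        d = fake_draws({"beta": x})
        assert tail_probability(d, "beta", 0.0, "greater") == 0.75

    def test_all_above(self):
        d = fake_draws({"beta": np.array([[1.0, 2.0, 3.0]])})
        assert tail_probability(d, "beta", 0.0, "greater") == 1.0

    def test_ties_count_as_greater(self):
        d = fake_draws({"beta": np.array([[0.0, 1.0, -1.0, -1.0]])})
        assert tail_probability(d, "beta", 0.0, "greater") == 0.5
        assert tail_probability(d, "beta", 0.0, "less") == 0.5


class TestSummarize:
    def test_constant_draws(self):
        d = fake_draws({"beta": np.full((1, 10), 3.5)})
        s = summarize(d, "beta")
        assert s["mean"] == 3.5 and s["sd"] == 0.0
        assert s["q2.5"] == s["q97.5"] == 3.5

    def test_quantile_rule_on_1_to_100(self):
        # median-unbiased empirical rule: h = (n + 1/3) p + 1/3
        d = fake_draws({"beta": np.arange(1.0, 101.0).reshape(1, 100)})
        s = summarize(d, "beta")
        assert s["q2.5"] == pytest.approx((100 + 1 / 3) * 0.025 + 1 / 3)
        assert s["q97.5"] == pytest.approx((100 + 1 / 3) * 0.975 + 1 / 3)
        assert s["q50"] == pytest.approx(50.5)

    def test_symmetric_draws_mean_near_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(2, 4000))
        s = summarize(fake_draws({"alpha": x}), "alpha")
        assert abs(s["mean"]) < 3 * s["sd"] / np.sqrt(x.size)


class TestDerivedNames:
    def test_sigma_is_inverse_sqrt_precision(self):
        d = fake_draws({"tau_phi": np.array([[4.0, 25.0]])})
        assert np.allclose(d.pooled("sigma_phi"), [0.5, 0.2])
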