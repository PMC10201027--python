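import json

import numpy as np
import pytest

from spotrisk import (AreaYearPanel, ModelSpec, PosteriorDraws, classify_gr,
                      classify_rr, cluster_rate_series, overlay)
from spotrisk.spots import COLD, EXCESSED, HOT, MODERATE, NEUTRAL, NONE


def rr_draws_from_logrr(log_rr: np.ndarray, area_ids=None) -> PosteriorDraws:
    """Wrap an (n, I) matrix of log area RRs as a minimal RR fit."""
    n, i = log_rr.shape
    spec = ModelSpec(family="RR_SPACE_TIME", include_nu=False)
    params = {"alpha": np.zeros((1, n)),
              "phi": log_rr[None, :, :]}
    return PosteriorDraws(params, 0, n, [0], spec,
                          area_ids or [f"a{k}" for k in range(i)])


def gr_draws_from_loggr(log_gr: np.ndarray, area_ids=None) -> PosteriorDraws:
    n, i = log_gr.shape
    spec = ModelSpec(family="GROWTH_EXCH")
    params = {"alpha": np.zeros((1, n)),
              "gamma": log_gr[None, :, :]}
    return PosteriorDraws(params, 0, n, [0], spec,
                          area_ids or [f"a{k}" for k in range(i)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestClassifyRR:
    def test_interval_positions(self, rng):
        n = 2000
        log_rr = np.column_stack([
            np.log(rng.uniform(1.1, 1.4, n)),   # all above 1 -> excessed
            np.log(rng.uniform(0.6, 0.9, n)),   # all below 1 -> moderate
            rng.normal(0.0, 0.5, n),            # straddles 1 -> neutral
        ])
        point, lo, hi, classes = classify_rr(rr_draws_from_logrr(log_rr))
        assert classes == [EXCESSED, MODERATE, NEUTRAL]
        assert lo[0] > 1.0 and hi[1] < 1.0

    def test_point_estimate_is_mean_of_rr_draws(self, rng):
        log_rr = rng.normal(0.2, 0.1, size=(5000, 1))
        point, *_ = classify_rr(rr_draws_from_logrr(log_rr))
        # mean of exp, not exp of mean (Jensen gap)
        assert point[0] == pytest.approx(np.exp(log_rr).mean(), rel=1e-12)
        assert point[0] > np.exp(log_rr.mean())

    def test_requires_spatial_effects(self, rng):
        spec = ModelSpec(family="RR_SPACE_TIME", include_phi=False,
                         include_nu=False)
        d = PosteriorDraws({"alpha": np.zeros((1, 10))}, 0, 10, [0], spec,
                           ["a"])
        with pytest.raises(ValueError, match="spatial"):
            classify_rr(d)

    def test_monotone_in_upward_shift(self, rng):
        rank = {MODERATE: 0, NEUTRAL: 1, EXCESSED: 2}
        log_rr = rng.normal(0.0, 0.3, size=(1000, 6)) \
            + np.linspace(-0.5, 0.5, 6)
        _, _, _, base = classify_rr(rr_draws_from_logrr(log_rr))
        for shift in (0.1, 0.5, 2.0):
            _, _, _, shifted = classify_rr(
                rr_draws_from_logrr(log_rr + shift))
            assert all(rank[s] >= rank[b] for s, b in zip(shifted, base))


class TestClassifyGR:
    def test_interval_positions(self, rng):
        n = 2000
        log_gr = np.column_stack([
            np.log(rng.uniform(1.05, 1.2, n)),
            np.log(rng.uniform(0.8, 0.95, n)),
            rng.normal(0.0, 0.3, n),
        ])
        _, _, _, classes = classify_gr(gr_draws_from_loggr(log_gr))
        assert classes == [EXCESSED, MODERATE, NEUTRAL]

    def test_uniform_growth_fit_rejected(self):
        spec = ModelSpec(family="GROWTH_UNIFORM")
        d = PosteriorDraws({"alpha": np.zeros((1, 10)),
                            "gamma": np.zeros((1, 10))}, 0, 10, [0], spec,
                           ["a"])
        with pytest.raises(ValueError, match="GROWTH_EXCH"):
            classify_gr(d)


class TestOverlay:
    def test_rule_table(self, rng):
        n = 1000
        # areas: (excessed, excessed), (moderate, moderate),
        #        (excessed, moderate), (neutral, excessed)
        log_rr = np.column_stack([np.log(rng.uniform(1.1, 1.3, n)),
                                  np.log(rng.uniform(0.7, 0.9, n)),
                                  np.log(rng.uniform(1.1, 1.3, n)),
                                  rng.normal(0, 0.5, n)])
        log_gr = np.column_stack([np.log(rng.uniform(1.1, 1.3, n)),
                                  np.log(rng.uniform(0.7, 0.9, n)),
                                  np.log(rng.uniform(0.7, 0.9, n)),
                                  np.log(rng.uniform(1.1, 1.3, n))])
        spots = overlay(rr_draws_from_logrr(log_rr),
                        gr_draws_from_loggr(log_gr))
        assert spots.overlap == [HOT, COLD, NONE, NONE]
        assert spots.hot_areas == ["a0"] and spots.cold_areas == ["a1"]

    def test_area_mismatch_rejected(self, rng):
        rr = rr_draws_from_logrr(rng.normal(size=(100, 2)), ["a", "b"])
        gr = gr_draws_from_loggr(rng.normal(size=(100, 2)), ["b", "a"])
        with pytest.raises(ValueError, match="ordering"):
            overlay(rr, gr)

    def test_geojson_export_joins_classes(self, tmp_path, rng):
        log_rr = np.log(rng.uniform(1.1, 1.3, size=(500, 1)))
        log_gr = np.log(rng.uniform(1.1, 1.3, size=(500, 1)))
        spots = overlay(rr_draws_from_logrr(log_rr, ["a0"]),
                        gr_draws_from_loggr(log_gr, ["a0"]))
        src = tmp_path / "areas.geojson"
        src.write_text(json.dumps({"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {"area_id": "a0"},
             "geometry": {"type": "Polygon",
                          "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 0]]]}}
        ]}))
        out = tmp_path / "classified.geojson"
        spots.to_geojson(src, out)
        props = json.loads(out.read_text())["features"][0]["properties"]
        assert props["overlap"] == HOT
        assert "rr_mean" in props


class TestClusterRateSeries:
    def _spots(self, overlap, area_ids):
        k = len(area_ids)
        z = np.ones(k)
        from spotrisk import SpotClassification
        return SpotClassification(area_ids, z, z, z, [NEUTRAL] * k,
                                  z, z, z, [NEUTRAL] * k, overlap)

    def test_single_hot_area_rates(self):
        panel = AreaYearPanel(["h", "x"], [2015, 2016],
                              np.array([[10, 20], [1, 1]]),
                              np.array([[100.0, 100.0], [100.0, 100.0]]))
        spots = self._spots([HOT, NONE], ["h", "x"])
        series = cluster_rate_series(panel, spots)
        assert np.allclose(series["hot"], [0.10, 0.20])
        assert series["cold"] is None

    def test_pooled_rate_is_population_weighted_mean(self):
        panel = AreaYearPanel(["a", "b"], [2015],
                              np.array([[10], [30]]),
                              np.array([[100.0], [300.0]]))
        spots = self._spots([COLD, COLD], ["a", "b"])
        series = cluster_rate_series(panel, spots)
        rates = panel.counts[:, 0] / panel.populations[:, 0]
        weights = panel.populations[:, 0] / panel.populations[:, 0].sum()
        assert series["cold"][0] == pytest.approx(float(rates @ weights))
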