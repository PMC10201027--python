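"""Cold-/hot-spot classification by overlaying relative-risk and growth maps.

An area is classed "moderate" when its posterior 95% credible interval for
the quantity of interest lies entirely below 1, "excessed" when it lies
entirely above 1, and "neutral" otherwise.  Applying the rule to the
baseline relative risk exp(alpha + phi_i + nu_i) gives the RR map; applying
it to the per-period growth factor exp(gamma_i) gives the GR map.  Areas
where both maps agree — both moderate or both excessed — are the cold-spots
and hot-spots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws, QUANTILE_METHOD
from .panel import AreaYearPanel

__all__ = [
    "SpotClassification",
    "area_rr_draws",
    "growth_rate_draws",
    "classify_rr",
    "classify_gr",
    "overlay",
    "cluster_rate_series",
]

MODERATE, EXCESSED, NEUTRAL = "moderate", "excessed", "neutral"
COLD, HOT, NONE = "cold", "hot", "none"


@dataclass
class SpotClassification:
    """Per-area RR/GR point estimates, interval classes and overlap label."""

    area_ids: list
    rr_point: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    rr_class: list
    gr_point: np.ndarray
    gr_low: np.ndarray
    gr_high: np.ndarray
    gr_class: list
    overlap: list = field(default_factory=list)

    @property
    def cold_areas(self) -> list:
        return [a for a, o in zip(self.area_ids, self.overlap) if o == COLD]

    @property
    def hot_areas(self) -> list:
        return [a for a, o in zip(self.area_ids, self.overlap) if o == HOT]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area_id": self.area_ids,
            "rr_mean": self.rr_point,
            "rr_q2.5": self.rr_low,
            "rr_q97.5": self.rr_high,
            "rr_class": self.rr_class,
            "gr_mean": self.gr_point,
            "gr_q2.5": self.gr_low,
            "gr_q97.5": self.gr_high,
            "gr_class": self.gr_class,
            "overlap": self.overlap,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_geojson(self, geojson_path, out_path,
                   id_property: str = "area_id") -> None:
        """Join classes onto polygon features for choropleth rendering."""
        with open(geojson_path, "r", encoding="utf-8") as fh:
            gj = json.load(fh)
        rows = {str(r["area_id"]): r
                for r in self.to_frame().to_dict("records")}
        for feat in gj["features"]:
            key = str((feat.get("properties") or {}).get(id_property))
            if key in rows:
                feat.setdefault("properties", {}).update(rows[key])
        with open(out_path, "w", encoding="utf-8") as fh:
            json.dump(gj, fh)


def _interval_classes(draws_matrix: np.ndarray):
    """Point estimate, central 95% interval and class per column.

    Point estimates are posterior means of the risk itself (exp applied
    draw-wise, then averaged).
    """
    point = draws_matrix.mean(axis=0)
    low, high = np.quantile(draws_matrix, [0.025, 0.975], axis=0,
                            method=QUANTILE_METHOD)
    classes = [MODERATE if h < 1.0 else EXCESSED if lo > 1.0 else NEUTRAL
               for lo, h in zip(low, high)]
    return point, low, high, classes


def area_rr_draws(draws: PosteriorDraws) -> np.ndarray:
    """Pooled draws of the baseline area relative risk exp(alpha+phi+nu).

    Uses whichever spatial effects the fitted spec includes; requires at
    least one of them so areas actually differ.
    """
    spec = draws.spec
    if not (spec.include_phi or spec.include_nu):
        raise ValueError("fit has no spatial effects; cannot classify areas")
    log_rr = draws.pooled("alpha")[:, None]
    if spec.include_phi:
        log_rr = log_rr + draws.pooled("phi")
    if spec.include_nu:
        log_rr = log_rr + draws.pooled("nu")
    return np.exp(log_rr)


def growth_rate_draws(draws: PosteriorDraws) -> np.ndarray:
    """Pooled draws of the per-period growth factor exp(gamma_i)."""
    if draws.spec.family not in ("GROWTH_EXCH", "GROWTH_CAR"):
        raise ValueError("growth classification needs area-specific growth "
                         "rates; fit GROWTH_EXCH (or GROWTH_CAR)")
    return np.exp(draws.pooled("gamma"))


def classify_rr(draws: PosteriorDraws):
    """Per-area moderate/excessed/neutral classes for the RR surface."""
    return _interval_classes(area_rr_draws(draws))


def classify_gr(draws: PosteriorDraws):
    """Per-area moderate/excessed/neutral classes for the growth rates."""
    return _interval_classes(growth_rate_draws(draws))


def overlay(rr_draws: PosteriorDraws,
            gr_draws: PosteriorDraws) -> SpotClassification:
    """Overlay the RR and GR maps into cold/hot-spot labels.

    cold = moderate on both maps; hot = excessed on both; anything else is
    "none".
    """
    if list(rr_draws.area_ids) != list(gr_draws.area_ids):
        raise ValueError("RR and GR fits use different area orderings")
    rr_point, rr_lo, rr_hi, rr_cls = classify_rr(rr_draws)
    gr_point, gr_lo, gr_hi, gr_cls = classify_gr(gr_draws)
    labels = []
    for r, g in zip(rr_cls, gr_cls):
        if r == g == MODERATE:
            labels.append(COLD)
        elif r == g == EXCESSED:
            labels.append(HOT)
        else:
            labels.append(NONE)
    return SpotClassification(list(rr_draws.area_ids), rr_point, rr_lo,
                              rr_hi, rr_cls, gr_point, gr_lo, gr_hi, gr_cls,
                              labels)


def cluster_rate_series(panel: AreaYearPanel,
                        classification: SpotClassification) -> dict:
    """Yearly pooled event rates for the cold and hot area sets.

    For each year, sum of counts over the set divided by the summed
    population — the population-weighted mean of member rates.  An empty
    set yields ``None`` for that series.
    """
    idx = {str(a): i for i, a in enumerate(panel.area_ids)}
    out = {}
    for label, areas in (("cold", classification.cold_areas),
                         ("hot", classification.hot_areas)):
        if not areas:
            out[label] = None
            continue
        rows = [idx[str(a)] for a in areas]
        y = panel.counts[rows].sum(axis=0)
        n = panel.populations[rows].sum(axis=0)
        out[label] = y / n
    return out
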