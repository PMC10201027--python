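"""Area-by-year event panels and internally standardized expected counts.

The unit of analysis is a panel of event counts ``y_it`` over small areas
``i`` and consecutive years ``t``, with reference populations ``n_it``
(person-years).  Expected counts ``e_it`` — the Poisson offset — are
derived by internal standardization: one overall event rate for the whole
panel (default) or one rate per year, applied to each cell's population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AreaYearPanel",
    "CovariatePanel",
    "read_panel",
    "write_panel",
    "compute_expected",
    "read_covariates",
]


@dataclass
class AreaYearPanel:
    """Dense area x year panel of counts, populations and expected counts.

    ``counts`` and ``populations`` are I x T matrices aligned to
    ``area_ids`` (rows) and ``years`` (columns).  ``expected`` is filled by
    :func:`compute_expected` and is required by every model fit.
    """

    area_ids: list
    years: list
    counts: np.ndarray = field(repr=False)
    populations: np.ndarray = field(repr=False)
    expected: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.populations = np.asarray(self.populations, dtype=float)
        ii, tt = len(self.area_ids), len(self.years)
        if self.counts.shape != (ii, tt) or self.populations.shape != (ii, tt):
            raise ValueError("counts/populations must be I x T")
        if len(set(self.area_ids)) != ii:
            raise ValueError("duplicate area ids")
        yrs = np.asarray(self.years)
        if tt > 1 and not np.all(np.diff(yrs) == 1):
            raise ValueError("gap in year sequence: years must be consecutive")
        if not np.all(np.equal(np.mod(self.counts, 1), 0)):
            raise TypeError("counts must be integers")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self.counts = self.counts.astype(np.int64)
        if self.expected is not None:
            self.expected = np.asarray(self.expected, dtype=float)
            if self.expected.shape != (ii, tt):
                raise ValueError("expected must be I x T")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def smr(self) -> np.ndarray:
        """Raw standardized morbidity ratios y_it / e_it."""
        if self.expected is None:
            raise ValueError("expected counts not computed")
        return self.counts / self.expected


@dataclass
class CovariatePanel:
    """One covariate x_it aligned to an :class:`AreaYearPanel`."""

    name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariate values must be an I x T matrix")
        if np.isnan(self.values).any():
            raise ValueError(f"covariate {self.name!r} has missing cells")


def _read_long(path, value_name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"area_id", "year", "value"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns area_id, year, value")
    df["area_id"] = df["area_id"].astype(str)
    dup = df.duplicated(["area_id", "year"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"duplicate ({row['area_id']}, {row['year']}) "
                         f"in {value_name} file")
    return df


def read_panel(counts_path, pop_path) -> AreaYearPanel:
    """Read long-format count and population CSVs into a dense panel.

    Both files need columns ``area_id, year, value`` and identical
    (area, year) key sets; years must form a consecutive run.
    """
    cdf = _read_long(counts_path, "counts")
    pdf = _read_long(pop_path, "populations")
    cpiv = cdf.pivot(index="area_id", columns="year", values="value")
    ppiv = pdf.pivot(index="area_id", columns="year", values="value")
    if set(cpiv.index) != set(ppiv.index) or list(cpiv.columns) != list(ppiv.columns):
        missing = (set(cpiv.index) ^ set(ppiv.index)) or (
            set(cpiv.columns) ^ set(ppiv.columns))
        raise ValueError(f"counts/population key mismatch: {sorted(missing)}")
    ppiv = ppiv.loc[cpiv.index]
    if cpiv.isna().any().any() or ppiv.isna().any().any():
        r, c = np.argwhere(cpiv.isna().to_numpy() | ppiv.isna().to_numpy())[0]
        raise ValueError(f"missing cell for ({cpiv.index[r]}, {cpiv.columns[c]})")
    years = [int(y) for y in cpiv.columns]
    if len(years) > 1 and np.any(np.diff(years) != 1):
        raise ValueError("gap in year sequence")
    counts = cpiv.to_numpy()
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise TypeError("non-integer count value")
    pops = ppiv.to_numpy(dtype=float)
    if np.any(pops <= 0):
        raise ValueError("populations must be positive")
    return AreaYearPanel(list(cpiv.index), years, counts, pops)


def write_panel(panel: AreaYearPanel, counts_path, pop_path) -> None:
    """Write a panel back to the long CSV layout ``read_panel`` accepts."""
    rows_c, rows_p = [], []
    for i, a in enumerate(panel.area_ids):
        for t, y in enumerate(panel.years):
            rows_c.append((a, y, panel.counts[i, t]))
            rows_p.append((a, y, panel.populations[i, t]))
    cols = ["area_id", "year", "value"]
    pd.DataFrame(rows_c, columns=cols).to_csv(counts_path, index=False)
    pd.DataFrame(rows_p, columns=cols).to_csv(pop_path, index=False)


def compute_expected(panel: AreaYearPanel, per_year: bool = False) -> AreaYearPanel:
    """Fill expected counts by internal standardization.

    Default is one overall rate r = sum(y) / sum(n) for the whole panel, so
    e_it = n_it * r and the expected counts sum exactly to the observed
    counts.  ``per_year=True`` uses a separate rate per column instead.
    """
    if np.any(panel.populations <= 0):
        raise ValueError("populations must be positive")
    if per_year:
        rate = panel.counts.sum(axis=0) / panel.populations.sum(axis=0)
        expected = panel.populations * rate[None, :]
    else:
        rate = panel.counts.sum() / panel.populations.sum()
        expected = panel.populations * rate
    return AreaYearPanel(panel.area_ids, panel.years, panel.counts,
                         panel.populations, expected)


def read_covariates(path, panel: AreaYearPanel) -> list:
    """Read covariates aligned to a panel.

    Accepts either the long layout ``area_id, year, covariate, value`` or a
    wide per-area layout ``area_id, <name1>, <name2>, ...`` whose constants
    are broadcast across all years.  Every covariate must cover every panel
    area.
    """
    df = pd.read_csv(path)
    if df.empty and df.shape[1] == 0:
        return []
    df.columns = [str(c) for c in df.columns]
    out: list[CovariatePanel] = []
    index = {str(a): i for i, a in enumerate(panel.area_ids)}
    ii, tt = panel.n_areas, panel.n_years

    if {"area_id", "year", "covariate", "value"}.issubset(df.columns):
        if df.empty:
            return []
        df["area_id"] = df["area_id"].astype(str)
        for name, sub in df.groupby("covariate", sort=True):
            mat = np.full((ii, tt), np.nan)
            piv = sub.pivot(index="area_id", columns="year", values="value")
            missing_areas = set(index) - set(piv.index)
            if missing_areas:
                raise ValueError(f"covariate {name!r} missing areas "
                                 f"{sorted(missing_areas)}")
            for a, row in piv.iterrows():
                i = index[a]
                if piv.shape[1] == 1:
                    mat[i, :] = row.iloc[0]
                else:
                    for t, yr in enumerate(panel.years):
                        if yr not in piv.columns or pd.isna(row.get(yr)):
                            raise ValueError(f"covariate {name!r} missing "
                                             f"({a}, {yr})")
                        mat[i, t] = row[yr]
            out.append(CovariatePanel(str(name), mat))
        return out

    if "area_id" not in df.columns:
        raise ValueError("covariate file needs an area_id column")
    if df.empty or df.shape[1] == 1:
        return []
    df["area_id"] = df["area_id"].astype(str)
    missing_areas = set(index) - set(df["area_id"])
    if missing_areas:
        raise ValueError(f"covariate file missing areas {sorted(missing_areas)}")
    df = df.set_index("area_id").loc[[str(a) for a in panel.area_ids]]
    for name in df.columns:
        col = df[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"covariate {name!r} has missing values")
        out.append(CovariatePanel(name, np.repeat(col[:, None], tt, axis=1)))
    return out
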