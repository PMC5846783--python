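"""Prediction grids and density / uncertainty maps.

A :class:`PredictionGrid` holds per-day covariate values on a fixed cell set
(the mapping convention is a 0.05 deg x 0.05 deg cell grid, but any cell set
works).  Daily model predictions on the grid are combined into a survey-period
:class:`DensityMap` (cellwise mean, valid only where every day is valid) and
an :class:`UncertaintyMap` of coefficients of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PredictionGrid",
    "DailyPredictions",
    "DensityMap",
    "UncertaintyMap",
    "average_predictions",
    "uncertainty_cv",
    "prediction_mse",
]


@dataclass
class PredictionGrid:
    """Covariates per cell and day.

    ``covariates[name]`` has shape (n_days, n_cells); every day supplies the
    same ordered cell set.
    """

    cell_ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    days: np.ndarray
    covariates: dict

    def __post_init__(self):
        n_days, n_cells = len(self.days), len(self.cell_ids)
        for name, arr in self.covariates.items():
            if arr.shape != (n_days, n_cells):
                raise ValueError(f"covariate {name!r} has shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"covariate {name!r} has non-finite values")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_days(self) -> int:
        return len(self.days)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates=None) -> "PredictionGrid":
        """Build from a long table ``cell_id, lon, lat, day_index, <cov...>``."""
        required = {"cell_id", "lon", "lat", "day_index"}
        if not required.issubset(df.columns):
            raise ValueError(f"grid frame needs columns {sorted(required)}")
        if covariates is None:
            covariates = [c for c in df.columns if c not in required]
        days = np.sort(df["day_index"].unique())
        first = df[df["day_index"] == days[0]].sort_values("cell_id")
        cell_ids = first["cell_id"].to_numpy()
        arrs = {c: np.empty((len(days), len(cell_ids))) for c in covariates}
        for i, d in enumerate(days):
            sub = df[df["day_index"] == d].sort_values("cell_id")
            if not np.array_equal(sub["cell_id"].to_numpy(), cell_ids):
                raise ValueError("every day must supply the same cell set")
            for c in covariates:
                arrs[c][i] = sub[c].to_numpy(dtype=float)
        return cls(
            cell_ids=cell_ids,
            lon=first["lon"].to_numpy(dtype=float),
            lat=first["lat"].to_numpy(dtype=float),
            days=days,
            covariates=arrs,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.days):
            block = {
                "cell_id": self.cell_ids,
                "lon": self.lon,
                "lat": self.lat,
                "day_index": d,
            }
            for c, arr in self.covariates.items():
                block[c] = arr[i]
            rows.append(pd.DataFrame(block))
        return pd.concat(rows, ignore_index=True)


@dataclass
class DailyPredictions:
    """Per-day density predictions with validity masks and delta-method
    variances; shapes (n_days, n_cells)."""

    grid: PredictionGrid
    density: np.ndarray
    valid: np.ndarray
    variance: np.ndarray


@dataclass
class DensityMap:
    """Survey-period mean density (individuals per km^2) per cell."""

    cell_ids: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "lon": self.lon,
                "lat": self.lat,
                "value": np.where(self.valid, self.values, np.nan),
                "valid": self.valid.astype(int),
            }
        )


class UncertaintyMap(DensityMap):
    """Per-cell coefficient of variation in percent."""


def average_predictions(daily: DailyPredictions) -> DensityMap:
    """Cellwise mean over days; valid only where every day is valid."""
    if daily.density.shape[0] < 1:
        raise ValueError("need at least one day of predictions")
    valid = daily.valid.all(axis=0)
    vals = np.where(valid, daily.density.mean(axis=0), np.nan)
    return DensityMap(
        cell_ids=daily.grid.cell_ids,
        lon=daily.grid.lon,
        lat=daily.grid.lat,
        values=vals,
        valid=valid,
    )


def uncertainty_cv(daily: DailyPredictions, sqrt_convention: bool = True) -> UncertaintyMap:
    """CV map combining between-day and within-day prediction variance.

    total variance = population variance across days of the daily means
    plus the mean of the daily delta-method variances;
    CV = 100 * sqrt(total variance) / period mean.  ``sqrt_convention=False``
    gives the literal variance-to-mean ratio instead.  Cells with zero mean
    are reported invalid (undefined CV).
    """
    valid = daily.valid.all(axis=0)
    mean = daily.density.mean(axis=0)
    between = daily.density.var(axis=0)  # population variance across days
    within = daily.variance.mean(axis=0)
    total = between + within
    ok = valid & (mean > 0)
    spread = np.sqrt(total) if sqrt_convention else total
    vals = np.where(ok, 100.0 * spread / np.where(mean > 0, mean, 1.0), np.nan)
    return UncertaintyMap(
        cell_ids=daily.grid.cell_ids,
        lon=daily.grid.lon,
        lat=daily.grid.lat,
        values=vals,
        valid=ok,
    )


def prediction_mse(
    map_exp: DensityMap, map_base: DensityMap, standardise: bool = False
) -> float:
    """Mean over jointly valid cells of squared prediction differences.

    With ``standardise=True`` each map is first divided by its own mean over
    the jointly valid cells, so the comparison measures distribution
    *pattern* rather than absolute scale.  This is how experimental models
    are scored in the thinning experiment: thinning lowers predicted
    densities roughly in proportion to the retained fraction while the
    spatial pattern is what a surviving model should preserve.
    """
    if len(map_exp.cell_ids) != len(map_base.cell_ids) or not np.array_equal(
        map_exp.cell_ids, map_base.cell_ids
    ):
        raise ValueError("maps are on different grids")
    both = map_exp.valid & map_base.valid
    if not both.any():
        raise ValueError("no jointly valid cells")
    a = map_exp.values[both].astype(float)
    b = map_base.values[both].astype(float)
    if standardise:
        ma, mb = a.mean(), b.mean()
        if ma <= 0 or mb <= 0:
            raise ValueError("cannot standardise a map with nonpositive mean")
        a = a / ma
        b = b / mb
    return float(np.mean((a - b) ** 2))
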