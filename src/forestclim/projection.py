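"""Scenario-based projection of LST change from forest-change rasters.

Given a fitted total standardized effect of forest change on LST and the
sample SDs that anchor the standardized scale, a scenario raster of future
forest change (e.g. 2050 minus 2010, in percentage points) maps linearly to
a predicted LST change per cell:

    dLST_pred = total_std × (dF / sd_dF) × sd_dLST      [°C]

The projection assumes the fitted relationships remain unchanged over the
scenario horizon (stationarity) — a simplification surfaced in the output
metadata, useful for contrasting land-use futures, not for forecasting
climate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GeoGrid, resample_bilinear

__all__ = ["ScenarioRaster", "ProjectionResult", "project_dlst", "summarize_projection"]

STATIONARITY_NOTE = (
    "assumes the fitted forest-change/albedo/ET/LST relationships remain "
    "unchanged over the scenario horizon"
)


@dataclass
class ScenarioRaster:
    """Forest-change raster for one land-use scenario (%, −100..+100)."""

    dF: GeoGrid
    label: str = "scenario"

    def __post_init__(self) -> None:
        valid = self.dF.values[self.dF.mask]
        if valid.size and np.nanmax(np.abs(valid)) > 100 + 1e-9:
            raise ValueError("scenario dF outside [-100, 100]")

    def at_resolution(self, target: GeoGrid) -> "ScenarioRaster":
        """Bring a coarser scenario raster onto the analysis grid (bilinear)."""
        return ScenarioRaster(resample_bilinear(self.dF, target), self.label)


@dataclass
class ProjectionResult:
    """Predicted LST change grid plus summary over valid cells."""

    dLST_pred: GeoGrid
    mean: float
    min: float
    max: float
    label: str
    metadata: dict

    def summary(self) -> tuple[float, float, float]:
        return self.mean, self.min, self.max


def summarize_projection(grid: GeoGrid) -> tuple[float, float, float]:
    """(mean, min, max) over valid cells only."""
    vals = grid.values[grid.mask]
    if vals.size == 0:
        raise ValueError("fully masked raster has no summary")
    return float(vals.mean()), float(vals.min()), float(vals.max())


def project_dlst(
    scenario: ScenarioRaster,
    total_std: float,
    sd_dF: float,
    sd_dLST: float,
) -> ProjectionResult:
    """Project per-cell LST change from a forest-change scenario.

    ``total_std`` is the total (direct + indirect) standardized effect of
    forest change on LST from the fitted path model; ``sd_dF`` (%) and
    ``sd_dLST`` (°C) are the sample SDs defining the standardized scale.
    The mapping is linear and exactly zero where dF is zero.
    """
    if sd_dF <= 0 or sd_dLST <= 0:
        raise ValueError("standard deviations must be positive")
    if not np.isfinite(total_std):
        raise ValueError("total effect must be finite")
    g = scenario.dF
    pred = np.where(g.mask, total_std * (g.values / sd_dF) * sd_dLST, np.nan)
    out = GeoGrid(pred, g.mask.copy(), g.origin_lon, g.origin_lat, g.res)
    mean, mn, mx = summarize_projection(out)
    return ProjectionResult(
        dLST_pred=out,
        mean=mean,
        min=mn,
        max=mx,
        label=scenario.label,
        metadata={
            "total_std": total_std,
            "sd_dF": sd_dF,
            "sd_dLST": sd_dLST,
            "caveat": STATIONARITY_NOTE,
        },
    )
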