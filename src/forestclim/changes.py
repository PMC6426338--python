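"""Decadal change layers and latitudinal region labels.

Change is always the later epoch minus the earlier epoch per cell: forest
cover 2010 minus 2000 (ΔF, in percentage points, range −100..+100), and for
each climate variable the annual mean of the later climate year minus the
earlier one (ΔLST °C, ΔET mm/month, Δalbedo %).  The climate epochs are
offset one year after the forest epochs by default (2001/2011 versus
2000/2010) so that the forest change, the presumed cause, precedes the
climate response; a same-epoch mode is available for robustness runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GeoGrid

__all__ = ["ChangeLayer", "decadal_change", "classify_region", "REGIONS"]

REGIONS = ("tropical", "temperate", "boreal")

#: absolute-latitude upper bounds of the equatorward classes; boundary values
#: belong to the lower-latitude class (|lat| = 20 is tropical, 50 temperate)
TROPICAL_MAX_ABS_LAT = 20.0
TEMPERATE_MAX_ABS_LAT = 50.0


def decadal_change(later: GeoGrid, earlier: GeoGrid) -> GeoGrid:
    """Per-cell change ``later − earlier``; masked where either input is."""
    if not later.same_geometry(earlier):
        raise ValueError("epoch grids are not co-registered")
    mask = later.mask & earlier.mask
    vals = np.where(mask, later.values - earlier.values, np.nan)
    return GeoGrid(vals, mask, later.origin_lon, later.origin_lat, later.res)


def classify_region(lat: float) -> str:
    """Latitudinal region label: tropical ≤ 20°, temperate ≤ 50°, boreal beyond."""
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of range [-90, 90]")
    a = abs(lat)
    if a <= TROPICAL_MAX_ABS_LAT:
        return "tropical"
    if a <= TEMPERATE_MAX_ABS_LAT:
        return "temperate"
    return "boreal"


@dataclass
class ChangeLayer:
    """Co-registered decadal change grids for all four variables."""

    dF: GeoGrid
    dLST: GeoGrid
    dET: GeoGrid
    dAlbedo: GeoGrid
    epochs: dict | None = None  # e.g. {"forest": (2000, 2010), "climate": (2001, 2011)}

    def __post_init__(self) -> None:
        for name in ("dLST", "dET", "dAlbedo"):
            if not self.dF.same_geometry(getattr(self, name)):
                raise ValueError(f"{name} geometry differs from dF")
        valid_df = self.dF.values[self.dF.mask]
        if valid_df.size and (np.nanmax(np.abs(valid_df)) > 100 + 1e-9):
            raise ValueError("dF outside [-100, 100]")

    @property
    def grids(self) -> dict[str, GeoGrid]:
        return {"dF": self.dF, "dLST": self.dLST, "dET": self.dET, "dAlbedo": self.dAlbedo}
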