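"""Window-searching strategy: focal/reference cell pairs from change rasters.

The grid is tiled with overlapping search windows (default 5 cells in
longitude by 3 in latitude, advancing 2 cells in each direction so adjacent
windows share 3 columns and 1 row).  Within each window at most one pair of
cells is selected:

* the *focal* cell — the valid cell with the greatest absolute forest change,
  provided it exceeds the focal threshold (default 15 percentage points);
* the *reference* cell — the valid cell with the smallest absolute forest
  change, provided it is below the reference threshold (default 5).

Because both members of a pair sit within the same ~25 km window they share
the same regional background climate, so the standardized change
(focal minus reference, for each variable) isolates the local signal of
forest change from the regional trend.  A pair of cells that is selected by
two overlapping windows is kept only at its first occurrence, scanning
windows row-major from the northwest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .changes import ChangeLayer, classify_region
from .grid import GeoGrid

__all__ = [
    "WindowSpec",
    "CellPair",
    "tile_windows",
    "select_pair",
    "standardize_changes",
    "dedupe_pairs",
    "subset_by_change",
    "find_pairs",
    "pairs_to_frame",
]

VARIABLES = ("dF", "dLST", "dET", "dAlbedo")


@dataclass(frozen=True)
class WindowSpec:
    """Search-window geometry and forest-change thresholds (units: cells, %)."""

    size_lon: int = 5
    size_lat: int = 3
    stride_lon: int = 2
    stride_lat: int = 2
    focal_thresh: float = 15.0
    ref_thresh: float = 5.0

    def __post_init__(self) -> None:
        if not (1 <= self.stride_lon <= self.size_lon and 1 <= self.stride_lat <= self.size_lat):
            raise ValueError("strides must satisfy 1 <= stride <= size per axis")
        if not (0 < self.ref_thresh < self.focal_thresh <= 100):
            raise ValueError("thresholds must satisfy 0 < ref < focal <= 100")


@dataclass
class CellPair:
    """One focal/reference pair with standardized (focal − reference) changes.

    ``changes`` maps variable name to the standardized change; a variable is
    absent when either member cell lacks valid data for it, so pairs enter
    different analyses in different numbers.  ``focal_changes``/``ref_changes``
    retain the member values needed by the paired mixed model.
    """

    window_id: int
    focal_index: tuple[int, int]
    ref_index: tuple[int, int]
    focal_lon: float
    focal_lat: float
    ref_lon: float
    ref_lat: float
    changes: dict = field(default_factory=dict)
    focal_changes: dict = field(default_factory=dict)
    ref_changes: dict = field(default_factory=dict)

    @property
    def dF_std(self) -> float:
        return self.changes["dF"]

    @property
    def region(self) -> str:
        # region is assigned from the focal cell's latitude
        return classify_region(self.focal_lat)

    @property
    def category(self) -> str:
        return "forestation" if self.dF_std > 0 else "deforestation"


def tile_windows(
    shape: tuple[int, int], spec: WindowSpec
) -> list[tuple[int, int]]:
    """Window origins (row, col) in row-major order from the northwest.

    Only windows that fit entirely inside the grid are emitted; partial
    windows at the south/east edges are dropped rather than padded.
    """
    nlat, nlon = shape
    if nlat < spec.size_lat or nlon < spec.size_lon:
        raise ValueError(f"grid {shape} smaller than one {spec.size_lat}x{spec.size_lon} window")
    rows = range(0, nlat - spec.size_lat + 1, spec.stride_lat)
    cols = range(0, nlon - spec.size_lon + 1, spec.stride_lon)
    return [(r, c) for r in rows for c in cols]


def select_pair(
    dF: GeoGrid, origin: tuple[int, int], spec: WindowSpec, window_id: int = 0
) -> CellPair | None:
    """Select the focal/reference pair of one window, or None.

    Focal: valid cell maximizing \\|ΔF\\| among those with \\|ΔF\\| > focal_thresh.
    Reference: valid cell minimizing \\|ΔF\\| among those with \\|ΔF\\| < ref_thresh.
    Ties break first-in-row-major; absence of either candidate yields None.
    """
    r0, c0 = origin
    sub = dF.values[r0 : r0 + spec.size_lat, c0 : c0 + spec.size_lon]
    subm = dF.mask[r0 : r0 + spec.size_lat, c0 : c0 + spec.size_lon]
    absd = np.where(subm, np.abs(sub), np.nan)

    with np.errstate(invalid="ignore"):
        focal_ok = subm & (absd > spec.focal_thresh)
        ref_ok = subm & (absd < spec.ref_thresh)
    if not focal_ok.any() or not ref_ok.any():
        return None
    # row-major argmax/argmin on flattened arrays: np.nanargmax/min return the
    # first occurrence, which implements the first-wins tie break
    focal_flat = np.where(focal_ok, absd, -np.inf).ravel()
    fi = int(np.argmax(focal_flat))
    ref_flat = np.where(ref_ok, absd, np.inf).ravel()
    ri = int(np.argmin(ref_flat))
    f_idx = (r0 + fi // spec.size_lon, c0 + fi % spec.size_lon)
    r_idx = (r0 + ri // spec.size_lon, c0 + ri % spec.size_lon)
    if f_idx == r_idx:  # cannot happen with ref_thresh < focal_thresh; guard anyway
        return None
    return CellPair(
        window_id=window_id,
        focal_index=f_idx,
        ref_index=r_idx,
        focal_lon=float(dF.lon_center(f_idx[1])),
        focal_lat=float(dF.lat_center(f_idx[0])),
        ref_lon=float(dF.lon_center(r_idx[1])),
        ref_lat=float(dF.lat_center(r_idx[0])),
    )


def standardize_changes(pair: CellPair, change: ChangeLayer) -> CellPair:
    """Fill the pair's standardized changes from a change layer.

    For each variable the standardized change is the focal cell's change minus
    the reference cell's; the entry is absent when either cell is masked for
    that variable.
    """
    nlat, nlon = change.dF.shape
    for (i, j) in (pair.focal_index, pair.ref_index):
        if not (0 <= i < nlat and 0 <= j < nlon):
            raise IndexError(f"pair index ({i}, {j}) outside grid {change.dF.shape}")
    for name, grid in change.grids.items():
        fi, fj = pair.focal_index
        ri, rj = pair.ref_index
        if grid.mask[fi, fj] and grid.mask[ri, rj]:
            fv = float(grid.values[fi, fj])
            rv = float(grid.values[ri, rj])
            pair.changes[name] = fv - rv
            pair.focal_changes[name] = fv
            pair.ref_changes[name] = rv
    return pair


def dedupe_pairs(pairs: Sequence[CellPair]) -> list[CellPair]:
    """Keep only the first occurrence of each (focal_index, ref_index) pair.

    Input order must be window order (row-major from the northwest), so the
    retained pair is the one from the earliest window.
    """
    seen: set = set()
    out: list[CellPair] = []
    for p in pairs:
        key = (p.focal_index, p.ref_index)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def subset_by_change(pairs: Sequence[CellPair], low: float, high: float) -> list[CellPair]:
    """Pairs with ``low < |dF_std| < high`` (strict inequalities)."""
    if not low < high:
        raise ValueError("low must be < high")
    return [p for p in pairs if low < abs(p.dF_std) < high]


def find_pairs(change: ChangeLayer, spec: WindowSpec = WindowSpec()) -> list[CellPair]:
    """Run the full window search on a change layer.

    Tiles the grid, selects at most one pair per window on the ΔF grid,
    extracts standardized changes for every variable from the exact same
    cells, drops pairs lacking a valid ΔF for either member, and removes
    duplicate pairs keeping first occurrences.
    """
    pairs: list[CellPair] = []
    for wid, origin in enumerate(tile_windows(change.dF.shape, spec)):
        p = select_pair(change.dF, origin, spec, window_id=wid)
        if p is None:
            continue
        standardize_changes(p, change)
        if "dF" in p.changes:
            pairs.append(p)
    return dedupe_pairs(pairs)


def pairs_to_frame(pairs: Sequence[CellPair]) -> pd.DataFrame:
    """Tabulate pairs as one row each; absent variables become NaN."""
    rows = []
    for p in pairs:
        row = {
            "window_id": p.window_id,
            "focal_row": p.focal_index[0],
            "focal_col": p.focal_index[1],
            "ref_row": p.ref_index[0],
            "ref_col": p.ref_index[1],
            "focal_lon": p.focal_lon,
            "focal_lat": p.focal_lat,
            "ref_lon": p.ref_lon,
            "ref_lat": p.ref_lat,
        }
        for v in VARIABLES:
            row[f"{v}_std"] = p.changes.get(v, np.nan)
            row[f"{v}_foc"] = p.focal_changes.get(v, np.nan)
            row[f"{v}_ref"] = p.ref_changes.get(v, np.nan)
        row["region"] = p.region
        row["category"] = p.category
        rows.append(row)
    return pd.DataFrame(rows)
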