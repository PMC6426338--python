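"""Seeded synthetic landscapes and pair tables with known causal ground truth.

Two generators serve every stage of the pipeline:

* :func:`generate_landscape` builds two-epoch forest and climate rasters on a
  lat/lon grid: patchy decadal forest change, climate changes produced by the
  linear causal chain forest → albedo/ET → LST, cell-level plus spatially
  correlated noise, a smooth regional background trend shared by both members
  of any nearby pair (which the window pairing is designed to cancel), and
  per-cell QC layers with a configurable failure rate.
* :func:`generate_pairs` draws pair-level standardized changes directly from
  the same structural equations, bypassing rasters for fast statistical tests.

The structural coefficients are specified on the standardized scale.  By
default the noise variance of each endogenous variable is set so that every
standardized variable has unit population variance, which makes the supplied
coefficients exactly the population standardized path coefficients and the
per-equation explained variance exactly the population R².  The default
coefficients put the total standardized effect of forest change on LST at
−0.64 (direct −0.23), the regime reported for tropical South America.

Identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist, squareform

from .changes import ChangeLayer, decadal_change
from .grid import GeoGrid, QCRule, apply_qc
from .gls import CorrelationStructure, correlation_value

__all__ = [
    "SyntheticParams",
    "SyntheticLandscape",
    "generate_landscape",
    "generate_pairs",
    "implied_moments",
    "landscape_change_layer",
]

_ZVARS = ("dF", "dAlbedo", "dET", "dLST")


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the synthetic generators.

    Structural coefficients (standardized scale): ``s_FA`` forest→albedo,
    ``s_FE`` forest→ET, ``s_AE`` albedo→ET, ``s_FL`` forest→LST (direct),
    ``s_AL`` albedo→LST, ``s_EL`` ET→LST.  ``noise_sds`` of None selects the
    unit-variance convention described in the module docstring.  ``scale_*``
    convert standardized changes to physical units (%, mm/month, °C).
    """

    n_lat: int = 60
    n_lon: int = 60
    res: float = 0.05
    origin_lon: float = -74.0
    origin_lat: float = 5.0
    change_patch_rate: float = 0.05
    forestation_fraction: float = 0.5
    s_FA: float = -0.5
    s_FE: float = 0.5
    s_AE: float = -0.04
    s_FL: float = -0.23
    s_AL: float = 0.3
    s_EL: float = -0.5
    noise_sds: tuple[float, float, float] | None = None  # (albedo, ET, LST), z units
    spatial_noise_family: str = "exponential"
    spatial_noise_range: float = 1.0  # degrees
    spatial_noise_share: float = 0.15  # fraction of noise variance that is spatial
    background_trend_amplitude: float = 0.5  # z units, smooth regional trend in each climate change
    qc_fail_rate: float = 0.02
    scale_albedo: float = 1.5
    scale_et: float = 4.0
    scale_lst: float = 0.57
    window_effect_sd: float = 0.5  # shared window background, z units
    lat_range: tuple[float, float] = (-33.0, 5.0)
    lon_range: tuple[float, float] = (-74.0, -35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.change_patch_rate, self.forestation_fraction, self.qc_fail_rate,
                  self.spatial_noise_share):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.noise_sds is not None and any(s < 0 for s in self.noise_sds):
            raise ValueError("noise SDs must be non-negative")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("degenerate grid")

    @property
    def coefficients(self) -> dict[tuple[str, str], float]:
        return {
            ("dF", "dAlbedo"): self.s_FA,
            ("dF", "dET"): self.s_FE,
            ("dAlbedo", "dET"): self.s_AE,
            ("dF", "dLST"): self.s_FL,
            ("dAlbedo", "dLST"): self.s_AL,
            ("dET", "dLST"): self.s_EL,
        }

    @property
    def scales(self) -> dict[str, float]:
        return {"dAlbedo": self.scale_albedo, "dET": self.scale_et, "dLST": self.scale_lst}


# ---------------------------------------------------------------------------
# population bookkeeping
# ---------------------------------------------------------------------------

def _mixture_moments(params: SyntheticParams) -> tuple[float, float]:
    """Population mean and SD of the pair-level forest change mixture.

    Focal |ΔF| is uniform on (15, 100) with sign + (forestation) at the
    stated fraction; the reference ΔF is uniform on (−5, 5).
    """
    f = params.forestation_fraction
    lo, hi = 15.0, 100.0
    m1 = (lo + hi) / 2.0
    m2 = (lo**2 + lo * hi + hi**2) / 3.0
    mean = (2.0 * f - 1.0) * m1
    var_signed = m2 - mean**2
    var_ref = (10.0**2) / 12.0
    return mean, float(np.sqrt(var_signed + var_ref))


def implied_moments(params: SyntheticParams) -> dict:
    """Population covariance, noise SDs, per-equation R² and total effect.

    Works in the standardized (z) space.  With the unit-variance convention
    the noise SD of each endogenous variable is sqrt(1 − explained variance);
    explicit ``noise_sds`` give variables non-unit variance, in which case
    the population standardized coefficients differ from the structural ones
    and are derived from the implied covariance.
    """
    order = list(_ZVARS)
    coeffs = params.coefficients
    idx = {v: i for i, v in enumerate(order)}
    sigma = np.zeros((4, 4))
    sigma[0, 0] = 1.0  # zF has unit variance by construction
    noise = {"dF": 0.0}
    given = None if params.noise_sds is None else dict(zip(("dAlbedo", "dET", "dLST"), params.noise_sds))
    for v in order[1:]:
        parents = [p for p in order if (p, v) in coeffs]
        b = np.array([coeffs[(p, v)] for p in parents])
        pa_idx = [idx[p] for p in parents]
        explained = float(b @ sigma[np.ix_(pa_idx, pa_idx)] @ b)
        if given is None:
            if explained >= 1.0:
                raise ValueError(f"explained variance of {v} is ≥ 1; reduce coefficients")
            psi = 1.0 - explained
        else:
            psi = given[v] ** 2
        noise[v] = float(np.sqrt(psi))
        cov_with = sigma[:, pa_idx] @ b  # cov(z_u, v) for all u filled so far
        i = idx[v]
        sigma[:, i] = cov_with
        sigma[i, :] = cov_with
        sigma[i, i] = explained + psi
    sds = np.sqrt(np.diag(sigma))
    with np.errstate(invalid="ignore", divide="ignore"):
        std_coeffs = {
            (p, v): coeffs[(p, v)] * sds[idx[p]] / sds[idx[v]] for (p, v) in coeffs
        }
        r2 = {}
        for v in order[1:]:
            r2[v] = 1.0 - noise[v] ** 2 / sigma[idx[v], idx[v]]
        total = float(sigma[idx["dF"], idx["dLST"]] / (sds[idx["dF"]] * sds[idx["dLST"]]))
    return {
        "sigma": sigma,
        "order": order,
        "noise_sds": noise,
        "r2": r2,
        "standardized_coefficients": std_coeffs,
        "total_effect": total,
    }


# ---------------------------------------------------------------------------
# pair-level generator
# ---------------------------------------------------------------------------

def _spatial_noise(coords: np.ndarray, params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated field at scattered points (Cholesky)."""
    n = coords.shape[0]
    structure = CorrelationStructure(params.spatial_noise_family, params.spatial_noise_range)
    C = correlation_value(structure, squareform(pdist(coords)))
    np.fill_diagonal(C, 1.0)
    C[np.diag_indices_from(C)] += 1e-8
    L = linalg.cholesky(C, lower=True)
    return L @ rng.standard_normal(n)


def generate_pairs(params: SyntheticParams, n_pairs: int) -> pd.DataFrame:
    """Draw a pair table straight from the structural equations.

    Standardized forest change is a forestation/deforestation mixture; the
    three climate responses follow the structural equations with independent
    cell-level noise plus a spatially correlated component at the stated
    family and range.  Focal coordinates are uniform over the configured
    lon/lat box; the reference cell sits within one window extent of its
    focal cell.  Member (focal/reference) values share a per-window
    background so the paired mixed model is exercisable.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(params.seed)
    mean_f, sd_f = _mixture_moments(params)
    moments = implied_moments(params)
    noise_sds = moments["noise_sds"]

    sign = np.where(rng.random(n_pairs) < params.forestation_fraction, 1.0, -1.0)
    focal_df = sign * rng.uniform(15.0, 100.0, n_pairs)
    ref_df = rng.uniform(-5.0, 5.0, n_pairs)
    df_std = focal_df - ref_df
    zF = (df_std - mean_f) / sd_f

    lon = rng.uniform(*params.lon_range, n_pairs)
    lat = rng.uniform(*params.lat_range, n_pairs)
    coords = np.column_stack([lon, lat])
    ref_lon = lon + rng.uniform(-0.25, 0.25, n_pairs)
    ref_lat = lat + rng.uniform(-0.15, 0.15, n_pairs)

    w = params.spatial_noise_share
    z = {"dF": zF}
    for v in ("dAlbedo", "dET", "dLST"):
        mean = np.zeros(n_pairs)
        for (p, resp), c in params.coefficients.items():
            if resp == v:
                mean += c * z[p]
        sd = noise_sds[v]
        eps = np.sqrt(1.0 - w) * rng.standard_normal(n_pairs)
        if w > 0:
            eps += np.sqrt(w) * _spatial_noise(coords, params, rng)
        z[v] = mean + sd * eps

    data = {
        "window_id": np.arange(n_pairs),
        "focal_row": np.full(n_pairs, -1),
        "focal_col": np.full(n_pairs, -1),
        "ref_row": np.full(n_pairs, -1),
        "ref_col": np.full(n_pairs, -1),
        "focal_lon": lon,
        "focal_lat": lat,
        "ref_lon": ref_lon,
        "ref_lat": ref_lat,
    }
    scales = {"dF": 1.0, **params.scales}
    for v in _ZVARS:
        std = (df_std if v == "dF" else z[v] * scales[v])
        bg = params.window_effect_sd * scales[v] * rng.standard_normal(n_pairs)
        data[f"{v}_std"] = std
        data[f"{v}_ref"] = (ref_df if v == "dF" else bg)
        data[f"{v}_foc"] = data[f"{v}_ref"] + (focal_df - ref_df if v == "dF" else std)
    df = pd.DataFrame(data)
    df["region"] = [
        "tropical" if abs(la) <= 20 else ("temperate" if abs(la) <= 50 else "boreal")
        for la in lat
    ]
    df["category"] = np.where(df["dF_std"] > 0, "forestation", "deforestation")
    return df


# ---------------------------------------------------------------------------
# landscape generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLandscape:
    """Two-epoch rasters, QC layers and the generating ground truth."""

    forest_t1: GeoGrid
    forest_t2: GeoGrid
    climate_t1: dict  # variable -> GeoGrid
    climate_t2: dict
    qc: dict  # layer name -> GeoGrid
    true_changes: dict  # variable -> GeoGrid of the generated change fields
    params: SyntheticParams


def _smooth_field(shape, sigma_cells, rng) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise normalized to unit variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="wrap")
    s = f.std()
    return f / s if s > 0 else f


def _background_trend(params: SyntheticParams) -> np.ndarray:
    """Smooth regional trend over the domain (scale ≈ the whole grid)."""
    i = np.arange(params.n_lat)[:, None] / max(params.n_lat - 1, 1)
    j = np.arange(params.n_lon)[None, :] / max(params.n_lon - 1, 1)
    return params.background_trend_amplitude * np.sin(np.pi * i) * np.cos(np.pi * j)


def generate_landscape(params: SyntheticParams) -> SyntheticLandscape:
    """Generate a two-epoch synthetic landscape with known causal structure.

    Forest change is near zero (uniform ±5%) except on spatially clustered
    patches (1–3 cells square, sign per the forestation fraction, magnitude
    uniform 15–100%); the baseline forest map is adjusted so both epochs stay
    within 0–100%.  Climate changes follow the structural equations applied
    to the standardized forest change, with cell noise scaled so that the
    *pair-differenced* system matches the standardized-scale coefficients,
    plus a spatially correlated noise field and the shared background trend.
    Second-epoch rasters are first epoch plus change, exactly.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.n_lat, params.n_lon)
    ncells = params.n_lat * params.n_lon

    # baseline forest cover from a smoothed field scaled to [0, 100]
    base = _smooth_field(shape, sigma_cells=5, rng=rng)
    forest1 = 100.0 * (base - base.min()) / max(float(np.ptp(base)), 1e-12)

    # near-zero change everywhere, then grow patches of real change
    dF = rng.uniform(-5.0, 5.0, shape)
    target = int(round(params.change_patch_rate * ncells))
    changed = np.zeros(shape, dtype=bool)
    guard = 0
    while changed.sum() < target and guard < 10 * ncells:
        guard += 1
        ci = rng.integers(0, params.n_lat)
        cj = rng.integers(0, params.n_lon)
        side = int(rng.integers(1, 4))
        sgn = 1.0 if rng.random() < params.forestation_fraction else -1.0
        mag = rng.uniform(15.0, 100.0)
        sl = (slice(ci, min(ci + side, params.n_lat)), slice(cj, min(cj + side, params.n_lon)))
        jitter = rng.uniform(-2.0, 2.0, dF[sl].shape)
        dF[sl] = sgn * np.clip(mag + jitter, 15.0 + 1e-6, 100.0)
        changed[sl] = True
    # make room in the baseline so t2 = t1 + dF stays inside [0, 100]
    forest1 = np.where(dF < 0, np.maximum(forest1, -dF), forest1)
    forest1 = np.where(dF > 0, np.minimum(forest1, 100.0 - dF), forest1)
    forest2 = forest1 + dF

    moments = implied_moments(params)
    noise_sds = moments["noise_sds"]
    _, sd_f = _mixture_moments(params)
    zF = dF / sd_f

    # cell noise at sd/sqrt(2): pair differencing doubles it back to sd^2.
    # The spatially correlated component and the background trend sit outside
    # that budget: they are regional structure at scales much longer than the
    # window, which the pairing is designed to (and does) largely cancel.
    w = params.spatial_noise_share
    range_cells = max(params.spatial_noise_range / params.res, 1.0)
    trend = _background_trend(params)
    z = {"dF": zF}
    for v in ("dAlbedo", "dET", "dLST"):
        mean = np.zeros(shape)
        for (p, resp), c in params.coefficients.items():
            if resp == v:
                mean += c * z[p]
        sd = noise_sds[v]
        eps = rng.standard_normal(shape) / np.sqrt(2.0)
        if w > 0:
            eps += np.sqrt(w) * _smooth_field(shape, range_cells / 2.0, rng)
        z[v] = mean + sd * eps + trend

    geom = dict(origin_lon=params.origin_lon, origin_lat=params.origin_lat, res=params.res)
    full = np.ones(shape, dtype=bool)
    scales = params.scales
    climate1, climate2, true_changes = {}, {}, {}
    baselines = {"dAlbedo": 18.0, "dET": 80.0, "dLST": 25.0}
    for v in ("dAlbedo", "dET", "dLST"):
        delta = z[v] * scales[v]
        t1 = baselines[v] + 3.0 * scales[v] * _smooth_field(shape, sigma_cells=8, rng=rng)
        climate1[v] = GeoGrid(t1, full.copy(), **geom)
        climate2[v] = GeoGrid(t1 + delta, full.copy(), **geom)
        true_changes[v] = GeoGrid(delta, full.copy(), **geom)
    true_changes["dF"] = GeoGrid(dF, full.copy(), **geom)

    fail = {name: rng.random(shape) < params.qc_fail_rate for name in ("LST", "ET", "albedo")}
    qc = {
        "emissivity_error": GeoGrid(np.where(fail["LST"], 0.03, 0.01), full.copy(), **geom),
        "lst_error": GeoGrid(np.where(fail["LST"], 3.0, 1.0), full.copy(), **geom),
        "flag": GeoGrid(np.where(fail["albedo"], 3.0, 0.0), full.copy(), **geom),
        "valid_subpixels": GeoGrid(np.where(fail["ET"], 35.0, 36.0), full.copy(), **geom),
    }
    return SyntheticLandscape(
        forest_t1=GeoGrid(forest1, full.copy(), **geom),
        forest_t2=GeoGrid(forest2, full.copy(), **geom),
        climate_t1=climate1,
        climate_t2=climate2,
        qc=qc,
        true_changes=true_changes,
        params=params,
    )


def landscape_change_layer(landscape: SyntheticLandscape, *, use_qc: bool = True) -> ChangeLayer:
    """Assemble the analysis-ready change layer from a synthetic landscape."""
    qc = landscape.qc
    c1, c2 = landscape.climate_t1, landscape.climate_t2

    def qc_grid(name: str, grid: GeoGrid) -> GeoGrid:
        if not use_qc:
            return grid
        return apply_qc(grid, qc, QCRule(variable=name))

    dF = decadal_change(landscape.forest_t2, landscape.forest_t1)
    dLST = decadal_change(qc_grid("LST", c2["dLST"]), qc_grid("LST", c1["dLST"]))
    dET = decadal_change(qc_grid("ET", c2["dET"]), qc_grid("ET", c1["dET"]))
    dAlb = decadal_change(qc_grid("albedo", c2["dAlbedo"]), qc_grid("albedo", c1["dAlbedo"]))
    return ChangeLayer(dF=dF, dLST=dLST, dET=dET, dAlbedo=dAlb,
                       epochs={"forest": ("t1", "t2"), "climate": ("t1", "t2")})
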