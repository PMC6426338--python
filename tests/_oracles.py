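"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive results by exhaustive enumeration or closed
form, without reusing any pipeline internals beyond the data containers.
"""

import numpy as np

from forestclim import ChangeLayer, WindowSpec
from forestclim.grid import GeoGrid


def brute_force_pairs(dF: GeoGrid, spec: WindowSpec) -> list[tuple[tuple, tuple]]:
    """Exhaustive window scan: (focal_index, ref_index) per window, deduplicated.

    Enumerates every window origin on the stride lattice, every candidate
    cell within it, and picks focal/reference by scanning candidates in
    row-major order, then drops repeated index pairs keeping the first.
    """
    nlat, nlon = dF.shape
    results = []
    for r0 in range(0, nlat - spec.size_lat + 1, spec.stride_lat):
        for c0 in range(0, nlon - spec.size_lon + 1, spec.stride_lon):
            focal, best_f = None, -np.inf
            ref, best_r = None, np.inf
            for i in range(r0, r0 + spec.size_lat):
                for j in range(c0, c0 + spec.size_lon):
                    if not dF.mask[i, j]:
                        continue
                    a = abs(dF.values[i, j])
                    if a > spec.focal_thresh and a > best_f:
                        focal, best_f = (i, j), a
                    if a < spec.ref_thresh and a < best_r:
                        ref, best_r = (i, j), a
            if focal is not None and ref is not None:
                results.append((focal, ref))
    seen, unique = set(), []
    for pair in results:
        if pair not in seen:
            seen.add(pair)
            unique.append(pair)
    return unique


def random_change_layer(rng, nlat, nlon, mask_rate=0.1) -> ChangeLayer:
    """A random change layer with heavy-tailed forest change and partial masks."""

    def g(vals, mask=None):
        if mask is None:
            mask = np.ones_like(vals, dtype=bool)
        return GeoGrid(vals, mask, origin_lon=-60.0, origin_lat=0.0, res=0.05)

    dF = rng.choice([-60.0, -30.0, -10.0, -2.0, 0.0, 2.0, 10.0, 30.0, 60.0], size=(nlat, nlon))
    dF = dF + rng.uniform(-4, 4, (nlat, nlon))
    dF = np.clip(dF, -100, 100)
    mask = rng.random((nlat, nlon)) > mask_rate
    return ChangeLayer(
        dF=g(dF, mask),
        dLST=g(rng.normal(size=(nlat, nlon)), rng.random((nlat, nlon)) > mask_rate),
        dET=g(rng.normal(size=(nlat, nlon)), rng.random((nlat, nlon)) > mask_rate),
        dAlbedo=g(rng.normal(size=(nlat, nlon)), rng.random((nlat, nlon)) > mask_rate),
    )
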