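# forestclim

Tools for quantifying how decadal forest-cover change drives *local*
land-surface temperature (LST) change through its two main biophysical
pathways — surface albedo and evapotranspiration (ET) — and for projecting
LST change under forest-change scenarios.

Clearing or regrowing forest changes the energy balance of the ground
beneath it: less forest usually means higher albedo (more shortwave
reflected, cooling) but much lower ET (less latent-heat export, warming), and
the balance of the two shifts with latitude. The package implements the full
analysis chain for gridded two-epoch data at 0.05° resolution:

1. **Rasters → change layers** (`grid`, `changes`): block-mean upscaling,
   bilinear resampling, per-product quality control (emissivity/LST-error
   thresholds for LST, quality flags for albedo, complete-subpixel counts for
   ET), hierarchical temporal averaging to annual means, and decadal
   differences ΔF, ΔLST, ΔET, Δalbedo (later minus earlier epoch).
2. **Window pairing** (`pairing`): overlapping 5×3-cell search windows each
   contribute at most one *focal* cell (|ΔF| > 15%) and one *reference* cell
   (|ΔF| < 5%) a few km apart. The standardized change of a variable is
   focal minus reference, which cancels the shared regional climate signal
   and isolates the local effect of forest change.
3. **Spatially correlated models** (`gls`): paired mixed models (cell type
   fixed, window random) and GLS fits with exponential, gaussian, rational
   quadratic, spherical or linear residual correlation in (lon, lat) degrees,
   selected by AICc. Under the independence structure the paired model *is*
   the paired t-test.
4. **Piecewise SEM** (`sem`): the causal chain

   ```
   ΔF → Δalbedo,   ΔET ~ ΔF + Δalbedo,   ΔLST ~ ΔF + Δalbedo + ΔET
   ```

   fitted equation-by-equation by GLS; standardized path coefficients
   (raw × SD(x)/SD(y)); effect decomposition — direct effect plus the three
   indirect pathways ΔF→Δalbedo→ΔLST, ΔF→ΔET→ΔLST, ΔF→Δalbedo→ΔET→ΔLST,
   whose sum with the direct link is exactly the total effect; d-separation
   tests with Fisher's C = −2·Σ ln pᵢ ~ χ²(2k) for pruned models.
5. **Scenario projection** (`projection`): per cell,
   `ΔLST_pred = total_std × (ΔF / SD_ΔF) × SD_ΔLST`.
6. **Synthetic data** (`synthetic`): seeded landscapes and pair tables with
   known structural coefficients, providing ground truth for every stage.

## Worked example

```python
from forestclim import (
    SyntheticParams, generate_landscape, landscape_change_layer,
    find_pairs, pairs_to_frame, fit_path_model, effects_decomposition,
    CorrelationStructure,
)

params = SyntheticParams(seed=42, n_lat=200, n_lon=200)   # total effect −0.64
land = generate_landscape(params)
pairs = pairs_to_frame(find_pairs(landscape_change_layer(land)))
model = fit_path_model(pairs, structure=CorrelationStructure("rational_quadratic"))
dec = effects_decomposition(model)
print(f"n = {model.n} pairs")
print(f"direct {dec.direct:+.3f}  indirect {dec.indirect_sum:+.3f}  total {dec.total:+.3f}")
print({k: round(v, 3) for k, v in model.r2.items()})
```

prints

```
n = 865 pairs
direct -0.255  indirect -0.403  total -0.658
{'dAlbedo': 0.274, 'dET': 0.277, 'dLST': 0.67}
```

The generating landscape was built with a direct standardized effect of
−0.23 and a total of −0.64: a one-SD gain in forest change cools the surface
by 0.64 SD of ΔLST, and the fitted model recovers that within sampling error
from the rasters alone — including QC masking, window pairing and spatially
correlated noise. The `r2` entries are the per-equation coefficients of
determination of the three component regressions.

The same steps run from the shell:

```bash
forestclim simulate --seed 42 --size 200x200 --out land.nc
forestclim pairs --landscape land.nc --out pairs.csv
forestclim sem-fit --pairs pairs.csv --structure ratio --out model.json
forestclim project --model model.json --scenario bau.nc --out pred.nc
```

## Limitations

The statistical machinery assumes linear relationships, Gaussian errors and
a stationary effect over projection horizons; precipitation and cloud
feedbacks are outside the model. Distance-based correlation structures
require distinct observation locations, so path-model fits keep one pair per
focal cell when several overlapping windows select the same focal cell.
See `docs/methods.md` for the full model description and design choices.
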