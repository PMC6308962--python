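# tracheidnir

Vis-NIR spectral de-noising and PLS calibration of wood tracheid length.

Visible/near-infrared (Vis-NIR) spectroscopy can predict wood anatomical
traits — here the length of tracheids, the water-conducting cells whose
dimensions drive pulp and timber quality — without wet-lab maceration. The
catch is spectral noise: the calibration chain is only as good as the
de-noising that precedes it. This package implements that chain end to end
for ring-resolved larch-like cohorts:

* **LWT** — a lifting-scheme wavelet transform (split/predict/update) with
  multilevel decomposition, equivalent to the classical convolution DWT,
  and de-noising by a global fixed threshold
  `λ = σ̂·√(2 ln n)`, `σ̂ = median(|d₁|)/0.6745`, hard by default;
* **LCM** — local correlation maximization: per wavelength, pick the
  decomposition level whose de-noised absorbance correlates best (in |r|)
  with tracheid length on the calibration set, and assemble a hybrid
  spectrum from the winners;
* comparator smoothers — moving average, Savitzky-Golay, loess, lowess —
  swept over segment sizes 3..25;
* **PLS1 (NIPALS)** calibration with the chemometrics diagnostics
  R², RMSE (÷n), MAPE %, SEC (bias-corrected, ÷(n−1)) and RPD = SD/SEC;
* a **synthetic cohort generator** (7 trees, every ring ≤ 20 and every 2nd
  ring after, 164 samples split 117/47, Gompertz radial growth, Gaussian
  absorption bands affine in the trait) so the whole study runs without
  any proprietary spectra.

## Worked example

The numbered drivers under `analysis/` run the study stage by stage and
write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_screen_wavelets.py
python analysis/03_sweep_order_and_level.py
python analysis/04_sweep_smoothers.py
python analysis/05_final_models.py
```

`01_simulate_cohort.py` prints the cohort design:

```
cohort: 164 samples, 2048 wavelengths (350-2397 nm)
set             n     max     min    mean      sd    skew    kurt
calibration   117   4.246   1.896   3.366   0.612  -0.698  -0.518
prediction     47   4.340   2.202   3.418   0.737  -0.563  -1.284
total         164   4.340   1.896   3.381   0.649  -0.630  -0.810
Pearson r(ring, tracheid length) = 0.886
```

164 ring-level samples from 7 trees, split 117/47; tracheid length rises
from ~1.9 mm near the pith toward a ~4.3 mm plateau, hence the strong
ring correlation and mild negative skew.

`05_final_models.py` fits the four final calibrations (PCs = 7) and
compares them on the calibration and held-out sets:

```
  model  pcs   Rc2  RMSEC  MAPEc   SEC  RPDc   Rp2  RMSEP   SEP  RPDp
    Raw    7 0.856  0.232  5.870 0.233 2.633 0.780  0.342 0.343 2.149
    LWT    7 0.850  0.236  5.981 0.237 2.582 0.780  0.342 0.343 2.151
LWT-LCM    7 0.852  0.234  5.944 0.235 2.602 0.782  0.341 0.342 2.158
     WT    7 0.850  0.236  5.981 0.237 2.582 0.780  0.342 0.343 2.151
```

Reading the row for LWT: de-noised spectra explain 85% of calibration
variance with a 0.236 mm RMS error; an RPDc of 2.6 (reference sd over
corrected error) marks a usable screening model, and Rp² = 0.78 shows it
generalizes to the held-out set. LWT and WT rows agree to 1e-15 — the
lifting path and the convolution filter bank are the same transform, which
the pipeline exploits as a built-in regression check. On synthetic cohorts
the de-noising margins between pretreatments are small (fractions of a
percent of Rc²), as they are in real wood NIR calibrations.

The same operations are scriptable via the `tracheidnir` CLI
(`simulate`, `denoise`, `smooth`, `lcm`, `fit`, `compare`) on wide CSV
spectra tables (`sample_id, tree_id, ring, set, tracheid_mm, A350..A2397`).

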