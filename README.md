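# osteospec

NIR spectroscopy chemometrics and micro-CT morphometry of human subchondral
bone, with a synthetic cohort generator.

## The problem

Changes in the bone directly beneath articular cartilage — thickening of the
subchondral plate, remodelling of the trabecular network — accompany and may
precede cartilage degeneration in osteoarthritis. Near-infrared (NIR)
diffuse-reflectance spectroscopy can probe through cartilage into the
subchondral bone, raising the question: **can spectra acquired at the
cartilage surface predict the morphometry of the bone underneath?**

`osteospec` implements the complete analysis for this question:

* **Spectral pre-processing** — absorbance from raw reflectance/dark/white
  counts, `A(λ) = -log₁₀((R-D)/(W-D))`; repetition averaging; restriction to
  the three tissue optical windows (OW1 650–950 nm, OW2 1100–1350 nm, OW3
  1600–1870 nm); multiplicative scatter correction (MSC); Savitzky–Golay
  smoothing derivatives.
* **PLS1 regression** — single-response partial least squares via NIPALS,
  with 10-fold cross-validation over a component grid, a parsimony rule for
  choosing the number of latent variables, and the standard chemometrics
  metrics: RMSECV and RMSEC as percent of the reference range, and R² as
  squared Pearson (or Spearman, for non-normal responses) correlation.
* **Bone morphometry** — from binary micro-CT voxel volumes: subchondral
  plate thickness (Sb.Th) and trabecular thickness (Tb.Th) by the
  model-independent largest-inscribed-sphere definition, bone volume
  fraction (BV/TV) by voxel counting, and structure model index
  (SMI = 6·V·S′/S², ≈0 for plates, 3 for rods, 4 for spheres), plus the
  plate/trabecular segmentation with the intracortical pore rule.
* **Group statistics** — D'Agostino–Pearson normality gating into
  ANOVA/Kruskal–Wallis across anatomical locations and t-test/Mann–Whitney
  between cartilage-degeneration classes (Mankin score < 4 vs > 4), with
  mean ± 95 % CI summaries.
* **Synthetic cohort generator** — because no such cadaver dataset is
  publicly deposited, the package generates a statistically analogous cohort
  (48 samples, 13 donors, 4 knee locations) with known ground truth: spectra
  whose first-optical-window band amplitudes encode the morphometric
  parameters, and voxel bone phantoms (plate slab with intracortical pores
  over a trabecular rod lattice) matching the drawn Sb.Th/Tb.Th/BV/TV.

## Worked example

```python
from osteospec import CohortConfig, generate_cohort, extract_window, DEFAULT_WINDOWS, PLS1
from osteospec.pipeline import RunConfig, run_window_comparison

cfg = CohortConfig(seed=1)
ds, _, truth = generate_cohort(cfg, with_volumes=False)

run = RunConfig(cohort=cfg, cv_seed=1)
results = run_window_comparison(ds, truth, run)
print(results[results.best_window].to_string(index=False))
```

```
window     parameter  n_components  cv_r2_pct  rmsecv_pct  rmsec_pct
   OW1      sb_th_mm             3  86.935390    7.688301   6.052091
   OW1      tb_th_mm             2  83.670304   10.032607   8.696415
   OW1 bvtv_fraction             3  84.391706    9.601374   7.500048
   OW1           smi             2  61.361289   12.984941   9.899418
```

The first optical window is flagged best for all four parameters: its bands
carry the morphometry signal by construction, while the second and third
windows contain only morphometry-independent absorption — the cross-validated
R² there collapses to a few percent. `n_components` is the number of PLS
latent variables chosen by the parsimony rule (smallest count within 5 % of
the minimum RMSECV); `rmsecv_pct`/`rmsec_pct` are cross-validated and
calibration errors as percent of each parameter's range.

A single model fit looks like statsmodels:

```python
ow1 = extract_window(ds, DEFAULT_WINDOWS[0])
res = PLS1(truth["sb_th_mm"].to_numpy(), ow1.absorbance).fit(ncomp=3)
print(res.summary())
```

```
PLS1 Regression Results
==============================================
No. observations:                           48
No. predictors:                            301
No. components:                              3
RMSEC (% of range):                      9.302
R2 calibration (%):                     80.845
Intercept:                            0.411394
==============================================
```

The same workflow is available from the shell:

```bash
osteospec all --out run1 --seed 1        # simulate + fit + stats + figures
osteospec simulate --out cohort --seed 2 # cohort only (CSV + TIFF volumes)
```

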