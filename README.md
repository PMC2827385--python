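# aortaflow

Quantification of misdirected systolic aortic outflow from
velocity-encoded (phase-contrast) cardiovascular MR, for studying the
link between abnormal flow patterns and aortic dilatation in bicuspid
aortic valve (BAV) patients.

In a normal aorta the peak-systolic flow jet runs along the axis of the
left ventricular outflow tract (LVOT); a bicuspid valve deflects it
toward the vessel wall.  The package measures that deflection as a
single angle, relates it to aortic-root size, and quantifies how
reproducibly both can be measured:

* **Flow-jet angle** `θ = ∠(v̄, d)` — the angle between the mean
  systolic jet vector `v̄` (unweighted average of the 3-component
  velocity vectors over all forward-flow pixels inside the aortic ROI
  of a mid-sinus slice) and the LVOT channel axis `d`.  The axis is
  triangulated from two oblique LVOT views: in each view the vector
  average of two manually drawn proximal→distal wall segments gives the
  *projection* of the axis onto that plane, and
  `d ∝ (p_A × n_A) × (p_B × n_B)` lifts the two projections back to 3-D.
* **Morphometry** — maximal cross-sectional diameters at the aortic
  valve (AOV), sinus of Valsalva (SOV), sinotubular junction (STJ) and
  ascending aorta (AAO), each normalized as `D / √BSA` with the Haycock
  body-surface-area formula `BSA = 0.024265 · W^0.5378 · H^0.3964`.
* **Cohort statistics** — pooled Student's t-tests for group
  comparisons, Pearson r with the exact `t = r√(n−2)/√(1−r²)` p-value,
  Spearman rank correlations for the (non-normal) plasma biomarkers
  MMP-2/9 and TIMP-1/2, Shapiro–Wilk normality checks and a Mahalanobis
  outlier screen (report-only).
* **Observer agreement** — within-subject replicate SD
  `√(Σ(m₁−m₂)²/2n)`, coefficient of variation, Lin's concordance
  correlation coefficient and Bland–Altman 95% limits of agreement.
* **Synthetic data** — tube phantoms with a jet tilted by a known
  ground-truth angle, and simulated BAV/control cohorts whose group
  means and angle–diameter correlation structure are calibrated
  analytically, so the entire pipeline runs and is tested with no
  patient data.

## Worked example

Simulate a phantom with a 16° jet tilt and measure it back through the
full landmark → axis → jet path:

```bash
aortaflow simulate-phantom --out /tmp/ph --tilt 16 --seed 3
aortaflow jet-angle --velocity /tmp/ph --landmarks /tmp/ph_landmarks.json
```

```json
{
 "angle_deg": 16.00000000000032,
 "n_pixels": 716,
 "mean_speed": 99.99999999999879
}
```

The numbered scripts under `analysis/` run the whole study on simulated
data (each writes its tables under `results/`):

```bash
python analysis/01_phantom_recovery.py   # tilt/noise recovery sweep
python analysis/02_simulate_cohort.py    # 18 BAV + 10 control subjects
python analysis/03_cohort_statistics.py  # group tests + correlations
python analysis/04_reproducibility.py    # agreement statistics
python analysis/05_printed_statistics.py # published-summary recomputation
```

Typical output (seed 0):

```
noise-free recovery: worst |error| = 1.60e-13 deg
at 5 cm/s noise:     worst mean |error| = 0.142 deg

flow angle: BAV 16.49 vs control 10.71 deg (p = 9.49e-05)
pooled   significant angle-diameter correlations: AOV, SOV, STJ, AAO

pooled_AAO   r= 0.645 N=28  ->  p = 0.000
bav_AAO      r= 0.536 N=18  ->  p = 0.022
intra-rater flow-angle CV: 12.0 %
```

The phantom errors show the geometric pipeline is exact and that
realistic velocity noise perturbs the angle by well under a degree; the
cohort lines show the simulated study reproduces the group separation
and the pooled angle–diameter correlations it was calibrated to; the
last block shows the closed-form statistics reproduce published
correlation p-values from their printed (r, N) pairs.

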