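# Methods

## The misdirection metric

The quantity at the center of the package is the angle between the
peak-systolic flow jet and the LVOT channel axis.

**Jet vector.**  On a velocity-encoded slice placed centrally in the
sinuses of Valsalva, each pixel carries a 3-component velocity (cm/s,
patient frame).  The jet vector is the *unweighted* arithmetic mean of
the velocity vectors over all pixels that are (a) inside the manually
traced aortic ROI and (b) flowing forward.  "Forward" is defined as a
positive velocity component along the reconstructed channel axis; a
`reference="normal"` switch substitutes the slice normal, which
coincides with the axis only when scan planning is perfect.  The axis is
the analysis reference throughout, which is why it is the default.
Averaging is per-pixel with no speed weighting: a pixel's influence is
its own vector, nothing more.

**Channel axis.**  The axis is not measured directly.  In each of two
oblique LVOT views, two wall segments are drawn from the valve plane to
the sinotubular ridge on either side of the sinus; their vector average
is the projection of the channel direction onto that view.  A direction
`d` projecting parallel to `p_A` in plane A must be orthogonal to
`p_A × n_A`, so the unique direction consistent with both views is
`d ∝ (p_A × n_A) × (p_B × n_B)`, normalized, with the sign fixed by
`d · (p_A + p_B) > 0` (both projections point distally by the landmark
orientation convention).  View pairs with `|n_A × n_B| < 0.05` are
rejected as degenerate: the acquisition protocol makes the two views
orthogonal, so near-parallel planes can only mean corrupt metadata.
The projection→reconstruction round trip is exact; the test suite
verifies < 1e-6° worst-case error over 1000 random direction/plane-pair
draws, and rotational invariance of the whole angle computation.

All positions live in a right-handed RAS frame in millimetres; pixel
coordinates are (row, col) pairs mapped through
`origin + row·s_r·row_dir + col·s_c·col_dir`.

## Morphometry

The diameter at each aortic level is operationalized as the **maximum
Feret diameter** of the traced contour — the largest vertex-to-vertex
distance in patient millimetres.  The source protocol reports "largest
observed perpendicular cross-sectional diameter" without an algorithm;
max Feret is the standard computational reading, and a
`through_centroid=True` option restricts to chords through the vertex
centroid for sensitivity analysis.  The ascending-aorta measurement on
the candy-cane view takes the largest chord perpendicular to a
user-supplied centerline polyline, sampled between the projections of
the STJ marker and the brachiocephalic-trunk marker onto that
centerline.

Body surface area uses the Haycock formula
(`0.024265 · W^0.5378 · H^0.3964`, W in kg, H in cm); indexed diameters
are `D/√BSA`.  Note that averaging per-subject indexed values differs
slightly from indexing the group mean diameter by the group mean BSA —
group tables are always computed the first way.

## Statistics

* Group comparisons: pooled-variance Student's t (Welch behind a flag).
  A summary-statistic variant recovers SDs from printed SEMs
  (`SD = SEM·√n`) so published group rows can be re-tested.
* Pearson p-values come from the exact `t = r√(n−2)/√(1−r²)` transform;
  `pearson_p_from_r` applies the same transform to printed (r, N)
  pairs.  Spearman uses mid-ranks for ties and the same t transform on
  ρ; an exact permutation p is available behind a flag for n ≤ 8 (full
  enumeration; larger n falls back to the approximation with a
  warning).
* The Mahalanobis screen flags rows with D² above the χ²(k) quantile at
  1−α (default α = 0.025).  Flags are reported only; no row is ever
  dropped, matching the study protocol.
* Agreement: replicate SD is the one-way within-subject SD for
  duplicates, `√(Σd²/2n)`; CV pairs each quantity's replicate SD with
  the grand mean of all its measurements; Lin's CCC uses 1/n moment
  normalization (the original estimator), giving `|CCC| ≤ |r|` with
  equality only for an identity fit; Bland–Altman limits use the fixed
  1.96 multiplier, not a t quantile, per the cited convention.

## Synthetic data

**Phantom.**  A straight rigid tube (default radius 15 mm) carries a
jet tilted ψ ∈ [0°, 60°] from the tube axis at a configurable azimuth,
with plug or parabolic speed profile (default peak 100 cm/s) and
optional i.i.d. Gaussian noise per velocity component.  The mid-sinus
slice is a 48×48 grid at 1 mm spacing (≈ 700 in-lumen pixels); the two
LVOT views contain the tube axis with wall landmarks parallel to it, so
the axis reconstruction is exact and any measured-angle error isolates
the jet-averaging step.  Scalar profile weighting leaves the mean
direction unchanged, so noise-free recovery is exact to rounding for
both profiles; noise of σ per component perturbs the mean by σ/√N per
component, about 0.2° at σ = 5 cm/s — the basis of the 1° tolerance
used in the recovery tests.

**Cohort.**  Subjects are drawn from a two-group linear-Gaussian model.
Group flow-angle means/SDs and the four-level adjusted diameter
means/SDs default to the published summaries, with printed SEMs
converted to SDs (angles: 3.69° BAV, 4.08° control).  Diameters follow
`d = μ_d(group) + β·(angle − ā) + ε`.  Decomposing the pooled
covariance into a between-group part B (fixed by group means and
sizes) and a within-group part β·V_w gives the calibration
`β = (r·√(Var_a·Var_d) − B)/V_w`, with the residual SD chosen to
preserve the published within-group diameter SDs; the pooled
correlation then matches its target in expectation at any sample size,
and targets that would need negative residual variance are rejected at
validation.  Rare negative angle draws are reflected (an angle is a
magnitude).  Heights and weights are N(168, 9) cm and N(62, 11) kg,
clipped to plausible adolescent ranges, giving BSA ≈ 1.7 m² as in the
study population.  Biomarkers (BAV rows only) use a Gaussian-copula
link (latent ρ = 2·sin(π·ρ_s/6)) to one diameter level followed by a
lognormal marginal transform matched to the printed mean/SEM — monotone,
so the targeted Spearman correlation survives, and right-skewed, so the
marginals fail normality tests as the assayed ones did.  MMP-9 and
TIMP-1 are generated independent, matching their null correlations.

**What the simulation does not emulate.**  Velocity noise is Gaussian
per component (no Rician magnitude model — adequate for
velocity-difference data), the tube is straight and rigid (no sinus
bulge, curvature, pulsatility or partial-volume effects at the wall),
the angle–diameter link is linear-Gaussian where the study only asserts
correlation, and landmark/contour placement is exact rather than
observer-noisy except where rater noise is explicitly simulated.
Passing tests therefore demonstrate correctness of the measurement and
statistical machinery under the stated generative model, not clinical
accuracy on scanner data.

## Numerical and design choices

* Normalization rejects vectors with norm < 1e-9; arccos arguments are
  clamped to [−1, 1]; landmark segment sums below 1e-6 of the segment
  scale raise an inconsistent-landmarks error (anti-parallel tracing).
* Peak-systole phase is an explicit input; `pick_peak_phase` chooses
  the phase maximizing mean forward speed when unspecified, skipping
  phases with no forward flow.
* Zero-variance t-test inputs follow the conventions t = 0/p = 1 (equal
  means) and |t| = ∞/p = 0 (unequal); `|r| ≥ 1` printed inputs map to
  p = 0 with a warning.
* Velocity datasets are NIfTI (`<base>.nii`, shape rows×cols×phases×3)
  plus a JSON sidecar that is authoritative for plane geometry, VENC,
  units and the run-length-encoded ROI; geometry orthogonality and the
  cm/s unit tag are validated on read.  Landmark JSON round-trips
  bit-exactly (floats serialized at `repr` precision).
* Report CSVs round angles and millimetres to 0.01 and p-values to 3
  significant figures; JSON outputs keep full precision.  Every CLI run
  writes a manifest (tool version, seed, input digests, parameters);
  fixed seeds make all outputs byte-reproducible.

## Problem sizes

The test suite and the acceptance script use 48×48 phantom grids
(24×24 for the noise-sweep repetitions), cohorts of 28 subjects for
study-scale checks, n = 2000 for correlation-recovery checks and
n = 10⁵ for calibration verification, 500 seeds for the Fisher-z
coverage estimate, and 1000 draws for the geometry round-trip bound.
These sizes put Monte-Carlo error well below the asserted tolerances
while keeping a full run in the order of seconds.

## Known limitations

At the study's n = 18/10, individual simulated cohorts show substantial
sampling spread in within-group correlations (a given seed may find
fewer significant BAV-only levels than the pooled analysis, as the
underpowered subgroup analysis would in practice).  The exact Spearman
permutation option is limited to n ≤ 8.  DICOM ingestion, image
registration, automatic landmark/contour detection and 4-D flow
reconstruction are out of scope: landmarks, ROIs and phase selection
are inputs, as they were manual operations in the source protocol.
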