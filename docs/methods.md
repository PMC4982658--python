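# Methods

`facomp` analyses the molecular composition of focal adhesions measured by
multiplexed (cyclic immunofluorescence) imaging.  Its core question: when
two categories of adhesions are compared — small versus big, young versus
old, sparse versus dense — did the *noise* in their composition change, or
only their *diversity*?  This note records the models, the statistics, the
numerical choices, and what the synthetic validation does and does not
show.

## The noise/diversity decomposition

For each adhesion category the package computes, per labeled component,
the coefficient of variation (CV = sample sd / mean) of the component's
density across adhesions, and, per component pair, the squared Pearson
correlation r² between their densities.  Two latent sources inflate the
CV:

* **diversity** — differences in local cues and maturation state, modeled
  as a single factor multiplying the densities of *all* components of an
  adhesion together;
* **noise** — stochastic realization of alternative binding options,
  independent per component.

Both raise the CV, but diversity *raises* pairwise r² (shared factor)
while noise *lowers* it.  Comparing categories 1 → 2 via

* `Δlog(CV₁,CV₂)`: per component `log(CV₂/CV₁)`, averaged first over
  datasets (only datasets with ≥ 5 adhesions in both groups), then over
  components;
* `Δ(r₁²,r₂²)`: per pair `r₂² − r₁²`, averaged the same way,

the joint signs decide the verdict: (−, +) noise lower in 2; (+, −) noise
lower in 1; (+, +) diversity higher in 2; (−, −) diversity higher in 1.
If either |mean| is below its standard error of the mean, the sign is
insignificant and the comparison is *inconclusive*.  The SEM is taken
between dataset means (n = qualifying datasets); with a single qualifying
dataset it falls back to the spread between components (or pairs) within
that dataset.

Numerical conventions: CVs are computed on raw densities of the rows that
survive outlier removal (z-scored columns have zero mean, so their CV is
undefined); r² is computed on Box-Cox z-scores where available, since
linearity of the pairwise scatters is what justifies Pearson correlation.
This raw-CV choice is switchable (`delta_log_cv` accepts any table
columns).  A Fano-factor variant (`delta_fano`, variance/mean in place of
CV) is provided as a robustness check: it is not scale-free, so agreement
of its sign with `Δlog CV` indicates the verdict is not an artifact of
mean shifts.

## The stochastic assembly simulator

`assembly_sim` validates the sign rules on models where truth is known.
Each simulated adhesion draws a number of binding sites `N` (uniform /
truncated-normal / Poisson; "diversity" = the width of this distribution)
and, per recruited protein, a binding probability `p` drawn once per
adhesion from a uniform window of width `w` around its mean ("noise" =
`w`), clamped to [0, 1]; occupancy is then a binomial realization.
Topologies: *noncompetitive* (independent binomials, optionally with
unequal per-protein site stoichiometry), *competitive* (one multinomial
draw per adhesion over the `N` shared sites, so Cov(B,C) = −N·p_B·p_C at
fixed N), and *multistep* (a layer-k protein's count is the site count for
the layer-(k+1) proteins it recruits, so noise accumulates along the
chain).  Degenerate draws are clamped: site counts round to nonnegative
integers, probability vectors whose sum exceeds 1 under competitive noise
are renormalized per adhesion.

`inference_validation_grid` sweeps ordered pairs of (noise, diversity)
levels, runs the full Δ statistics on each simulated pair, and scores the
fraction of replicate verdicts consistent with the imposed change.  When
both axes change at once, any verdict compatible with the unambiguous sign
component counts as consistent (a simultaneous noise and diversity
increase guarantees CV up but leaves Δr² open).  Default validation scale:
n = 2000 adhesions per simulated category, 20 replicates per cell — at
this size the imposed changes are recovered in ≥ 90% of replicates for
both topologies.

## Image analysis

The imaging chain mirrors a standard adhesion-site workflow:

1. **Registration** — single-step upsampled Fourier cross-correlation
   (scikit-image `phase_cross_correlation`), default upsampling 100
   (0.01 px accuracy); each labeling cycle shares one translation.
2. **Background subtraction** — high-pass: image minus its Gaussian blur
   (default width 50 px), clipped at zero.  A plain smoothed-background
   estimate is biased upward near bright objects (their intensity leaks
   into the blur); once a segmentation exists, `analyze_stack` therefore
   re-estimates the background by normalized convolution over background
   pixels only.  On crowded fields this removes a several-percent
   density underestimate.
3. **Segmentation** — watershed on the inverted smoothed marker image.
   Seeds are regional maxima with *relative* prominence (h-maxima on the
   log image, `peak_merge_ratio` = 0.8): two maxima seed separate regions
   only if the valley between them dips below 80% of the lower peak.
   This keeps the shallow ripple along one elongated adhesion from
   oversplitting it while still dividing touching adhesions with distinct
   peaks, independent of brightness.  Regions are trimmed to their
   half-maximum contour (`region_half_max` = 0.5) and regions under 5 px
   dropped.  All parameters live in `SegmentationParams`.
4. **Measurement** — per region: pixel count, area (pixel count × pixel
   size²), eccentricity of the second-moment ellipse (inter-focal
   distance over major axis length; 0 = circle), and per channel the
   density = mean intensity over the region's pixels.
5. **Tracking** — backward from the fixation frame: maximum pixel-overlap
   match (ties: larger overlap fraction, then nearer centroid), else the
   nearest centroid within 10 px, evaluated after applying the
   registered inter-frame shift.  Regions absent at fixation are
   excluded.  Ages map the first-appearance frame to 3'–12' at the
   3-minute frame interval; adhesions present in every frame are >12'.
6. **Dynamics** — >12'-old adhesions are classified by the Pearson r of
   total marker intensity against time over the last four pre-fixation
   frames: r > 0.7 assembling (AS), r < −0.7 disassembling (DS),
   otherwise stationary (ST); constant traces are ST.

An equal-pixel-sampling control (`equal_pixel_control`) recomputes
densities from a random pixel subset per adhesion — either matching the
*mean* sampled count across area categories or a fixed count (default
10 px) for every adhesion — and reruns the inference, checking that an
area-axis verdict is not driven by pixel-count differences.

## Preprocessing

Per dataset, each component column is Box-Cox transformed,
`x(λ₁,λ₂) = ((y+λ₂)^λ₁ − 1)/λ₁` (log for λ₁ = 0), with λ₁ the mean of
per-component maximum-likelihood estimates (profile likelihood on a grid
over [−2, 2], step 0.01; the power branch is evaluated via `expm1` so the
transform stays accurate and monotone as λ₁ → 0).  λ₂ is 0 for positive
columns, else the smallest shift making them positive.  Transformed
columns are z-scored, and Tukey outliers (outside [Q₁ − 2·IQR,
Q₃ + 2·IQR] of the z vector, quartiles by linear interpolation) are
removed in a single pass; a row is dropped if flagged in any component,
keeping the matrix rectangular.

Adhesions are then categorized by area, eccentricity and mean normalized
density with three-class Otsu thresholding on values pooled across all
datasets.  Otsu runs on a 256-bin histogram with exhaustive cut search;
ties — which arise whenever a cut can move freely across empty bins
between separated modes — resolve to the middle of each gap, so
thresholds land between modes rather than at their edges.  The density
score averages the per-dataset z-scores of the eight protein components
(the two phosphosite channels report modification state, not amount, and
are excluded).  The published thresholds for the original datasets
(2.71/6.17 µm², 0.86/0.92, −0.42/0.282) are data-dependent and kept only
as reference constants.

## The high-order relation screen

For a chosen target component, every non-empty subset of the remaining
components (511 for a 10-component panel) is an input set for a small
multilayer perceptron (three hidden layers, each as wide as the input,
tanh units).  Per subset, `sessions` independent training sessions each
draw a random 40/30/30 train/validation/test split; optimization is
quasi-Newton (L-BFGS) in chunks of 20 iterations with validation-based
early stopping (best-validation weights kept, at most 2 chunks — enough
for these small networks, and the stopping is what controls overfit, not
exhaustive convergence).  The subset's final performance is the MSE/R² of
the *ensemble* (session-mean) prediction on the complete dataset; a
single best-validation network is available via `aggregate="best"`.
Random forests (500 trees, all inputs candidate at every split) provide
an independent method for comparison of the R² landscape.

The subsets form a Hamming-1 lattice.  For each neighboring pair a
two-sided variance-ratio F-test compares the per-adhesion squared errors
of the two ensemble predictions (the error samples are treated as scaled
χ² variates; ratio of means referred to F(n, n)); at α = 0.05 an edge is
added toward the better node, otherwise no edge.  Each node is scored
`L = L1/(L1+L2)`, with L1/L2 the shortest distances (over existing edges,
ignoring direction — direction-respecting distances are undefined for
most nodes) to the closest single-component node and the closest
null-out-degree node.  A subset is reported as a high-order relation if
L > 0.7 in at least 4 of the 6 datasets with at least 2 from each
labeling order; relations with mean ensemble R² < 0.6 are flagged weak.

## The synthetic study generator

No image data are published with the emulated study, so `synthetic_data`
generates the study design at desk scale: 6 datasets (3 repeats × 2
labeling orders), default 240 adhesions each.  Densities follow the same
effective model the inference assumes — a lognormal per-adhesion common
factor (diversity, sd 0.4 in log space) times independent per-component
lognormal noise (sd 0.25) — so Box-Cox λ ≈ 0 is a recoverable truth.  A
noise-area coupling (noise sd scaled by `(area/median)^-0.5`) reproduces
the headline phenomenon of noise reduction in growing adhesions, making
the full pipeline demonstrable end to end.  Areas are lognormal
(median 2 µm²) times an age factor (1.5 per 3-minute age step) with a
soft cap near 10 µm²: adhesions grow as they mature and saturate at a
physiological maximum.  The cap matters — Otsu on an uncapped lognormal
pool isolates a handful of extreme outliers as the "large" class; with
saturating growth the S/M/L split is roughly 50/40/7% and the pooled
thresholds (~3.4/7.8 µm²) resemble published adhesion-size categories.

Image sets render adhesions as uniform-intensity ellipses (density =
mean intensity over the mask by construction) in a 512 × 512 field at
0.15 µm/px — the scale of a 40×/CCD system — with 25 adhesions per
field.  Sparser fields than the density tables assume are deliberate:
high-pass background estimation is biased on crowded fields, and the
round-trip guarantee (area within 15%, density within 5% per adhesion)
is a property of the algorithm, not of scene crowding.  The marker
time-lapse (5 frames, 3-minute spacing) encodes appearance frames by age
and AS/ST/DS intensity trends; each labeling cycle's channels carry a
known translation to exercise registration.  Not modeled: point-spread
blur, photobleaching, antibody steric hindrance, intensity noise beyond
optional Gaussian read noise.

**What passing the synthetic validation shows — and does not.**  It shows
the statistics are computed exactly (closed-form fixtures at 1e−12), the
sign rules recover imposed noise/diversity changes under every simulated
topology, the imaging chain measures what was rendered, and the screen
recovers planted high-order structure.  It does not show that real CycIF
data satisfy the model assumptions (single common diversity factor,
linear pairwise scatters, registration-stable acquisitions), and verdicts
on real data inherit those assumptions.

## Problem sizes and determinism

Default validation scales — simulation grids at n = 2000 × 20 replicates,
multistep checks at n = 5000 × 10, planted screens at n = 5000 with 50
sessions per subset over a 5-component universe (full 10-component
screens use the same code with `sessions=500` as the full-scale setting) —
were chosen so the complete validation runs on a single CPU in tens of
minutes.  The acceptance script scales the planted screen to 3
repetitions at n = 3000 for the same reason.  Every stochastic component
takes an explicit seed; the pipeline derives per-stage seeds from one
global seed by hashing, and reruns with the same configuration are
byte-identical (stage outputs carry a config-hash sidecar and are reused
on rerun).

## Known limitations

* The ≥ 5-adhesions-per-group rule can silently drop datasets from a
  comparison; `DeltaMeasure.n_datasets` reports how many survived.
* The F-test treats per-adhesion squared errors as independent; errors of
  nested subsets are correlated, so edge significance is approximate —
  adequate for orienting a lattice, not for p-value reporting.
* Otsu-based categorization on heavily skewed pooled values can produce
  very unbalanced classes; inspect the thresholds the pipeline logs.
* The perceptron sessions are capped at 40 L-BFGS iterations; raising
  `chunk_iter`/`max_chunks` trades runtime for slightly better absolute
  R² (relative ordering across subsets, which drives the DAG, is stable).
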