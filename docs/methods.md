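# Methods

This note documents the models, algorithms and numerical choices
behind the package, what the synthetic data generator does and does
not emulate, and the limits of what the test suite can show.

## Photometry model

TMRM in non-quenching mode reports ΔΨm as a monotone (approximately
Nernstian) intensity signal; the pipeline works entirely in relative
units and never attempts millivolt calibration. The per-object
quantity is the background-ring-corrected mean intensity

> corrected = mean(signal over cell region) − mean(signal over ring),

which is exactly invariant to adding a constant to the image, and,
after division by a basal reference, invariant to multiplicative gain.
Negative corrected values are retained before averaging — clipping
would bias dim wells upward — but a group whose *basal* mean is ≤ 0
cannot be normalized and raises instead of propagating sign flips.

Geometry: the cell region is the nucleus mask dilated outward by
`r_cell` px (default 8), with growth between competing neighbors
shared by nearest-nucleus assignment; the ring is the annulus from
`r_gap` (2) to `r_gap + r_ring` (2+5) px outside the cell region,
excluding every cell region (rings of neighbors may overlap each
other). Where a ring is fully crowded out, the field-level 5th
percentile of non-cell pixels substitutes, and the row is flagged.
The instrument software whose role this pipeline fills does not
document its region geometry, so all three radii are configuration.

## Nuclear segmentation

Gaussian smoothing (σ = 2 px) → threshold → fill holes → remove
objects < 30 px → optional splitting of touching nuclei → optional
border-object removal (on by default; truncated regions bias means).
Three threshold rules are available: Otsu (default), a fixed value,
and a "relative" rule (background + 12% of the robust p5–p99.5 range)
used where dim single nuclei share a field with structures orders of
magnitude brighter (spheroid fields, mixed-brightness co-cultures) —
regimes where Otsu's two-class assumption fails.

Touching nuclei are split by marker-controlled watershed seeded at
local maxima of the smoothed image and flooded on its inversion.  A
distance-transform watershed was considered first, but densely packed
clusters merge into compact masks with no necks, so distance maxima
fuse while intensity peaks remain resolvable; seeding on intensity
handles both cases, and for two partially fused nuclei the two
approaches coincide.

## Kinetics

Objects are re-detected per timepoint (treatments are added to the
well between acquisitions; nothing guarantees identity), so traces are
built per group — well, condition, aggregation class — as the mean
corrected intensity over member objects, and single-object traces use
nearest-centroid linking with a 15 px displacement cap. Normalization
divides by one basal value: the trace's own (default) or an explicit
reference trace (e.g. a monoculture basal when comparing co-culture to
monoculture). Response summaries average normalized values over all
oligomycin and all FCCP timepoints; hyper/depolarization flags are
strict comparisons with 1.

## Aggregation classes

3D neural cultures form structures at four scales — single cells,
grouped cells, big aggregates, spheroids. Stages: per-channel
Z-projection (default max across planes, which preserves bright
in-focus nuclei; mean and focus-weighted projections are available),
cluster detection as 8-connected components of the unsplit Hoechst
foreground, and classing by projected area measured in multiples of
the median single-nucleus area. The unit is estimated from clusters
containing exactly one watershed-detected nucleus, because dense
clusters under-split and would inflate it. Thresholds a1 = 2,
a2 = 10, a3 = 60 nucleus-equivalents are package defaults exposed in
configuration — the four-class scheme is fixed but its cut-offs are
not published — and classing is monotone in area by construction.

## Fiber pipeline

Brightfield planes are flatfield-corrected by dividing out a
least-squares quadratic illumination surface (mean-preserving).  A
wide-Gaussian illumination estimate was tried first and rejected: its
boundary handling leaves most of a full-field vignetting dome in
place, while the parametric surface removes it exactly and is
idempotent.

Background is then removed per plane by a sliding-paraboloid greyscale
opening: structuring element z = −(x² + y²) / (2·c·s²) with curvature
c = 3 and lateral scale s = 10 px over a footprint of radius 2.5 s.
The opening never exceeds the image, so output = image − opening is
nonnegative and invariant to constant offsets; broad smooth domes pass
into the background (removed), narrow ridges such as fibers do not
(preserved). The curvature convention of the commercial operator this
replaces is undocumented, so this parameterization is equivalent in
behavior, not guaranteed identical; `s` is exposed separately.

Fiber-positive area is the union across planes of the thresholded
flattened planes ("3D reconstruction" reduced to a 2D mask — the only
downstream consumer). Thresholds are relative to the flattened
plane's median-to-p99.9 range (fraction 0.3); planes whose p99.9 lies
within 3× the median floor contain no structure and are skipped,
because the opening leaves a positive noise floor that a purely
relative threshold would segment. True fibers must pass three
conjunctive, individually switchable gates: area ≥ 1000 px, aspect
ratio ≥ 5, and striation score ≥ 0.2, the score being the fraction of
non-DC spectral power of the (envelope-detrended) intensity profile
along the major axis that falls in the 6–24 px period band. Debris is
rejected primarily by aspect ratio; unstriated cylinders by the
spectral gate. Fiber TMRM uses the same ring photometry with a 6 px
ring gap, clearing the dim fiber fringe that brightfield thresholding
leaves outside the mask.

## Nuclear features

28 features per nucleus, fixed order, schema-versioned (a hash is
stored with trained models and checked at scoring time): area,
Crofton perimeter (markedly less rasterization bias than the polygonal
estimate on smooth shapes), roundness 4πA/P², axial ratio, solidity;
mean, SD, 5/25/50/75/95% quantiles and integrated intensity on
background-subtracted values (field 5th percentile — per-object rings
would be contaminated by neighboring nuclei inside aggregates); GLCM
contrast, correlation, entropy and homogeneity at offsets 1, 2, 4 px
averaged over four directions, computed on 32-level quantized
object-masked patches (out-of-object pixels get a reserved level whose
co-occurrence rows are dropped before normalization); a 180°-rotation
asymmetry (normalized L1 difference about the centroid); and the
fraction of pixels above 1.2× and 1.5× the object median. These are
open equivalents of proprietary texture families (e.g. SER features),
not reimplementations of them. Objects under 10 px are dropped with a
warning. All features are translation- and 90°-rotation-invariant to
within 2%.

## Population classifier

Architecture: BatchNorm on the standardized input, then five
dense+dropout pairs of 350, 224, 128, 96, 96 ReLU units with dropout
rate 0.01, then one sigmoid output unit — the score is the probability
of belonging to population A. Training: plain SGD at learning rate
0.01, batch size 128, class-weighted binary cross-entropy, at most 250
epochs with early stopping (patience 25) monitored on the held-out
split, best weights restored. Features are z-scored by training-split
statistics (required for SGD at this rate on heterogeneous feature
scales). Initialization is Glorot-uniform; BatchNorm running-moment
momentum is 0.99. Loss, batch size, class weighting, the 80/20
stratified split, the initializer and the momentum are package choices
where the procedure this mirrors reports none. The network is
implemented directly on numpy arrays (explicit forward/backward
passes); training is deterministic given the seed, and a logistic
regression serves as an independent baseline in the tests, never as
the implementation.

Score filtering: assigned A iff score ≥ θ, B iff score ≤ 1 − θ,
otherwise discarded; θ defaults to 0.6, and a score of exactly θ is
retained (only scores strictly below the threshold for both classes
are discarded). The discarded fraction is monotone in θ.
Permutation importance ranks features by mean held-out accuracy drop
over seeded column permutations; PCA exploration standardizes, drops
constant columns with a warning, and returns loadings plus
explained-variance fractions.

## Cell-cycle gating

Integrated background-subtracted Hoechst intensity per nucleus is
proportional to DNA content. The G0/G1 mode *m* is located on a
log-domain KDE (Silverman bandwidth — appropriate under multiplicative
CV noise) as the densest peak in the lower half of the value range;
gates at t1·m = 1.4·m and t2·m = 1.75·m split cells into G0/G1
[0, 1.4 m), S [1.4 m, 1.75 m) and G2/M [1.75 m, ∞). Mode-relative
gates make the fractions exactly invariant to intensity units; the
specific multipliers approximate midpoints of the 2N–4N doubling and
are configuration. Degenerate inputs: all-equal values gate as pure
G0/G1; a structureless (flat) distribution — no interior KDE peak
standing ≥ 3× above the range-edge density in the linear domain —
raises rather than gating noise; fewer than 50 cells sets a low-n
flag. Simple interval gating is intentional; parametric DNA-content
models (Watson, Dean–Jett–Fox) are out of scope.

## Synthetic data generator

The generator produces every input the pipeline consumes, with the
latent truth recorded at generation time so that each estimate the
pipeline produces has an oracle.

- **Nuclei** are isotropic Gaussian spots truncated at 3σ (σ = 4 px
  for monolayers, 2.5 px in aggregation fields), placed by
  dart-throwing with a minimum separation (an over-dense request
  raises). **TMRM** is a flat perinuclear annulus hugging the visible
  nucleus footprint (inner radius 2.2σ, width 4 px) — a proxy that
  puts the ROI/ring geometry under test without modeling
  mitochondrial networks.
- **Kinetics**: the annulus amplitude is basal_mean × f(t) with
  f = 1, f_o, f_f at basal / oligomycin / FCCP timepoints. Defaults
  f_o = 1.3, f_f = 0.4 — a moderate hyperpolarization and a deep
  depolarization, chosen once as typical of healthy adherent cells;
  no quantitative per-cell-type amplitudes are published, so these
  are free parameters of the study conditions.
- **Noise**: per-pixel multiplicative log-normal with mean 1 and CV
  0.05 (typical of well-exposed fluorescence), plus additive Gaussian
  read noise (SD 2).
- **Aggregation fields** place structures of the four classes with
  disjoint nominal area ranges (checked): singles; golden-angle-packed
  touching clusters of 4–5 and 20–26 nuclei; spheroids as filled
  textured discs of 150–180 px diameter. Each structure is sharp in
  one focal plane of the Z-stack and Gaussian-blurred in the others
  proportionally to plane distance (1.8 px per plane step at the
  default 13 µm spacing) — defocus emulation, not optics.
- **Fibers** are capsules (length 300, width 24 px by default) with
  sinusoidal axial striation (period 12 px, modulation 0.45) and
  cosine cross-sectional shading, non-intersecting by segment-distance
  rejection sampling, each sharp in one plane; debris are round blobs
  of fiber-like contrast; brightfield planes carry a parabolic
  illumination dome (amplitude 200 on background 1000).
- **Feature tables** are Gaussian clouds in 30 named feature
  dimensions; population B is offset by `class_shift` on a random
  third of the features. Shift 0 makes labels independent of
  features; shift 2 with unit noise is comfortably separable (a
  linear baseline exceeds 95% held-out accuracy, as the tests verify
  independently).
- **DNA content**: G0/G1 at the mode, G2/M at twice it, S uniform on
  the central 1.45–1.70× band of the doubling, multiplicative CV
  noise. The S band is an inner band rather than the full (1, 2)×
  interval so that interval gates bracket the S population cleanly;
  with full-band S phase, boundary-adjacent S cells are intrinsically
  misassigned by *any* interval gate and phase-fraction recovery is
  limited by that censoring, not by the estimator.

What the generator does **not** emulate — and what passing tests
therefore cannot certify on real data: realistic PSFs and optical
sectioning, photobleaching, TMRM quenching-mode behavior, spatial
background structure beyond smooth domes, cell crowding and overlap,
mitochondrial network morphology, and biological variability of
responses within a population (kinetic factors are shared per
population/class). Recovery results on synthetic plates demonstrate
the estimators are unbiased under the stated noise model, not that
segmentation or gating survive arbitrary real-world imagery.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: fields of
256–640 px, tens to a hundred cells per field, 10,000-row feature
tables, three-plane fiber stacks. These sizes were chosen so that
every statistical tolerance in the tests (e.g. ±10% on kinetic ratios
at n ≥ 100 cells, ±3 points on phase fractions at n = 10,000) has
comfortable sampling margin. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical seeds
reproduce images, tables, training trajectories and scores
bit-identically, and each workflow writes a provenance JSON (config +
seed + package version) sufficient to re-run it exactly.

## Known limitations

- Object linking across timepoints is nearest-centroid with a fixed
  15 px cap; it is only exercised for single-object traces, matching
  the per-well averaging the workflows use.
- The fiber striation gate assumes a roughly straight fiber (profile
  sampled along the regionprops major axis); strongly curved fibers
  would need skeleton-path sampling.
- GLCM features are computed at fixed offsets in pixels, so they are
  not invariant to magnification changes.
- The classifier trains on monoculture wells; domain shift between
  monoculture and co-culture appearance (e.g. density-dependent
  nuclear morphology) is not modeled by the generator and would
  degrade real-data transfer.
- Cluster classing uses projected area only; overlapping structures
  in Z project onto one cluster.
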