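# Methods

This note documents the models, estimators and design choices behind
`mcfnano`, the assumptions they rest on, and what the synthetic-data
benchmarks do and do not demonstrate about real AFM data.

## Study design being emulated

Eight experimental groups cross two ages (adult, aged), two mechanical
histories (normally loaded control vs. 28-day hindlimb unloading, HLU) and
two in-situ axial tibial loads during scanning (0 N, 4 N).  Each group has
n = 6 mice with 5 scan sites per tibia.  Per site the protocol measures
the D-periodic spacing of 10 traced fibrils, the orientation of 20
randomly sampled fibrils, and 20 nanoindentation curves.  The generator's
per-group defaults are the published group statistics (D-period mean ± SD
in nm; radial modulus mean ± SD in GPa), used as generative ground truth
so the full pipeline can be validated by parameter recovery.

## Synthetic micrographs

A scan is a 5 μm × 5 μm raster (1,024 px by default; the recovery
benchmarks run at 512 px, i.e. 9.77 nm/px, which still resolves a 70 nm
period at ~7 px/cycle).  Fibrils are straight ribbons: width uniform in
80–300 nm, length uniform in 1.2–3.2 μm, axis angle normal about a
per-image dominant direction (SD 15° by default), and along-axis amplitude

    A(s) = A0 · (1 + c · cos(2π s / D + φ)),   c = 0.3,

with a sine-squared edge taper.  Per-fibril D-periods are truncated-normal
draws (lower bound 40 nm, also guaranteeing ≥ 4 px/period); placement is
rejection-sampled with a 60 nm clearance margin on both the candidate and
the occupancy map so ribbons stay ≥ ~120 nm apart and segmentation can
bridge band valleys without merging neighbours.  Backgrounds are per-line
quadratics with coefficients uniform in ±0.4 (amplitude units) — exactly
the artifact second-order line flattening removes — plus white Gaussian
noise (SD 5% of the body amplitude).  The height channel renders a
parabolic ridge cross-section; it is generated for completeness but no
quantitative result depends on it.

Choices made where the source protocol is silent: cosine banding rather
than a sawtooth (peak-to-peak intervals are insensitive to band shape at
this contrast); straight centerlines (a curvature option was considered
and left out — none of the measured quantities depends on gentle
curvature, and straightness gives an independent lever for trace-quality
checks); truncated normal distributions for D, angle and modulus (mean ±
SD are the only published constraints; consequently population *fractions*
above a threshold are not reproduced and are out of scope).  0 N and 4 N
are independent parameter sets per group — no constitutive load model is
simulated.

## Synthetic force curves

The piezo ramps at 2.5 μm/s for 4.8 s (24,000 samples); that travel
includes the approach, so the simulated record covers the window around
contact: displacement 0–270 nm (max contact offset 120 nm + max
indentation 150 nm) at the full sample count.  Force is baseline drift
(slope uniform in ±0.005 nN/nm) plus the conical Hertz term beyond the
contact point z₀ (uniform in 30–120 nm), plus white noise with SD 5% of
the curve's peak elastic force (an absolute nN value can be configured
instead).  With E in GPa and δ in nm the Hertz prefactor
(2/π)·tan α/(1 − ν²) yields force directly in nN (GPa·nm² = nN), checked
against the hand-evaluated reference point E = 1 GPa, δ = 100 nm →
1233.55 nN.

## Image post-processing

`flatten_lines` subtracts the per-row least-squares polynomial (order 2
default) using a Vandermonde design on [−1, 1]; it is an exact projection,
hence idempotent, and removes any per-line polynomial of equal or lower
order.  The plain fit is the default because it is what instrument
software applies; a `robust` flag re-fits each line with >2 SD pixels
down-weighted (two iterations).  `lowpass_amplitude` (Gaussian σ = 0.8 px,
reflective boundary) exists for display only: it flags its output, and
every quantitative entry point rejects flagged images.  D-spacing analysis
runs on the flattened, *unfiltered* amplitude signal — the amplitude
deviation.

## Segmentation and tracing

The trainable-classifier segmentation of the original workflow is
replaced by a deterministic classical pipeline.  The ridge feature is
band-texture energy: squared high-pass residuals (Gaussian σ = 8 px) taken
along rows — immune to the residual per-line background bias the plain
flatten leaves on fibril-rich lines, because that bias is low-frequency
along the row — summed with the same quantity taken along columns of a
robustly re-detrended copy (covering fibrils parallel to the scan lines,
for which per-line statistics are uninformative), then envelope-smoothed
(σ = 4 px).  Otsu thresholding, speckle removal, a 30 nm morphological
closing (bridging sub-threshold D-band valleys), and shape filtering
(major axis ≥ 300 nm, aspect ratio ≥ 3) yield the label map.  All of this
feeds segmentation only; profiles are sampled from the flattened image.

Tracing skeletonizes a region, extracts the longest geodesic path (two
breadth-first passes), trims one estimated ribbon-width from each end
(skeleton spurs hook into region corners), smooths with a 7-point moving
average, re-extends both ends along their tangents to the region
boundary (restoring the arclength skeletonization erodes), and resamples
at one-pixel arclength steps.  Branched skeletons whose longest path
covers < 75% of the skeleton are rejected as crossing/merged objects.
Amplitude profiles average bilinear samples across ± 10 nm perpendicular
to the local tangent.

## D-spacing and orientation estimation

Peaks of the mean-subtracted profile with prominence ≥ 0.5 profile-SD and
separation ≥ 40 nm are refined by parabolic interpolation through their
three-point neighbourhood; the per-fibril D-spacing is the arithmetic mean
of consecutive peak-to-peak intervals, requiring ≥ 3 peaks.  The
prominence/separation defaults pass the nominal 67–77 nm periods while
rejecting noise peaks; both are configurable.  Per site the 10 longest
traces are measured (mirroring the 10 manually traced fibrils of the
protocol); orientation uses a seeded uniform sample of 20 traced fibrils
per image.  Orientation is the axial angle of the total-least-squares
line through the trace nodes, reported in (−90°, 90°] against the image
horizontal; per-image normalization subtracts the circular-aware axial
mean (doubled-angle method, period 180°), and histograms bin the absolute
deviation in 10° bins.  Known small bias: residual trace wiggle inflates
arclength slightly, overestimating D by ~0.2 nm (≈ 0.3%) at the benchmark
scale — an order of magnitude inside the ±2 nm recovery tolerance.

## Hertz fitting

For each candidate contact sample i the baseline (a, b) is the
least-squares line over samples < i, and the elastic amplitude
c = Σ r δ² / Σ δ⁴ (r the baseline-subtracted force, δ = z − z_i) is the
closed-form least-squares solution, linear in the δ² regressor.  Prefix
and suffix power sums make the full scan O(n); the best candidate is then
refined by bounded continuous minimization of z₀ between its neighbours.
E = c / prefactor.  Convergence requires ≥ 20 pre-contact and ≥ 50
post-contact samples, a positive amplitude, and an elastic signal at
maximum depth ≥ 5× the residual RMS (rejecting pure-baseline records that
would otherwise "fit" a negligible modulus).  A threshold-crossing
detector (first sustained 5σ departure from the extrapolated baseline,
used as an upper bound on z₀) is available behind the config.  On
noise-free synthetic curves the fit recovers E to 10⁻⁶ relative and z₀ to
one sample; at 5% force noise the Monte-Carlo mean is unbiased within 2%.
The rigid-lever conversion δ = z − z₀ is the default; a cantilever
stiffness correction δ = (z − z₀) − F/k is available but no calibration
routine is implemented (calibration is an instrument-side step).

## Statistics

All inferential pieces are implemented from their definitions: ECDFs
(right-continuous), the two-sample K-S sup-distance over the pooled
support with the asymptotic Kolmogorov p-value at effective size
n₁n₂/(n₁+n₂) (adequate at ~300 fibrils/group; scipy's special function
supplies the Kolmogorov distribution itself), Holm–Šidák step-down
adjustment 1 − (1 − p₍ᵢ₎)^(m−i+1) with enforced monotonicity, and Welch's
t-test feeding the pairwise tables.  α = 0.05 throughout.  The mouse/site
hierarchy is not modelled (no mixed effects) — matching the flat pooling
of the emulated protocol.

## Benchmark problem sizes and what they show

The recovery benchmarks run each group's full design — 30 images at
512 px (≈ 300 fibrils) and 600 force curves at 24,000 samples — in well
under a minute per group on one CPU; seeds split deterministically per
(master, group, mouse, site, stream), so any unit regenerates in
isolation.  Passing recovery shows the estimator chain is unbiased and
precise *under the generator's assumptions*: straight, well-separated,
fully resolved fibrils; cosine banding; Gaussian noise; ideal Hertzian
contact with no adhesion, viscoelasticity or tip convolution.  Real
micrographs violate several of these (crossing and curved fibrils,
scars/debris, drift, tip effects), so the benchmarks validate the
*software*, not the biology; the deterministic classical segmentation is
also a different instrument than an interactively trained classifier,
and per-image fibril counts can fall slightly short of the nominal 10/20
when placement or tracing rejects objects.

## Degenerate inputs and tie-breaks

Constant profiles, < 3 detected peaks, degenerate (coincident) traces and
pure-baseline curves are rejected rather than guessed at; single-value
summaries report SD = 0 with a warning; K-S on identical samples returns
D = 0, p = 1.  Peak refinement clamps the parabolic offset to ±½ sample.
Axial angles fold ties at exactly ±90° to +90°.
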