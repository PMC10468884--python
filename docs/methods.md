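# Methods

## Scope and approach

The package quantifies perfusion from laser speckle video in Relative
Perfusion Units (RPU) and ships a synthetic scene generator emulating
three porcine bowel experiments. The device that produced the original
data uses an unpublished proprietary processing chain; this implementation
substitutes the standard published single-exposure speckle-contrast model
(Fercher/Briers, Lorentzian velocity spectrum) and documents that
substitution rather than claiming to reproduce the vendor algorithm.
Because RPU is invariant to affine rescaling of the raw flow quantity,
the particular raw-value choice (here the flow index 1/K²) does not
affect any reported number — this invariance is property-tested.

## Speckle model and rendering

At exposure `T` and correlation time `tau_c`:

    K^2(T, tau_c) = (tau_c/2T) [2 − (tau_c/T)(1 − exp(−2T/tau_c))]

Perfusion `p` (percent, 0–100 with headroom to 110) maps to `tau_c` by
numerically inverting this closed form such that `1/K^2` is affine in
`p` between two anchors: `tau_static` (0.1 s, quasi-static speckle,
K ≈ 0.98) at `p = 0`, and `tau_full_perfusion` (0.1 ms, K ≈ 0.14) at
`p = 100`. This affinity is the generator's calibration contract: it is
what makes end-to-end recovery of configured ground truth through the
imaging chain meaningful (linearity is enforced by a test at R² ≥ 0.98).

Rendering parameters (defaults): 120 fps frame rate, 5 ms exposure
(the frame period is 8.33 ms; the source system states no exposure),
1:1 pixel:speckle ratio, 16-bit frames with mean intensity 1000 counts,
optional Gaussian read noise (off by default — the source says nothing
about sensor noise).

Two modes:

* **analytic** (default): per-pixel integrated intensities drawn from a
  gamma distribution with shape `1/K^2` ("effective degrees of freedom")
  and mean equal to the configured intensity. Frames are i.i.d. in time.
  This is exact for the spatial-contrast statistics used downstream and
  runs in milliseconds.
* **dynamic**: a complex circular-Gaussian field evolving per pixel as an
  AR(1) process with substep field correlation `exp(−dt/tau_c)`
  (so the intensity autocovariance is `exp(−2dt/tau_c)`, the Lorentzian
  model), exposure-integrated over 64 substeps per frame and advanced
  through the inter-frame dead time. It is the physics oracle: rendered
  contrast agrees with the closed form to < 3 % at the default substep
  resolution, degrading (with a warning) when `dt` exceeds `tau_c/2`.
  Speckle grains > 1 px are realized by low-pass filtering the complex
  field (variance-renormalized); this departs from the 1:1 calibration
  and is excluded from the calibration contract.

Off-mask pixels render as static speckle at full intensity so contrast
windows crossing tissue borders degrade gracefully.

## Contrast engine

Contrast is the population sigma/mean in a 7×7 sliding spatial window
(reflect padding; zero-mean windows give K = 0). 7×7 is common practice
at a 1:1 pixel:speckle ratio; the source device's spatial/temporal choice
is unstated, so the default chain — per-frame spatial contrast, flow
index `1/max(K, 0.05)^2`, then a 5-frame moving average on flow maps —
is an assumption, modelled on the original system's use of a temporal
smoothing window. A per-pixel temporal-contrast estimator is also
provided. Windowed moments are computed with `scipy.ndimage` and are
tested against brute-force double-loop oracles for exact agreement.

## RPU quantification

Regions are discrete disks of exactly 317 pixels (radius ≈ 10 px), the
nearest-pixel set with radius ties broken by angle then row-major order —
a disk is rotation-fair along curved arcs; the shape itself is not
specified by the source. The source methods print both 317 and 21 pixels
as the region area; 317 is adopted (stated twice and tied to all
regions), 21 remains available via `area_px`. RPU per frame uses
references re-sampled on the same frame from fixed user-supplied
coordinates; 5 representative frames are selected evenly across a 0.5 s
cardiac window, so pulsatile phases average out — the original system
accounts for the cardiac cycle but publishes no algorithm, so the
selector is pluggable. Hot/Cold selection is
manual by design; `validate_references` only warns (weak separation,
implausible percentiles).

## Synthetic scenes

Geometry is simplified to rectangular tissue bands with straight parallel
arcs at 20 px/cm: every reported quantity depends only on distance along
an arc. Scene construction is deterministic; all stochasticity lives in
the renderer and the occlusion schedule.

**Gradient scene.** The centerline profile is piecewise linear: ischemic
floor 1.9 % to 2 cm, a steep rise to a slope break at 5 cm, a gentle rise
to the plateau 98.8 % at 8 cm. The value at the break is solved (the
target is affine in it) so that the *measured* watershed mean — disk
regions of 317 px sampled every 0.5 cm across 4–6 cm — equals the
configured 78.3 %. Three longitudinal lanes split the reported 16.6-point
mesenteric−antimesenteric offset asymmetrically (+1.2/−15.4 around the
centerline) so that the perfused-segment centerline (98.8), mesenteric
arc (100.0) and antimesenteric arc (83.4) levels are all simultaneously
exact; the offset fades with the ischemia fraction so the ischemic zone
is uniformly dead. A zero-flow "cold pad" (stapled/coagulated tissue)
behind the staple line hosts the Cold reference — the recovered ischemic
mean can only equal 1.9 % if the Cold anchor sits at true zero flow. The
Hot reference sits on the mesenteric arc at 9.5 cm (ground truth 100).

**Occlusion schedules.** MAP is never printed in the source, so the MAP
axis is invented and configurable: baseline 65 mmHg, arterial end
20 mmHg, venous end 40 mmHg, residual perfusion scale 0.05 at complete
occlusion. The global perfusion scale factor is linear in MAP with a
kind-specific slope (venous ≈ 0.038/mmHg > arterial ≈ 0.021/mmHg — the
venous phantom reaches the same low-flow state over a much smaller MAP
drop, encoding the observed venous hypersensitivity) plus Gaussian noise;
the baseline step is noise-free, the final step is clamped, and
monotonicity is enforced. The noise SDs (arterial 9.2, venous 25.0, in
percent of full scale) were chosen by the included schedule-level
Monte-Carlo calibration script to land the expected regression R² in the
reported range (≈ 0.96 arterial, ≈ 0.86 venous, perfused segment); the
venous figure is printed inconsistently in the source (0.86 in the
results text, 0.06 in a figure caption) and the results-text value is
used, with the discrepancy recorded rather than silently resolved.
During occlusion runs the Hot/Cold reference raw values are frozen at the
baseline step: re-sampling them on occluded frames would cancel the
global perfusion change out of the ratio and no MAP correlation could
exist.

**Anastomosis scene.** Two bands carry linearly declining point profiles
over 10 matched points (0–4.5 cm): antimesenteric 82.2 → 25.8 (mean 54,
SD 18), mesenteric 61.5 → 14.5 (mean 38, SD 15), antimesenteric strictly
higher at every matched point. Profiles are linearly extrapolated ~0.75 cm
past the span so end-point sampling disks see a locally linear field.
Hot (100 %) and Cold (0 %) reference pads sit beside the bands.

## Analysis

Two-sided tests throughout, α = 0.05; matched-point designs use paired
t-tests; segments are compared by one-way ANOVA with the gap regions
(2–4, 6–8 cm) excluded from summaries. Profiles default to 0.5 cm
spacing — fine enough to localize the decline onset, which is detected by
exhaustively fitting a continuous two-piece linear model with the break
at each candidate sample position inside a 2–8 cm window (where the
gradient truly is two-piece; over 0–10 cm it is four-piece and a
single-break model is misspecified), requiring the proximal slope to
exceed the distal slope 2:1 to report an onset. Breakpoint candidates are
sample positions only, keeping the search reproducible and
oracle-checkable. Mean RPU is regressed on MAP by ordinary least squares.

## Numerical choices and degenerate inputs

Contrast floor `k_floor = 0.05` caps the flow index at 400; population
(not sample) standard deviation everywhere, fixed for oracle
reproducibility; bilinear interpolation for arc queries (exact at grid
nodes); region extraction refuses to clip map borders, and profile
samples whose region would clip are dropped with a warning; swapped
(Hot ≤ Cold) references are a hard error; identical groups yield F = 0,
p = 1 rather than NaN. Seeding uses `numpy` `SeedSequence` spawning so
every stage is independently and reproducibly seeded; identical
configuration and seed reproduce stacks byte for byte.

## Problem sizes

Default experiment sizes: gradient scene 140×256 px (11 cm × 5 cm band),
64 rendered frames per run, profiles of 21 samples per arc; occlusion
runs 10 steps × 16 frames with 3 ROIs per segment; anastomosis 64 frames,
10 matched points. These desk-scale sizes recover segment means with a
seed-to-seed SD of ≈ 1.7 RPU points (dominated by the sampling noise of
the 317-px reference regions, which enters all ROIs of a run as a common
scale factor), so multi-seed checks pool five runs, mirroring the pooled
analysis of the original experiments.

## What the phantom does and does not show

Passing recovery tests shows the quantification chain is unbiased to
within ~1 RPU point under the stated speckle physics, with two known
small systematic residuals: disk smearing at profile kinks (the ischemic
segment reads ≈ +0.3 at its 2 cm boundary) and a mild compressive
nonlinearity (≲ 1 point at high flow) from the K-dependence of the
windowed estimator's bias. The phantom deliberately omits: tissue and
scope motion (the source fixed the scope at 20 cm), cardiac/respiratory
pulsation (frames are stationary in distribution; the cardiac-window
frame selector is therefore exercised only trivially), depth-dependent
scattering, vessel-tree anatomy, specular highlights, and any
fluorescence-angiography modality. Agreement on the phantom therefore
validates the computation, not the device, and says nothing about
in-vivo confounders.
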