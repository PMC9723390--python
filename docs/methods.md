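# Methods

## Scope

`osteonlo` implements the quantitative image-analysis chain used to
characterize bone composition and collagen architecture in co-registered
multimodal nonlinear-optical (NLO) microscopy of murine vertebra sections:
bright-field, two-photon excited fluorescence (TPEF), second-harmonic
generation (SHG, acquired under two linear pump polarizations), and
stimulated Raman scattering (SRS) at 2850 cm⁻¹ (CH₂/lipids) and 2920 cm⁻¹
(CH₃/proteins).  Because no public raw images exist for this kind of study,
the package ships a synthetic vertebra-scene generator with retained ground
truth, so every downstream stage is testable end to end.

Microscope modelling (optics, point-spread function, detection physics),
image registration and automated tissue segmentation are out of scope:
stacks are assumed co-registered and tissue ROIs are an input label map, as
they would be drawn manually in practice.

## Collagen content (ROI intensity statistics)

SHG intensity scales linearly with the density of non-centrosymmetric
scatterers (collagen) in the focal volume, so the *raw* mean pixel
intensity over a tissue-class ROI is used as a collagen-density readout —
no rescaling, flat-fielding or background subtraction is applied.
"Mineralized bone" is the union of the cortical and trabecular classes;
per-compartment results are also emitted.  Dispersion is reported as the
sample standard deviation (n−1) and SEM = sd/√n, matching the mean ± SEM
convention of the field.  Growth plate, intervertebral disc/growth bands
and background never enter any ROI.

Bone-vs-marrow composition for the SRS channels is the ratio of the
mineralized-bone ROI mean to the marrow ROI mean, per sample and channel.
Group statistics operate on per-sample ratios (one value per animal), not
on pooled pixels.

## Fiber orientation (Sobel chain)

Gradients are cross-correlations (not convolutions) with the 3×3 Sobel
kernels

    Gx = [[+1,0,-1],[+2,0,-2],[+1,0,-1]]     Gy = Gxᵀ

with symmetric ("reflect") border padding, so output shape equals input
shape.  Implementation detail: both responses are computed by the same
row-major nine-term accumulation (Gy as the transposed Gx pass), which
makes the results bit-reproducible against a scalar double-loop oracle and
exactly zero on constant images.

The local gradient direction φ = atan2(Gy, Gx), folded to the axial range
[0°, 180°), is perpendicular to the local fiber axis; the reported fiber
angle is (φ + 90°) mod 180°.  With the convention that the image rows run
craniocaudally, a vertical (craniocaudal) structure reads 90° and a
horizontal one 0°.  The full-quadrant arctangent replaces the raw ratio
arctan(Gy/Gx); after axial folding the two agree wherever the ratio is
defined, but atan2 has no pole at Gx = 0.

Pixels whose gradient magnitude falls below ε carry no orientation
information and are masked.  ε defaults to 10⁻⁶ × the maximum magnitude —
effectively "count every pixel with any gradient", i.e. plain pixel counts.
A percentile-based gate is available for noisy data (`RunConfig.eps`);
raising ε can only shrink the analyzable set.

ROI orientations are histogrammed into 180 left-closed 1° bins on
[0°, 180°) and normalized to percent of analyzable pixels, so the bins
always sum to 100.

## Orientation-peak model and alignment ratio

Histograms are fitted with a flat baseline plus a single Gaussian peak:

    f(θ) = B + A · exp(−((θ − θ0) / (2σ))²)

B is the randomly oriented portion, A the peak−baseline amplitude, θ0 the
preferential orientation and σ the width.  The exponent is implemented
exactly in this form; it equals a standard Gaussian with standard deviation
σ√2.  σ is *fitted and reported in this parameterization* because the
published reference parameter tables are only comparable under it.

Fitting is bounded trust-region least squares (A ≥ 0, B ≥ 0,
θ0 ∈ [0°, 180°], σ ∈ (0.5°, 90°]) initialized from the data: B₀ = min,
A₀ = max − min, θ0₀ = argmax bin centre, σ₀ from the half-width at
half-prominence (f drops to B + A/2 at |θ − θ0| = 2σ√ln2).  If the default
start fails, a multistart over θ0 ∈ {15°, 45°, …, 165°} is run; smallest
residual sum of squares wins, ties broken by smaller σ.  R² = 1 −
SS_res/SS_tot; a perfectly flat histogram (SS_tot = 0) fitted exactly is
reported as R² = 1.  The fit is deterministic for fixed input.

The alignment ratio summarizes the degree of orientation:

    AR = 100 · A_G / (A_G + A_B),   A_B = 180°·B

with A_G the area under the Gaussian term alone (offset zero).  A_G is
integrated over the finite data domain [0°, 180°] (closed form via the
error function; a trapezoid oracle is used in tests) rather than over
(−∞, ∞): the data are axial and finite, and for σ ≤ 45° the difference is
negligible.  Randomly oriented fibers give AR → 0, a pure aligned
population with no baseline gives AR = 100.  AR is strictly increasing in
A and strictly decreasing in B.

No wrapped/circular fitting is attempted: the model is a plain Gaussian on
[0°, 180°], so peaks very close to 0°/180° are split by the domain edge and
are not handled — a known limitation, irrelevant for craniocaudally
dominated bone where θ0 ≈ 90°.

Condition summaries average fits per (genotype × compartment ×
polarization) cell and report cross-condition means rounded half-up at the
printed precision.  The means are accumulated in decimal arithmetic: binary
floating point turns decimal ties such as (25.4+27.6+29.0+28.3)/4 = 27.575
into 27.5749…, which would round the wrong way.

Published AR table values are *not* recomputed from the published (A, σ, B)
rows: no standard area convention (finite or infinite domain, either σ
parameterization) reproduces them, so the original integration scheme is
unknown.  The AR implemented here is the documented truncated-domain
convention above.

## Group statistics

Two test families are provided because both appear in this literature:
the Mann–Whitney U test (default) and the two-sample t test
(Student/Welch).  The Mann–Whitney exact null is enumerated over all
C(n, n_a) rank assignments when n_a + n_b ≤ 12, with ties mid-ranked; the
two-sided p is the null probability of a U at least as far from n_a·n_b/2
as observed (equivalent to tail doubling for the symmetric tie-free null).
Larger samples use the normal approximation with tie correction.
Zero-variance t-test inputs are handled explicitly (equal means → p = 1;
unequal → flagged degenerate).  Significance defaults to p < 0.1 — the
unusual threshold is deliberate, mirroring how these small-n (n = 3 per
genotype) bone phenotype comparisons are reported — and is configurable.
No multiple-testing correction is applied.  Group summaries are mean ± SEM.

## Synthetic vertebra scenes

The generator emulates the features the analysis chain measures, not the
appearance of real tissue.

**Geometry.**  Background margin, growth-plate bands at the cranial and
caudal ends, a connected cortical frame, and a marrow interior crossed by
evenly spaced vertical trabecular struts.  Defaults (512×512, 1 µm pixels):
20 px margin, 30-row growth plates, 48 px cortical thickness, 4 struts of
28 px.  Compartments are deliberately wide relative to fibre size so that
compartment boundaries neither clip many fibres nor contribute a
significant population of axis-aligned mask edges to the histograms.

**SHG fibres.**  `n_fibres` (default 800) line segments, centres uniform on
bone pixels, lengths uniform in 20–60 px, confined to the bone classes.
Axial orientations follow the mixture
aligned_fraction · WrappedNormal(θ0_true, √2·σ_true) +
(1 − aligned_fraction) · Uniform[0°, 180°), sampled by folding an unwrapped
normal modulo 180°.  σ_true is expressed in the peak-model
parameterization (the wrapped normal's standard deviation is √2·σ_true),
so the parameter the downstream fit estimates *is* σ_true.  Each fibre is
drawn as a stroke with a constant-width Gaussian cross-section,
amp·exp(−(d/width)²) with d the distance to the segment (width 1.5 px):
a smooth profile keeps the image gradient perpendicular to the fibre axis
all along its flanks, whereas hard-rasterized lines snap local gradients to
the 0°/45°/90°/135° raster directions and would contaminate the orientation
histogram with spurious spikes.

**Polarization.**  A fibre at angle θ under excitation polarized at angle p
radiates SHG power ∝ cos⁴(θ − p); amplitudes are scaled by
floor + (1 − floor)·cos⁴(θ − p).  The floor (default 0.75) keeps fibres
perpendicular to the polarization visible.  The two SHG channels share
identical fibre geometry — the same section imaged under the two
polarizations.  Total rendered energy is maximal when the polarization
matches θ0, reproducing the parallel > perpendicular intensity ordering.

**SRS / TPEF channels.**  Piecewise constant per tissue class, with the
bone level set to ratio × marrow level before noise, so the measured
bone:marrow mean ratio equals the spec'd value exactly in the noiseless
limit.  Defaults: lipid ratio 1.5, protein ratio 1.3 (bone richer than
marrow in both, the qualitative finding for this tissue), TPEF ratio 1.

**Noise and determinism.**  Additive Gaussian noise (default sd 2, ~2% of
fibre amplitude), clipped at zero.  All randomness flows from
`SceneSpec.seed` through per-channel substreams; identical specs give
bit-identical images, and the polarization angle only rescales amplitudes
without advancing the random stream.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: SHG speckle and coherent interference, the
optical PSF, fibre curvature and bundling, partial-volume mineral effects,
spatial noise correlation, and any realistic marrow texture.  The phantom
validates the *measurement chain*, not biological realism.

**Estimator bias at the phantom's edges.**  Three genuine imaging effects
narrow the measured orientation width relative to the generating mixture,
and grow with fibre crowding and polarization-modulation depth: crossing
fibres average their gradients toward the distribution centre; brightness
weighting by cos⁴ makes dim off-peak fibres easier to bury where fibres
cross; and compartment boundaries clip fibres.  The default scene
parameters keep total fibre coverage moderate and the modulation mild, a
regime where the full pipeline recovers θ0 to ~2° and σ to better than 20%
(median over seeds) at aligned_fraction 0.5, σ_true = 25°.  Denser or more
strongly modulated scenes are valid inputs but measure a visibility-weighted
width smaller than σ_true — the same effect that makes real
parallel-polarization widths smaller than perpendicular ones.

## Numerical and I/O conventions

* Row-major, origin top-left, 0-based; rows increase caudally, 90° =
  vertical = craniocaudal.
* Stacks are multipage grayscale TIFFs (page order = channel enum order,
  channel identity and stack metadata as JSON page descriptions); label
  maps are single-page 8-bit TIFFs with the fixed code table 0 background,
  1 cortical, 2 trabecular, 3 marrow, 4 growth plate; tables are CSV;
  configs are flat YAML.  Round-trips are bit-exact for 8/16-bit integer
  and 32/64-bit float data.
* Composite export min–max scales each selected channel, blends
  additively into RGB and clips to the display range; it never modifies the
  stack.
* Histogram bins are left-closed; an angle of exactly 180° cannot occur
  (axial fold returns [0°, 180°)).

## Problem sizes used in the shipped checks

Reference-row refits are 180-point deterministic least-squares problems.
Stochastic recovery checks use 20 seeds of the default 512×512 scene
(800 fibres; 500 for the fully aligned mode check), chosen to match the
default study conditions while keeping the whole suite around ten seconds.
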