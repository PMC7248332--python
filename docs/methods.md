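# Methods

## Image model

A transcript is a point emitter. Emitters are binned to an integer pixel
grid before convolution (several emitters may share a pixel; no sub-pixel
PSF shifting), scaled, and convolved with an isotropic Gaussian
point-spread function whose e⁻² radius is ω₀:

PSF(x, y) = I₀ · exp(−2(x² + y²)/ω₀²).

The rendering kernel is **normalized to unit sum** and truncated at a
4·ω₀ radius (truncation error < 10⁻⁶ of its mass). Each emitter's pixel
is multiplied by ε·π·(ω₀/px)² before convolution, so one isolated
punctum integrates to exactly ε·π·(ω₀/px)² intensity units — with the
defaults (ε = 100 i.u., px = 200 nm, ω₀ = 300 nm) that is ≈ 706.9 i.u.
with a peak amplitude of 2ε = 200 i.u., because the unit-sum e⁻² Gaussian
evaluates to 2/(π·(ω₀/px)²) at its center. This normalization makes ε the
mean per-particle count by construction; I₀ is carried as metadata only.
The disk area ε·π·ω₀² is computed in **pixel units**; the choice affects
only the absolute intensity scale, never any linearity or saturation
conclusion. The signal model is linear (no saturation, no shot noise, no
photobleaching, no camera gain); detection noise is additive i.i.d.
zero-mean Gaussian, default sd 1 i.u. — small against the 2ε = 200 i.u.
single-punctum peak so the 6-i.u. detection threshold stays meaningful.
The noise magnitude is a modeling choice of this package; the detector
and the saturation experiment accept any (noise_sd, threshold) pair.

Emitter counts in a region of area A at density ρ are Poisson(ρ·A), not
round(ρ·A): at the lowest swept density (0.0001/µm² in a 25-µm ROI) the
mean count is 0.049, where rounding would degenerate to zero.

## Spot detection

A pixel is a peak candidate if it strictly exceeds the amplitude
threshold, is ≥ all in-bounds 8-neighbors, strictly exceeds its
lexicographically preceding neighbors (a flat plateau keeps only its
smallest pixel — deterministic tie-breaking), and exceeds at least one
neighbor (a perfectly flat region has no maxima). Candidates are then
thinned greedily in descending amplitude: a peak strictly closer than the
minimum separation (default ω₀ in pixels, 1.5 px; Euclidean distance) to
an already-kept peak is suppressed, but a peak conflicting only with
*suppressed* peaks survives. These are the normative semantics, locked by
an exhaustive brute-force reference implementation that the test suite
compares against on a thousand random images. A merged cluster of
overlapping puncta yields ≥ 1 detected peak and is counted per peak; no
cluster-splitting step exists.

## Per-neuron quantification

* **Positivity:** ≥ 3 detected peaks inside the soma mask (configurable).
* **Intensity:** mean pixel value in a circular ROI centered in the soma
  with a physical radius of 10 px × 0.63 µm = 6.3 µm (converted to the
  rendering pixel size), minus the background — the average of the mean
  intensities of 3–5 puncta-free regions. Regions are verified
  puncta-free against the detector; neurons whose ROI would exit the
  image are excluded and flagged, and rare somata too small to contain
  the ROI shrink it to fit. Background subtraction removes any constant
  offset exactly.
* **Soma area:** mask pixel count × pixel area; size classes small
  (< 650 µm²), medium (650–900 µm², both endpoints inclusive — the
  boundary values belong to the middle class) and large (> 900 µm²).

## Population simulator

Neuron marker classes (NF200, CGRP, IB4, unlabeled) are multinomial.
Expression states come in two modes: independent per-(marker, probe)
Bernoulli draws (single-probe assays, marginal percentages) or a joint
multinomial over the 2³ combinations of a three-probe panel (multiplex
assay, co-expression pie). Per-cell punctum counts given the expression
state are configurable discrete distributions; the defaults — uniform
5–20 when expressing, {0: 0.8, 1: 0.1, 2: 0.1} otherwise — are stand-ins
chosen so the ≥3 rule separates the states nearly noiselessly, since no
per-cell transcript counts are published to estimate them from. Soma
areas are Gaussians truncated at zero (the published size histograms are
well fit by normal curves), independent of expression state. Nerve-injury
effects are per-(segment, marker, probe) replacements of the expression
probability or per-cell intensity multipliers; sham equals naive.

The end-to-end pipeline renders each soma on its own image tile per probe
rather than packing thousands of somata into shared fields — statistically
identical for positivity and intensity recovery, trivially parallel and
reproducible. `render_section` still composes shared multi-neuron fields
(non-overlapping random soma placement with bounded retries) for
mask-based analyses such as the circular-ROI vs whole-soma comparison.

What the simulator does **not** emulate: autofluorescence structure,
uneven illumination, tissue sectioning artifacts, touching/overlapping
somata, cluster morphology beyond PSF overlap, or any marker classes
beyond NF200/CGRP/IB4. Recovery results therefore demonstrate the
correctness of the measurement chain under its stated model, not
robustness to real-tissue nuisances.

## Statistics

Size histograms (100-µm² bins on fixed edges) are fit with a scaled
Gaussian A·exp(−(x−µ)²/2σ²) by unweighted least squares (moment-based
initialization). Two distributions are compared with the
extra-sum-of-squares F-test: the null model fits one curve through both
histograms' points (df = n₁+n₂−3), the alternative fits each separately
(df = n₁+n₂−6, SS summed), and F = ((SS_c−SS_s)/(df_c−df_s))/(SS_s/df_s)
is referred to the F(df_c−df_s, df_s) upper tail. Histogram fits (not
cumulative-curve fits) are the comparison substrate. The test's type-I
calibration is checked on Gaussian curve data with i.i.d. noise — the
model under which the nested-least-squares F statistic is calibrated;
histogram counts themselves carry Poisson noise, a known approximation
shared with the standard practice this mirrors.

Proportion comparisons use the classical pooled-variance unpaired t-test
(Welch variant by flag) with the **DRG as the experimental unit** — the
interface takes per-ganglion percentages, never per-neuron indicators.
Intensity comparisons use one-way ANOVA plus Tukey's multiple-comparison
test, delegated to scipy/statsmodels; an all-constant input is reported
as a flagged no-variance case. No multiplicity control is applied across
probes or segments beyond Tukey.

## Problem sizes and determinism

Recovery analyses use the published n where one exists (2038 multiplex
neurons) and 500 neurons per single-marker class; the saturation sweep
covers densities 0.0001–3.1 puncta/µm² at 100 repetitions per density.
One master seed feeds `numpy.random.SeedSequence`-spawned child streams
per stage, so identical configuration and seed reproduce byte-identical
output tables.

## Known limitations

* The detector is 2-D, pixel-resolution only (no sub-pixel localization,
  no LoG/wavelet filtering); adequate for the counting-saturation
  question it serves.
* Automated soma segmentation is out of scope by design: masks come from
  the simulator (or from manual ROIs in real use).
* The per-cell punctum-count defaults make positivity calling nearly
  error-free; accuracy under heavier overlap between the positive and
  negative count distributions has no published anchor and is left to the
  configurable distributions.
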