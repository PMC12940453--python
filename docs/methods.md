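# Methods

This note records the models, conventions and numerical choices behind
vibrotrack, and what the synthetic validation does and does not establish
about real recordings.

## Signal model and motion amplification

A rigid sub-pixel translation δ(t) of an image patch I₀ changes pixel
intensity as I(x, t) ≈ I₀(x) − δ(t)·∂I₀/∂x for |δ| small relative to the
feature scale. Amplification bandpasses each location's time series and adds
it back scaled by α:

    I_out = I + α · B(I)    ⇒    I_out(x, t) ≈ I₀(x − (1+α)·δ_B(t))

where δ_B is the in-band part of the motion. The **effective motion gain is
g = 1 + α** (the original signal contributes the factor of 1); quantify's
default divides tracked displacement by g = 101 for α = 100. A literal
"displacements scale by α" reading (g = 100) is one config key away; the
two differ by 1%, well inside the pipeline's error budget.

The temporal filter is an **ideal DFT-mask bandpass** applied offline over
the whole clip: coefficients with f_lo ≤ |f| ≤ f_hi (edges inclusive) are
kept, all others — including DC — zeroed. No windowing. Rationale: clips are
processed offline, and the ideal filter is exact for on-bin tones, which
makes every downstream number testable in closed form. The cost is spectral
leakage at the band edges for off-bin content, irrelevant at the tonal
signals this method targets.

Spatial decomposition is a Laplacian pyramid (5-tap binomial kernel;
reduce = blur + decimate, expand = polyphase binomial interpolation whose
boundary handling maps constants to constants; reconstruction is exact by
construction). With a **uniform α across levels** — the default — the
pyramid is mathematically redundant: the decomposition is a linear identity
that commutes with the temporal filter, so the implementation short-circuits
to `frames + α·bandpass(frames)`, which is exactly equivalent and much
faster. The pyramid path runs when per-level attenuation of fine scales is
requested (an option for noisy footage; it also attenuates the motion signal
carried by fine scales, so it is off by default and the gain calibration
g = 1+α holds only for the uniform path). Output is clamped to [0, 1]; a
saturation fraction above 1% is logged.

Validity limit: the first-order approximation needs (1+α)·δ below roughly a
quarter of the feature scale. At α = 100 and δ ≈ 0.005 px the amplified
excursion is ≈ 0.5 px against marker edges smoothed over ~1.5 px (optical
blur + anti-aliasing) — inside the regime, as the measured end-to-end gain
(within ~5% of 1+α) confirms.

## Tracking

Markers are matched by **normalized cross-correlation** (illumination
invariant) against a template rendered by the same cross model used for
simulation — in a real deployment, rendered from the measured marker
dimensions and the camera's approximate PSF. Per frame the search is
restricted to ±search_radius (default 5 px) around the previous position,
which bounds frame-to-frame jumps and keeps the matcher away from clutter.

Sub-pixel refinement fits a full 2-D quadratic to the 3×3 correlation
neighborhood and returns the paraboloid's stationary point. Offsets beyond
1 px are clipped to ±0.5 with a warning; a non-concave fit falls back to the
integer peak and flags quality. Measured accuracy on noise-free rendered
crosses: ≤ 0.02 px at typical fractional positions, ≤ 0.04 px worst case —
about 8% of a 0.5 px amplified excursion, consistent with the end-to-end
error budget. A centroid-based refinement (exact for a symmetric marker on a
uniform background, but more sensitive to background structure and noise) is
available via `method="centroid"`.

Tracking quality: the mean NCC peak drops on amplified clips because
α×(in-band sensor noise) is commensurate with the marker edge signal; this
is expected, not a tracking failure, because the search window keeps the
match unambiguous. The default floor (error if >5% of frames fall below NCC
0.3) is set accordingly.

Calibration divides the known physical cross extent by its measured pixel
extent per axis; uncertainty is first-order propagation of a ±0.5 px
extent-reading error. Defaults when no calibration is supplied: 0.49 (x) /
0.46 (y) mm/px.

## Displacement metrics, spectra

Displacement is reported **relative to the segment-mean position** in µm:
Δ(t) = (p(t) − p̄)·mm_per_px·1000/g, re-centered again after segmentation so
each condition segment has exactly zero mean. RMS = √mean(Δ²);
peak-to-peak = max − min. Pooled summaries use the midpoint-median
convention and pool all marker-axis values within a condition.

The amplitude spectrum uses the one-sided on-bin convention
a(k) = (2/N)|X_k| for 0 < k < N/2 (DC excluded — the series are zero-mean;
for even N the Nyquist bin is excluded as out of the open interval), the two
in-plane axes combined per bin as the Euclidean magnitude √(a_x² + a_y²),
and the result divided by Δf = fps/N to honor the µm/Hz unit. Consequences
used as tests: an on-bin tone of amplitude A lands entirely in its bin with
combined amplitude exactly A, and rms² = Σ a(k)²/2 (Parseval) holds to
numerical precision on odd-length series. The Euclidean combination rule is
isolated in one place; sum-of-magnitudes would be a one-line swap. An
optional Hann window (amplitude-corrected ×2) exists for display of
broadband content; the unwindowed path is the quantitative one. Spectra are
reported up to a configurable f_max (default 500 Hz).

## Statistics

**Split-half stability.** Each segment is split at the midpoint (odd length:
extra frame to the first half), each half re-centered, and the two RMS
values compared across all marker/axis/condition series by Bland–Altman on
percent differences d = 100(a−b)/((a+b)/2): mean difference and limits of
agreement mean ± 1.96·SD (sample SD). The "95% interval" reported is the LoA
interval itself, not a CI around the LoA — the conventional Bland–Altman
quantity. Sign convention is first-minus-second.

**Idle-vs-scan comparison.** The statistic is rms(scan) − rms(idle) per
marker and axis. Displacement series are strongly autocorrelated (tones plus
bandpassed noise), so frame-level resampling would be badly anticonservative;
the resampling unit is a **contiguous block of frames**, default 0.1 s
(trailing partial blocks dropped). The bootstrap resamples blocks with
replacement within each series independently, re-centers, and recomputes the
statistic; the 2.5/97.5 percentiles give the 95% CI. The permutation test
pools the blocks, permutes condition labels preserving group sizes, and uses
|rms(a*) − rms(b*)| with p = (1 + #{perm ≥ obs})/(n_perm + 1) — never zero,
floored at 1/(n_perm+1). Blocks make the null exchangeable for stationary
series, so the test is essentially exact: measured type-I ≈ 4–5% at nominal
5%. Both routines are computed from per-block sums and sums of squares,
which makes the resampled RMS exact and the whole thing vectorizable. A
mean-absolute-displacement statistic is available behind a flag. No
multiple-testing correction is applied across markers/axes.

## Synthetic scenes: what they emulate, and what they don't

The generator renders dark crosses (configurable polarity via contrast) on a
smooth seeded background texture, moved by summed sinusoidal tones specified
in µm and converted through the pixel pitch, with optional Gaussian
positional jitter (off by default so oracles stay exact), an optical PSF
blur (default σ = 0.7 px — a sharp but realistic lens), and i.i.d. Gaussian
sensor noise per frame. Condition pairs share seed, texture and noise
stream, so idle and scan clips differ only where marker intensity differs.

**Rasterization is exact area-weighted anti-aliasing**: per pixel, the
analytic area integral of the cross indicator (axis-aligned rectangles with
inclusion–exclusion), i.e. the limit of supersample-and-box-filter. This is
load-bearing: a discrete supersample grid quantizes representable positions
to 1/supersample px, which would erase the ~0.005 px motions entirely. The
discrete path is retained (`supersample=8, 16, ...`) purely as a convergence
cross-check of the analytic renderer.

Defaults are desk-scale so tests run in seconds: 128×128 px, 1000 fps, 2 s,
pixel pitch 0.49/0.46 mm, background 0.7, texture 0.05, noise σ = 0.005,
marker arms 10 × 2 mm (marker dimensions are not standardized anywhere;
they stay configurable). A full-scale profile (4000 fps, 4.4 s clips, band
10–1000 Hz, four condition time slots of an 87 s diffusion acquisition) is
bundled for realistic-geometry runs.

Not modeled, hence not validated by passing tests: mirror-path geometry and
mirror-induced artifact motion, illumination flicker, rolling shutter,
frame-rate error, non-rigid marker deformation, and non-Gaussian sensor
noise. On real footage the idle-condition "motion" additionally contains
building vibration and mirror instability, so the synthetic noise floor
(~0.6 µm RMS at the default settings — incidentally similar to what such
systems report at idle) is a lower bound, not a prediction.

## Problem sizes and numerical choices

End-to-end checks run at 128×128 px × 2000 frames (single-tone and
multi-tone recovery) and 64×64 px × 600 frames × 20 seeded repeats
(idle/scan discrimination); type-I calibration uses 200 series-level
simulations with n_perm = 199. These sizes put every stage's error well
below the property tolerances while keeping the suite and the acceptance
script at a few minutes on one CPU. Filter masks include band edges;
segment boundaries round t·fps to the nearest frame; detection ties break
by correlation then row-major order; all RNG flows from seeded
`numpy.random.Generator`s (condition pairs spawn independent texture/noise/
jitter streams from the scene seed), and reports carry the package version
plus a hash of the scientific part of the resolved config (the output
directory is excluded so reruns into different folders stay byte-identical).

## Known limitations

- The gain calibration g = 1+α assumes the uniform-α path and in-band
  motion; fine-level attenuation changes the effective gain.
- The paraboloid refinement has a position-dependent bias up to ~0.04 px on
  hard-edged markers; at amplified excursions ≳1 px the bias pattern, not
  noise, dominates the error budget.
- The ideal bandpass is acausal and offline by design; this tool does not
  stream.
- Percent Bland–Altman differences are undefined when a pair sums to zero
  (raised as an error rather than silently dropped).
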