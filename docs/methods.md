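# Methods

This note documents the models behind each stage of `blinkkit`, the
parameters that matter, the numerical choices, what the synthetic data do
and do not emulate, and the known limitations.

## Blinking model

An emitter is a two-state continuous-time Markov (telegraph) process:
exponential **on** dwells with rate `rate_off = 1/mean_on` and exponential
**off** dwells with rate `rate_on`.  The on:off (duty) ratio is
`rate_on / rate_off = mean_on / mean_off`.  `rates_for_duty(duty, mean_on)`
maps any requested duty in the working range (10⁻⁴–10⁻²) to a rate pair
exactly, holding the mean on-time fixed — mirroring how structural tuning
of a dye series shifts off-times far more than on-times.  The pH dependence
of the equilibrium is modelled by `duty_from_ph(pka, hill, ph) =
10^{−hill·(pH−pKa)}`: acid promotes the fluorescent (open) form, so the
duty cycle rises as pH falls and equals 1 at pH = pKa.  The Hill slope
defaults to 1 (a single protonation equilibrium); no published slope was
available to justify anything else.

Defaults of the generator are the regimes the analysis targets: mean
on-time 10 ms; duties 10⁻²–10⁻⁴; frame clocks 3 ms (2-ms exposure) and
27 ms (25-ms exposure), plus 10 ms (100 Hz) for fluctuation imaging;
pixel size 100 nm; PSF sigma 130 nm.  The emitted photon rate while on is
not a published number for these dyes; the default of 5×10⁵ photons/s was
chosen so a full 10-ms blink delivers ~5,000 detected photons — bright-dye
territory, and a peak-pixel SNR comfortably above 10 over a 5
photon/pixel/frame background.  Simulations that need dimmer spots pass
their own rate.

## Image formation

Frame `k` integrates over `[k·cycle, k·cycle + exposure)`.  Expected
signal photons of an emitter in a frame equal `photon_rate ×` (overlap of
its on-intervals with that window), so partial-frame blinks produce
proportionally dimmer spots — the effect the gap-closing and
frame-quantization logic downstream must cope with.  Photons convert to
photoelectrons via the quantum efficiency and spread over pixels by a 2D
Gaussian integrated per pixel (error-function differences, ±4σ support).
Noise: Poisson electron counts; EM gain as a gamma multiplication
(`shape = n_electrons, scale = gain`), the standard EMCCD approximation;
Gaussian read noise; then `ADU = electrons × conversion + offset`.  A
noise-free mode returns the exact expectation for oracle tests (frame sums
conserve photons to <0.5%, limited only by PSF truncation).

Coordinates are continuous nm with origin at the corner of pixel (0, 0);
pixel `(i, j)` spans `[j·px, (j+1)·px) × [i·px, (i+1)·px)`; x runs along
columns, y along rows; frames are 0-based in memory and 1-based in CSV
files.  Drift is applied to the sample (emitters and fiducials alike), so
fiducial-based correction is testable end to end.

Structures: uniform 2D point fields (nuclear-histone-like), persistent-
random-walk polylines with transverse Gaussian jitter of sigma =
width/2 (ER-tubule-like), and uniform balls (condensate-like, radius via
the cube-root transform).

## pKa fitting

Titrations are fit with a four-parameter logistic in pH with base-10
slope (Henderson–Hasselbalch form).  Initialization: pKa₀ at the
half-range crossing, hill₀ = 1; bounded least squares.  The 95% CI is
`pKa ± t₀.₉₇₅,n−₄ · SE` from the parameter covariance; at 2% absorbance
noise on 11 points this CI covers the truth at the nominal rate (the
acceptance suite verifies 93–97% over 500 replicates) and the bias is
<0.02 pH units.

Curves with an interior absorbance maximum — dyes whose ring nitrogens
protonate at very low pH show absorbance peaking near pH 4 before
declining — are **refused**, not fit: only an "apparent" pKa could be
quoted for them and this package deliberately does not define one.  The
monotonicity check applies a centred 3-point median filter before
measuring the largest pH-ordered rise against 5% of the dynamic range;
the filter keeps single-point noise excursions (measured false-rejection
≈1.5% at 2% noise) from masquerading as structure, while a genuine
interior peak (a rise of tens of per cent spanning several points)
survives it.

## Localization

Detection: difference of Gaussians (σ, 2σ; default σ = 1.2 px), local
maxima with non-maximum suppression within ~one PSF radius, threshold =
`dynamic_factor ×` a robust noise scale.  The noise scale is 1.4826 × MAD
of the **raw** frame: the band-pass attenuates white noise roughly
six-fold, so the default factor 1.7 corresponds to an effective ~10σ cut
on the filtered scale; measuring MAD on the filtered frame instead would
make 1.7σ sit inside the noise floor and flood the fitter with false
candidates.

Fitting: Poisson maximum likelihood of an integrated-Gaussian PSF on a
7-px ROI (x, y, photons, background; σ fixed at `sigma_start` by default,
refinable on request), L-BFGS-B with a 25-iteration cap.  One fitter
serves both acquisition styles.  ADU are converted to detected photons
through offset, conversion, EM gain and QE before fitting; the Poisson
model is exact at unit gain and a documented approximation under EM
amplification (excess noise is not modelled in the likelihood).  The
reported lateral precision is the Mortensen MLE formula
`σ² = σ_a²/N · (1 + 4τ + √(2τ/(1+4τ)))` with `σ_a² = σ_PSF² + a²/12` and
`τ = 2π σ_a² b/(N a²)`; Monte-Carlo checks show the empirical SD of
fitted positions within 20% of it, and RMSE within 25% across
N ∈ {200, 500, 2000} at the 130-nm PSF the defaults assume (a 7-px ROI
undersamples substantially wider PSFs, where the bound becomes
optimistic).

Filters keep rows with precision <40 nm and photons above a per-purpose
threshold (100 for blink quantification, 40 for lifetime measurements).
Edge candidates whose ROI leaves the frame are dropped and counted.
Fiducials are identified as spatial clusters present in >95% of frames
(300-nm clustering radius), averaged per frame and interpolated across
gaps; drift is the fiducial-mean displacement from its time average,
optionally box-smoothed, subtracted from all coordinates.

Rendering: count histograms (exactly count-conserving), per-localization
Gaussians of width = reported precision (unit integral each), and average
shifted histograms implemented as a fine histogram at `pixel/magnification`
box-filtered over `magnification/shift` bins — algebraically the average
of the shifted coarse histograms, and count-conserving.

## Blink kinetics

**Linking.**  Walking the filtered table in frame order, a localization
joins an open on-event when its frame is ≤ `gap + 1` frames past the
event's last frame and it lies within `radius` (default 100 nm) of the
event's *running centroid* (robust to single-frame jitter); ties go to
the nearest centroid, then the earlier event.  The default gap of 5
frames treats short sub-threshold dropouts as part of one emission burst.
A property-based suite holds the linker exactly equal to a naive
quadratic transcription of the same rules on thousands of random
instances.

**Grouping.**  Molecules are DBSCAN clusters of all pooled (x, y) at
eps = 100 nm with `min_samples = 1`, which makes the result exactly the
connected components of the ≤ eps adjacency graph — deterministic, no
border ambiguity — appropriate to the sparse-labeling regime in which
off-times are measured.  Off-times are the intervening fully dark frames
between consecutive events times the cycle.

**Durations and the quantization correction.**  An event's on-time is its
frame span × cycle (closed gaps count as on).  An on-interval of true
length L covers on average `L/cycle + 1` frames under perfect detection,
so span-based on-times overestimate by one cycle and dark-gap off-times
underestimate by one cycle, in expectation.  The summary therefore
reports both raw and corrected means (`mean_on − cycle`,
`mean_off + cycle`) and two pooled duty estimators: the raw
`Σon/Σoff` and a corrected pooled ratio built from the corrected means.
The correction is what makes a 10-ms on-time measurable with a 27-ms
clock: in the acceptance suite the corrected estimator recovers duties of
10⁻², 10⁻³ and 10⁻⁴ within a factor of 1.5 and rank-orders them correctly
in ≥99/100 seeded runs.  Events touching the first or last acquisition
frame are censored: counted as blinks, excluded from duration means.

**Gap sweep.**  Re-linking under gaps 1–5 reproduces the expected
validation trend: with simulated 10% missed detections the mean on-time
is non-decreasing in the gap; with perfect detection and off-times long
enough that no true dark interval is gap-closable, all gaps give
identical partitions.

## SOFI

`G₂(p, lag) = ⟨δI(p,t)·δI(p,t+lag)⟩` with the time mean subtracted;
default lag 1 so temporally white shot noise cancels (lag 0 is kept to
demonstrate the bias).  The auto-cumulant on the native grid is the
tested core; nearest-neighbour cross-cumulants on a 2× grid (Gaussian
distance-factor normalization from a supplied PSF width) are optional.

The decorrelation curve is the foreground-pixel mean of G₂ at lags
1…20, normalized at lag 1; foreground is Otsu on the mean-intensity
image unless a mask is supplied.  τ comes from bounded least squares of
`A·e^{−lag/τ} + c` (c ∈ [0, 1]; τ₀ from the first 1/e crossing); the fit
is to the pixel-averaged curve, not per pixel — averaging first is far
more stable for the sparse, low-duty regimes of interest.  For a
telegraph with total rate k sampled at Δt the theory is τ = 1/(k·Δt)
frames; fitted values track this within 20% for k ∈ {10, 25, 50, 100}/s
at 100 Hz, and a matched clock (10-ms on-times at 100 Hz, low duty)
pins τ at its ~1-frame floor — the regime in which fluctuation imaging
works best.

SNR and % useful pixels are defined operationally (the upstream tool's
formulas are not public): SNR = mean |G₂| over foreground / SD of G₂
over background; % useful = percentage of foreground pixels with
|G₂| > 3 background SDs.  The mask provenance is recorded with the
metrics.  Kymographs are raw intensity along a pixel line per frame.

## Fourier ring correlation

Standard ring-wise normalized cross-correlation of two independent
renderings; rings one frequency bin wide; resolution read at the first
downward crossing of 1/7 (the field's convention) with linear
interpolation, floored at twice the rendering pixel (Nyquist).  Images
are zero-padded to a power-of-two square and apodized with a Tukey
window (α = 0.25) to suppress edge ringing; an optional 3-bin smoothing
of the curve is off by default.  Agreement with an un-padded,
un-apodized direct-DFT reference is within 20% on 256² images.  Two
splitting modes: sequential fixed-length frame windows (e.g. 1,470
frames ≈ 5 s) rendered and compared pairwise for resolution-over-time,
and a seeded random half-split of a single table.

## Condensate spatial statistics

Density maps are voxel-count histograms (100-nm voxels by default,
matching the 100-nm slice thickness used for visualization); slices
select a slab `|coord − center| ≤ thickness/2` and bin in-plane; both
conserve counts exactly.

The CSR test uses the index of dispersion (variance/mean) of counts over
voxels lying fully inside the fitted support — near 1 under uniformity,
>1 under clustering — with a Monte-Carlo null: CSR draws of the same n
in the fitted minimal enclosing sphere (Ritter's algorithm with
refinement passes), each draw processed identically to the data
(support refit, same voxel size), `p = (1 + #{null ≥ observed})/(n_null
+ 1)`.  The reported support is padded 2% for geometry, but nulls are
drawn in the *unpadded* sphere: sampling the null from an enlarged
sphere makes it systematically more dispersed than the data and
measurably inflates the type-I error.  Calibration: empirical size at
α = 0.05 within [0.03, 0.07] and p-values uniform under CSR; power
≥90% against a Thomas process (50 parents × 100 offspring, σ = 50 nm,
r = 1.2 µm).  A mean nearest-neighbour-distance statistic is available
as an independent second statistic (one-sided low).  A sphere is assumed
as support because the condensates of interest are spherical; irregular
supports would need a different fit.

## Problem sizes in the test suite

The suites rerun every behaviour at sizes chosen to keep the whole run
around two minutes on one CPU while leaving each conclusion
statistically unambiguous: the τ-floor movie at its native 128×128 ×
10,000 frames; τ-vs-k at 144 telegraph pixels × 4,000 frames, median of
5 seeds; ratio recovery at 60 molecules × 33,333 frames (factor check)
and 20 molecules × 9,000 frames × 100 seeds (rank check); CSR
calibration at 200 runs × 99 nulls; CI coverage at 500 replicates.

## Known limitations

- Two-state photophysics only: no triplet shelving, no photobleaching,
  no multi-exponential dwells.
- 2D image formation; 3D coordinates are consumed as given (no
  astigmatic PSF model), so condensate analyses assume upstream z
  estimation.
- Single-emitter fitting only; overlapping emitters in dense scenes are
  not deconvolved, which is precisely why low duty cycles matter.
- The EM-gain excess noise is simulated but not propagated into the
  fitting likelihood or the Mortensen formula (both assume unit gain
  statistics on the converted photon scale).
- The dispersion-index CSR test is sensitive to clustering at or above
  the voxel scale; heterogeneity much finer than the voxel needs the
  nearest-neighbour statistic or smaller voxels (with correspondingly
  more points).
- SOFI orders >2, balanced/linearized variants and Fourier reweighting
  are out of scope.
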