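# Methods

This note documents the models behind `retinomeg`, the parameters that
matter, and what the synthetic benchmark does and does not show about
real MEG data.

## Coordinate frame and geometry

All positions are meters in a right-handed head-centered frame: +x right,
+y anterior, +z superior.  The conductor is a single homogeneous sphere of
radius 0.09 m centered at the origin.

The source space is a deliberately stylized early visual cortex: per
hemisphere, a dorsal and a ventral rectangular sheet ("calcarine banks")
at z = ±8 mm with opposed surface normals (∓z), spanning a
posterior→anterior extent that carries the eccentricity axis (occipital
pole, y = −70 mm, is foveal; eccentricity increases anteriorly), plus a
small dorsal-anterior patch standing in for V3A and an optional shell of
unlabeled "background" vertices representing non-visual cortex.  Left and
right hemispheres are exact mirror images.  Within each bank, three
mediolateral strips are labeled V1 (medial), V2 and V3; eccentricity bands
1–3 partition the posterior→anterior coordinate by configurable fractions
(default thirds).  The default study space uses 120 labeled vertices per
hemisphere (12 of them V3A) at 4 mm spacing plus 48 background vertices,
chosen so that every angular subregion (18 vertices), V3A side (12) and
eccentricity band (⅓ of V1–V3) has exactly the chance-level size fraction:
uniform-random active sets then reproduce 25 / 50 / 33⅓ % accuracy by
construction, which the test suite verifies by Monte Carlo.

Retinotopy rules encoded in the atlas: contralateral hemisphere; upper
visual field → ventral bank; lower field → dorsal bank; ring of
eccentricity k → band k across V1–V3 bilaterally; quarter-rings intersect
the angular subregion with the band.

## Forward model

Magnetometers measure the field component along their (radial)
orientation; each planar gradiometer reports a two-point finite difference
of that component along one of two orthogonal tangential axes, divided by
the 16.8 mm baseline (a Neuromag-like arrangement; the two gradiometers of
a pair share a site).  The field of a current dipole inside the sphere is
the closed Sarvas form, which preserves the physically essential
radial-silence property: a radial dipole produces no external field, so
background vertices are given tangential orientations to keep every
lead-field column informative.  The implementation is validated (to <1%)
against an independent oracle that computes the Biot–Savart field of the
primary dipole plus the Geselowitz surface integral of the volume
currents, with the surface potential from the classic Legendre series —
a different theoretical route through the same physics.

The default array has 60 magnetometers and 120 gradiometers: 40% of the
sites packed in two rings over the occiput, the rest quasi-uniform over
the upper helmet (radius 0.102 m).  A full 306-channel emulation is a
parameter choice, not a code change.

## Signal and noise model

Each trial is lead field × (patch weights × source waveform) + a draw of
stationary sensor noise.  The source waveform per active vertex is zero
before stimulus onset, a Gaussian first response peak (FRP) centered at
83 ms with 10 ms SD, and a ramped sinusoid at the second harmonic of the
4 Hz contrast-reversal rate (8 Hz) from 125 ms (the first contrast change)
to stimulus offset at 1000 ms, phase-locked across trials.  Amplitudes are
per-vertex dipole moments: 1 nAm for the FRP and 0.4 nAm for the steady
state.  At 4 mm spacing a vertex represents roughly 16 mm² of cortex, and
with typical cortical current densities (tens to hundreds of pAm/mm²)
1 nAm is a realistic effective moment; together with the noise model below
it leaves the single-trial FRP near the detection threshold (peak sensor
SNR ≈ 3) while 95-trial averages are clean, high-SNR responses — the
regime the acceptance properties are stated for.

Stimulus → patch: quadrants activate the full contralateral
dorsal-or-ventral subregion across V1–V3 (all bands — the stimuli span
0–5.4°) with contralateral V3A co-activated at 0.3 relative weight; rings
activate band k bilaterally in both banks; quarter-rings one angular
subregion × band.  Weights taper smoothly from 1 at the patch centroid to
0.5 at the rim.

Noise is zero-mean Gaussian, white in time by default (an optional 1/f
exponent colors it), with spatial correlation exp(−d/0.1 m) within each
sensor kind plus a 0.2 diagonal nugget (so co-located gradiometer pairs
stay non-degenerate).  Standard deviations per sample: 1.2e−13 T
(magnetometers), 7e−12 T/m (gradiometers) — chosen to sit near
instrument-plus-environment noise floors over a ~40 Hz bandwidth and to
produce the single-trial SNR above.

Quadrant protocols present stimuli back-to-back with no inter-stimulus
interval, so each epoch's −500…0 ms baseline contains the steady-state
tail of the *previous* stimulus; the simulator reproduces this
contamination because the real noise-covariance window would contain it.
Ring and quarter-ring protocols draw 600/800/1000 ms gaps (seeded
pseudo-random order), leaving the nominal baseline signal-free.

**Filter margins.**  Real pipelines filter continuous recordings, which
have no epoch edges.  Filtering finite epochs with a 1 Hz high-pass corner
leaves edge transients extending several hundred milliseconds, which would
inflate baseline variance and destroy the dSPM calibration.  The simulator
therefore generates each epoch with a 500 ms margin on both sides, and the
band-pass (zero-phase Butterworth, order 6) trims the margin after
filtering; all retained samples are transient-free.

## Inverse methods

All methods share the fixed-orientation (surface-normal) lead field.
Magnetometers and gradiometers are combined by whitening with the baseline
noise covariance — the whitened channels are unitless, which is how the
two sensor kinds become commensurable.  The noise covariance is the
empirical baseline (−500…0 ms) covariance pooled over trials, shrunk 10%
toward its diagonal.

**Minimum norm / dSPM.**  In whitened space, source weighting R has
diagonal (‖g̃ᵢ‖²)^(−p) with depth exponent p = 0.8 by default (p = 0 is
the IID variant), rescaled so trace(G̃ R G̃ᵀ) equals the channel count;
the kernel is R G̃ᵀ (G̃ R G̃ᵀ + λ²I)⁻¹ with λ² = 1/SNR² and an assumed
SNR of 3 (λ² = 1/9).  dSPM divides each source estimate by its noise
standard deviation *estimated from the projected baseline samples*
(scaled by 1/nave for an nave-trial average) and squares, giving an
F-like statistic that is ≈ 1 on source-free data and exactly invariant to
a global rescaling of the noise covariance.  The F map is averaged over a
20 ms window centered on the 83 ms FRP.  The IID variant is scored, like
the beamformer and MSP, by a trial-wise GLM t over a 40 ms
Gaussian-weighted window.

**LCMV beamformer.**  Weights w = C⁻¹l/(lᵀC⁻¹l) from the pooled
band-limited data covariance over 0–1000 ms, regularized by 5% of its
mean eigenvalue.  Evoked mode: 1–40 Hz, per-trial value = signed mean of
the projected time course over the 20 ms FRP window (the signed mean, not
power, mirrors a trial-wise difference contrast; power is reserved for the
TF mode).  Time-frequency mode: 7–9 Hz band power over 200–1000 ms, which
excludes the FRP and isolates the 8 Hz frequency tag.  Contrasts:
stimulus vs. the other stimuli for quadrants (no silent baseline exists);
stimulus vs. the −250…0 ms baseline for ring families.  The unit-gain
constraint keeps noise-only t maps free of systematic depth bias, which
the suite checks by Monte Carlo.

**Multiple sparse priors.**  The source covariance is a non-negative
combination of patch components: smooth profiles exp(−(d/σ)²) with
σ = 8 mm (support truncated below 1% of peak, i.e. beyond 3σ), 48
unilateral components with centers sampled evenly over the labeled sheets
plus 24 *correlated bilateral* components whose single profile spans a
mirror-symmetric patch pair — bilaterally synchronous activity selects
these, unilateral activity the former.  Hyperparameters maximize the
restricted log likelihood (variational free energy) of the
Gaussian-weighted window sample covariance via multiplicative fixed-point
updates (non-negative by construction, ReML stationarity as fixed point,
at most 128 iterations, ascent verified per iteration), followed by greedy
backward elimination: components are removed, smallest hyperparameter
first, whenever removal plus a short refit costs less free energy than a
BIC-style complexity charge of ½·log n_eff per hyperparameter.  On
single-patch data this leaves ≲5% of the library selected.  The posterior
mean is applied per trial; the default window is 40 ms Gaussian-weighted
on the FRP, with a flat 50–200 ms variant for comparison.  With a single
identity component the posterior mean reduces algebraically to the IID
minimum norm at matched regularization (tested).

## Evaluation framework

A reconstruction's active set is the top q% of vertices by statistic
across the whole source space; ties at the cutoff are all included.
Accuracy for a stimulus × ROI is 100·|active ∩ expected| / |active ∩ ROI|;
an empty intersection with the ROI flags the record excluded (it is
retained and reported, and counts as zero during threshold sweeps).  The
threshold grid is {0.1, 0.2, 0.5, 1, 2, 5, 10}%, and q is fixed per
subject × method at the sweep maximum (ties → smallest q), with the
objective being mean accuracy across the subject's stimuli over V1–V3.

Group inference: Wilcoxon signed-rank against the chance level, exact by
tie-aware enumeration of the W⁺ distribution for n ≤ 25 and a
continuity-and-tie-corrected normal approximation above; one-sided
("greater") by default since the hypothesis is localization *better* than
chance, with two-sided available.  Kruskal–Wallis (tie-corrected H, χ²
reference) compares methods.  Bonferroni families default to 16
(quadrants: 4 ROIs × 4 method columns), 9 (rings) and 4 (quarter-rings),
all configurable.

## Numerical choices and degenerate inputs

* Percentile cutoff: the ceil(q·n/100)-th largest value; all-equal maps
  activate everything (tie rule).
* Whitening uses a symmetric inverse square root; eigenvalues below
  1e−12 of the maximum raise a rank-deficiency error naming the
  covariance (increase shrinkage).
* ReML convergence: relative free-energy change ≤ 1e−6 per iteration;
  non-convergence warns and returns the best iterate, flagged in the
  estimate's provenance.
* Dipoles at the sphere center are rejected (field direction undefined);
  sources outside / sensors inside the sphere are construction errors.
* Zero-noise simulations are supported (PSD square root via
  eigendecomposition), which the forward-consistency tests rely on.
* Seeds: one master seed per study; per-subject seeds derive from it via
  `SeedSequence([seed, subject_index])`, so any subject is reproducible in
  isolation and all tabular outputs are byte-identical across reruns.

## Problem sizes

The default study conditions are desk-scale by design: 336 vertices,
180 channels, 6/7/5 subjects × ≥95 trials per stimulus for
quadrants/rings/quarter-rings.  They preserve the structure of the
full-scale problem (bank geometry, sensor mixture, trial counts, timing)
while keeping a complete multi-subject study in the minutes range on one
CPU.

## What the benchmark does and does not show

The generator reproduces the features that drive the methodological
story: retinotopic patch geometry with opposed calcarine banks (hence
bilateral field cancellation for rings — the per-active-vertex sensor RMS
of a ring patch is several-fold lower than a matched quarter-ring's),
correlated mirror sources (which depress beamformer output — both
mechanisms are asserted in the acceptance suite), depth-varying
eccentricity bands, a frequency-taggable steady state, and the
contaminated quadrant baseline.  It does *not* emulate realistic cortical
folding, inter-subject anatomical variability, co-registration error,
head movement, ocular/cardiac artifacts, or non-stationary environmental
noise.  Passing tests therefore validate the implementations and the
relative behavior of the priors under controlled conditions; they do not
predict absolute accuracy values on real human recordings, which depend
on anatomy, co-registration and noise conditions this generator does not
model.

Known limitations: the spherical conductor ignores return-current
asymmetries of real heads; the stylized sheets make V1/V2/V3 equally
detectable, whereas real V2/V3 geometry differs; MSP and the minimum norm
run on the same mesh by default (a template-vs-individual mismatch mode is
a geometry perturbation away but not built in); and evoked-mode beamformer
trial values are signed window means — a power variant would behave
differently for non-phase-locked responses.
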