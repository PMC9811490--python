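# Methods

This note records the models, parameter choices and numerical decisions
behind `hemipact`, and what the synthetic studies do and do not show
about real instruments.

## Array geometry and aperture coverage

Element centers follow a golden-angle (Fibonacci) spiral on a spherical
cap of radius R = 60 mm, equal-area in solid angle:
cos θᵢ = 1 − (i/N)(1 − cos Θ) with Θ = 63.6° and golden-angle azimuths.
The layout has three useful exact properties: channel order ascends in
polar angle, so the first N/4 channels form the polar cluster; the
prefix of k channels covers exactly k/N of the cap's solid angle; and a
Monte-Carlo Voronoi assignment shows per-element cells uniform to a few
percent (outer-ring cells excepted).  An element of area A = 12 mm²
subtends angular radius δ with 2πR²(1 − cos δ) = A (δ ≈ 1.87°).  The
coverage of a subset is the analytic cap out to the outermost selected
center plus δ: Ω = 2π(1 − cos(θ_out + δ)).  With these constants the
full and cluster apertures cover 1.170π and 0.312π sr; Θ is the one
free constant, chosen so both printed coverages hold simultaneously.
The true channel-to-position map of the commercial array is unknown;
"channels 1–256" is honored as an ordering convention.  A single-element
array degenerates to one element at the pole.

## Forward model

Each absorbing voxel is a point source under uniform fluence
(amplitude = absorption): no fluence heterogeneity, no acoustic
attenuation, point detectors (no element directivity or crosstalk).
The transducer response is a Gaussian-enveloped cosine at
f_c = 2.02 MHz whose −6 dB band equals f_c·(1 ± 0.27) (54% fractional
bandwidth); signals are sampled at 8.33 MHz.  The physical N-shaped
photoacoustic wavelet is folded into this response so the envelope peak
arrives at t = r/c, which is what the delay-and-sum inverse assumes.
Because the carrier has only ~4 samples per cycle, the simulator
evaluates the analytic Gaussian-cosine at exact sub-sample lags rather
than interpolating discrete taps (interpolation would attenuate
contributions by a phase-dependent factor of up to ~30%).  Amplitudes
carry 1/r spherical spreading normalized to r_ref = R.  The recording
window is computed from the whole array over the grid corners, so
frames of different subsets share t0 and the cluster rows of a full
frame equal the cluster frame exactly.  Speed of sound defaults to
1500 m/s (homogeneous), configurable.

## Delay-and-sum reconstruction

v(x) = Σᵢ sᵢ(‖x − pᵢ‖/c) with linear interpolation between samples, no
apodization, zero contribution outside the recorded window; the output
stays signed and |·| is taken only for display and metrics.  Default
grid: 128³ voxels at 0.1 mm.  The inner loop is a numba kernel; a naive
per-element `np.interp` oracle and a pure-Python triple loop back it in
the tests to 1e-6 relative.  Whole-body stitching takes the voxelwise
maximum over volumes placed at voxel-commensurate offsets (50% overlap
by default in scan plans).  Depth encoding colors the first argmax
along the projection axis.  FWHM is measured on the |amplitude| profile
through the peak, walking outward to the first half-maximum crossing
with linear interpolation, so side lobes beyond the first crossing are
ignored.

### Fidelity of the resolution study

The model reproduces the instrument's *axial* point-spread widths
(full/sparse ≈ 320–330 µm and cluster-z ≈ 265 µm on the 0.1 mm grid,
against measured ≈ 380 and ≈ 300 µm) but overestimates the *lateral*
widths by ~1.45–1.55× (full/sparse ≈ 480–580 µm vs ≈ 380; cluster-xy
≈ 1060 µm vs ≈ 700).  This is a property of the signed point-detector
delay-and-sum itself: the lateral PSF width is governed by carrier
dephasing across the aperture, FWHM_lat ≈ √(2 ln 2)·λ/(2π σ_u) with
σ_u the spread of sin θ cos φ over the cap (≈ 0.476 here, λ = 0.74 mm),
which matches the simulation analytically.  No carrier frequency can
reproduce a truly isotropic measured PSF under this model — raising f_c
to fix the lateral width would break the axial match — so the gap is
attributed to unmodeled system factors (element directivity, the real
pulse shape, display-chain envelope processing).  The *relative*
statements survive: sparse ≈ full on every axis, and the cluster is
z-sharpened and laterally blurred.  Conclusions drawn from the twin
about absolute lateral resolution should carry this ~1.5× caveat.

## Synthetic phantoms and dynamics

Vessel trees are random correlated walks with branching and tapering
radii; organs are ellipsoids; all generators are pure functions of
(parameters, seed) and dynamic sequences vary only in amplitude, never
in geometry.  ICG kinetics use a peak-normalized gamma-variate
((t−t₀)/(αβ))^α·exp(α − (t−t₀)/β) per compartment on a constant blood
baseline (0.3 of the unit dose): vessel t₀ = 2 s, peak 5 s; kidney peak
20 s; liver peak 60 s — a standard bolus model reproducing the reported
vessel → kidney → liver arrival order; the dose-to-amplitude map of the
real agent is unquantified, so amplitudes are arbitrary units.
Physiological modulation is multiplicative: 5% at 0.7 Hz (respiration)
and 2% at 5 Hz (cardiac).  The oxygen challenge composes
PA_λ = ε_HbO(λ)·sO₂·HbT + ε_HbR(λ)·(1 − sO₂)·HbT per voxel from a
piecewise schedule (default 2 min at 0.95, 2 min at 0.70, 2 min at
0.95 — hyperoxia/hypoxia plateaus chosen as typical cortical values);
extinction coefficients ship as configurable constants (750 nm:
ε_HbO = 518, ε_HbR = 1405; 850 nm: 1058, 691 cm⁻¹ M⁻¹) and every
correctness test is table-agnostic.

What the phantoms deliberately lack: anatomical realism, fluence
heterogeneity, motion, and instrument noise floors.  Passing tests
therefore demonstrate the correctness and internal consistency of the
computational chain, not in vivo performance.

## Progressive 3D U-net

Implemented on a small numpy reverse-mode autodiff core
(`hemipact.nn`): im2col-based 3D convolution, batch normalization
(momentum 0.1, ε = 1e-5, appended to every learned convolution), ReLU,
2× average pooling, 2× trilinear upsampling, and the Adam optimizer
with L2 coefficient 2e-6 added to the gradients.

Architecture.  Per-scale "from" (3³ conv block) and "to" (1³ linear
conv) layers frame a shared body.  Each level combines a channel-wise
skip (encoder feature concatenated into the decoder) and two voxel-wise
skips: the encoder feature added after fusion, and the input volume
added to the "to" output at every scale, so an untrained network is
near-identity (the "to" convs are initialized at std 0.01).  Channel
widths double toward coarse scales from a base (published preset: base
16, cap 128, scales 16³–128³ with batch sizes 16/16/8/4; desk preset:
base 8, cap 32, scales 8³/16³/32³ with batch sizes 16/16/8).  The
coarsest scale carries a constant-width U-net core of depth
log₂(edge) − 2.

Progression.  Growth appends one finer level; existing parameters are
untouched (bit-exact, asserted in tests).  During a stage's first half
(fade_in_fraction = 0.5) the blend weight α ramps linearly 0 → 1 at
both ends of the new level: the inner body receives
α·(new encoder path) + (1−α)·from_prev(2×-downsampled input), and the
output is α·(new decoder path + input) + (1−α)·upsample(previous "to"
output + downsampled input).  At α = 0 the grown network therefore
equals the upsampled coarse network exactly; the residual term is kept
inside both branches to preserve that identity.  Per stage: a fresh
Adam at the configured rate, plateau-based LR halving (patience 10),
early stopping (patience 20), seeded 90/10 train/validation split.

Loss.  J = λ·mean|V̂ − V| + (1−λ)·(1 − SSIM₃D) with λ = 0.2.  The SSIM
term uses an 11³ Gaussian window (σ = 1.5, canonical SSIM defaults),
zero-padded so gradients exist everywhere including 8³ stages (the
window shrinks to the volume edge when larger); the metrics module
evaluates the identical computation under `boundary="pad"`, and tests
hold the two equal to 1e-9.

Training data and normalization.  Pairs are (|cluster DAS|, |full DAS|)
volumes of the same phantom, min-max normalized by the global bounds of
each parent set (not per volume), preserving relative brightness; the
input and target sets carry their own bounds since the 256-channel sum
is ~4× dimmer than the 1024-channel sum.

Desk preset.  The factory for paired data uses a 256-element array
(element area scaled ×4 to keep the published coverage fractions,
cluster = first 64 channels) and 32³ grids at 0.4 mm — enough voxels to
express the cluster's ~2-voxel lateral blur.  The desk learning rate is
1e-3: the published 1e-4 belongs to the GPU-scale problem (1089 volumes
at 128³) and moves the tiny desk network too slowly to converge within
its short stages.  Ten epochs per stage train in ~8 minutes on one CPU.
Validation losses are compared within a stage only; across scales the
objective changes (different resolution and effective window), so
cross-stage loss values are not commensurable.

## Metrics

SSIM follows the standard windowed-statistics form with C₁ = (0.01 L)²,
C₂ = (0.03 L)², L = 1 for normalized volumes; the volumetric score
averages the map over the region where the window fits ("valid"),
matching the reference implementations (skimage is the independent
cross-check in tests).  MS-SSIM multiplies the contrast-structure term
over dyadic scales (2³ block-mean + subsample) with the luminance term
at the coarsest scale, weights = the canonical 5-scale vector truncated
and renormalized.  The published configuration NumScale = 4, Sigma = 8
implies a 49³ window and hence volumes of edge ≥ 392 — it is kept as
the documented default for large stitched volumes, while desk-scale
evaluations use num_scales = 2, σ = 1.5 (window 11³, valid for edges
≥ 44, or ≥ 22 single-scale).  Negative mean contrast-structure terms
are clamped at 0 before exponentiation.  PSNR = 10·log₁₀(peakval²/MSE)
with peakval defaulting to 1; identical volumes report +∞.  Metrics
operate on |amplitude| volumes under the training normalization.

## Unmixing

Negatives are clipped and a 3³ median filter applied before unmixing
(`scipy.ndimage`).  The default solver inverts the 2×2 extinction
matrix per voxel and clips negative concentrations post hoc; an exact
non-negative mode re-fits the free chromophore where a constraint is
active (for two wavelengths/two chromophores the modes coincide except
at sign violations, and with positive extinction values and
non-negative data both concentrations cannot be negative at once).
The HbT mask threshold defaults to 0.1 × max(HbT) (unstated in the
source system; config-exposed).  sO₂ is scale-invariant, so it survives
the linear acoustic round trip essentially exactly wherever the
reconstruction is positive — the end-to-end challenge test recovers the
schedule to < 0.02 with transitions at ± one frame.

## Dynamics

VOI traces are plain means over 10³-voxel blocks; the 5-frame centered
moving average shrinks its window at the edges.  Time-to-peak uses the
same smoothing, subtracts the pre-injection baseline mean, takes the
first maximum on ties, and flags constant voxels invalid.  Dominant-
frequency extraction removes the mean and a linear trend and applies a
Hann taper before the FFT: with a rectangular window the spectral
leakage of the aperiodic bolus transient decays only as 1/k and can
exceed the few-percent respiration sideband at the 0.2 Hz band edge of
a 60 s window, whereas Hann leakage (∝ 1/k³) leaves the 0.7 Hz line
dominant; the taper widens the main lobe but keeps the peak within one
FFT bin.

## I/O and determinism

Volumes: NIfTI (voxel size in the affine), TIFF (+ JSON sidecar for
spacing, since plain TIFF has none), HDF5; signal frames and sequences:
HDF5 with all acquisition attributes required on load.  Arrays are
float32 on disk; DAS and metric accumulations are float64 internally
(the NN core is float32).  All randomness flows from explicit seeds
through `numpy.random.Generator`; training, simulation and the pipeline
driver are bit-reproducible on a fixed platform, and the pipeline
manifest records SHA-256 checksums to prove it.

## Known limitations

No full-wave acoustics, attenuation, dispersion, or heterogeneous media;
no element directivity (see the resolution caveat); no adversarial
training (the progressive scheme is supervised only); no model-based
reconstruction or speed-of-sound autofocus; the published-scale network
(128³, thousands of volumes) is configurable but not trained here — the
desk preset demonstrates the mechanism, not in vivo image quality.
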