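# Methods

`bandloc` localizes movement-related oscillatory EEG changes on a cortical
dipole-patch model and compares them with BOLD fMRI activations mapped onto
the same patches. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Forward model

Cortical sources are dipole patches: each patch is one equivalent current
dipole with a fixed orientation perpendicular to the local cortical
surface, so a source is a single scalar amplitude per patch. The lead
field K (sensors × patches, µV per unit dipole moment) can be loaded from
file — the route for lead fields computed with realistic FDM/FEM/BEM head
models — or generated by the built-in analytic head model.

The analytic model is a four-shell concentric sphere (brain, CSF, skull,
scalp) with default radii 80/81/86/92 mm (a typical adult head) and
conductivities 0.25 / 1.79 / 0.018 / 0.44 S/m from the tissue-conductivity
literature. Eyeball (1.5 S/m) and white matter (0.35 S/m) values are
stored on `ConductivityProfile` for completeness but a concentric-sphere
geometry has no compartment for them; they are unused. For each spherical-
harmonic order n the radial two-point boundary-value problem (potential and
radial-current continuity at each interface, insulating scalp) is solved as
a small linear system with radii scaled by the scalp radius, and the scalp
potential is the resulting Legendre series:

* truncation default `n_terms = 60`; a `ConvergenceError` is raised when
  the last retained order still contributes more than 1e-8 (relative) for
  the worst patch. This bounds usable patch eccentricity to ~0.70 of the
  scalp radius at the default truncation; the synthetic patch models
  therefore keep centers at 30–64 mm. Superficial sources need a larger
  `n_terms`.
* the homogeneous (equal-conductivity) limit is checked in the tests
  against an independent closed-form single-sphere solution built from the
  summed generating functions of two current monopoles — no truncated
  series on the oracle side.

Coordinates are a right-handed head frame in mm, origin at the sphere
center; all distances in the metrics layer are Euclidean in this frame.

## Preprocessing

Fixed order, enforced by the pipeline driver: zero-phase 1–120 Hz
Butterworth band-pass plus a Q=30 notch at 60 Hz on the continuous record;
epoch extraction at −1000…+1000 ms around each response onset (endpoints
inclusive on the sample grid, events too close to a recording edge are
dropped and counted); per-trial bad-channel detection — a channel whose
signal, smoothed with a centered 80 ms boxcar (edges shrink), exceeds
200 µV anywhere — followed by spherical-spline replacement (Perrin-type,
order m = 4, 50 Legendre terms, regularization 1e-5, positions projected to
the unit sphere); artifact-epoch rejection; common-average re-referencing.

The rejection rule deserves a note: a literal ±25 µV absolute-amplitude
bound would reject essentially all EEG (normal background exceeds it and
the bad-*channel* rule sits at 200 µV). It is implemented as a
fast-transient criterion — reject a trial when any channel's
sample-to-sample first difference exceeds 25 µV — which is what blink and
muscle artifacts violate while ongoing oscillations (a 20 µV, 10 Hz rhythm
moves ~1.3 µV per sample at 1 kHz) do not. `mode="absolute"` is available
for the literal reading.

ICA denoising is out of scope (component selection is inherently manual);
`preprocess_pipeline(..., cleaned_hook=...)` is the injection point for
externally denoised epochs, called after channel repair and before
rejection.

## Time-frequency decomposition

Complex Morlet wavelets with a constant cycles-to-frequency ratio
(default 7; below 5 a warning is issued since the wavelet then spans less
than one full cycle of margin): σ_t = ratio/(2πf), Gaussian-windowed
complex exponential, truncated at ±3.5 σ_t (<0.1 % energy loss) and
normalized to unit energy. Coefficients are evaluated every 10 ms over
integer center frequencies 1–120 Hz. Grid points whose truncated support
extends beyond the epoch are flagged invalid rather than silently
zero-padded; all downstream baselines use only valid points.

Sensor-level ERD/ERS is 100·(P̄(t) − B)/B per channel and frequency, with
P̄ the trial-averaged power and B the mean of P̄ over the valid samples in
the −1000…−600 ms pre-movement baseline. Band aggregation is the
unweighted mean over integer bins (theta 5–8, mu 9–13, beta 14–30, low
gamma 31–60, high gamma 61–120 Hz); bins 59–61 Hz sit in the line-noise
notch's dead band and are excluded from band means by default. Display
thresholding keeps the top 10 % of |relative power| per band (configurable,
and switchable to a whole-plane cut), and the volume-conduction
plausibility screen keeps a suprathreshold (band, time) feature only where
the hot channels contain a connected component of ≥ 4 under the sensor
adjacency.

## Inverse solution

With common-average data y and lead field K (columns centered to match),
the minimum-norm transform is T = Kᵀ(KKᵀ + λH)⁺ where H is the
average-reference centering projector (the natural identity on the
rank-deficient sensor space; pseudoinverse cutoff 1e-10) and
λ = λ_rel·trace(KKᵀ)/n_sensors. λ_rel defaults to 0.05 — standard
minimum-norm practice; the standardized ratio below is insensitive to it
over orders of magnitude. sLORETA standardizes per patch by the
resolution-matrix diagonal S_jj = [TK]_jj (scalars, because orientations
are fixed): estimate_j = (Ty)_j/√S_jj. This estimator has zero
localization error for noiseless single sources, verified exhaustively in
the tests; the unstandardized minimum norm demonstrably mislocalizes deep
sources on the same toy in the underdetermined regime.

The operator is applied directly to the complex wavelet coefficients (real
and imaginary parts identically — the map commutes with global phase).
Source power is the trial-averaged |X|². The source-space baseline at
frequency f is a single coefficient per patch taken at
t_b = −600 − 3.5 σ_t ms (support just inside the baseline window), snapped
to the 10 ms grid. Two consequences:

* frequencies with 7 σ_t > 400 ms (below ≈19.5 Hz at ratio 7) have no
  feasible baseline in a −1000…−600 ms window and raise
  `BaselineInfeasibleError`. Band summaries in the recovery experiments
  therefore use the feasible 20–30 Hz upper-beta bins — for a band-wide
  amplitude change the relative power is the same in every carrier-bearing
  bin, so this does not bias the estimate;
* the alternative reading that places the wavelet *center* at −600 ms is
  available as `placement="center"`, which admits lower frequencies at the
  cost of letting the support overlap movement-related activity.

Relative source power is 100·(P − B)/B; negative is ERD, positive ERS.

## BOLD-to-patch mapping

Z volumes must already be in the patch frame (an optional 4×4 affine is
applied on load; registration chains are out of scope). Each finite voxel
is assigned to its nearest patch center within 6 mm (≈ one inter-patch
spacing); ties within 1e-9 mm go to the lowest patch id, making the
assignment order-independent. NaN marks non-brain and is excluded from all
counts. A patch is active when ≥ 25 % of its voxels reach Z ≥ 2.5, and its
value is then the mean of the suprathreshold Z; otherwise exactly 0.
Raising either threshold can only shrink the active set (tested).

## Localization metrics

Activity maps enter the metrics through their magnitude: a
desynchronization is localizable activity, its sign kept only for labeling.
The active set is { i : a_i ≥ 0.97·max a }. Reported per session: peak
position (argmax, ties to lowest id), center of gravity (activity-weighted
mean position over the active set), distance of each to a representative
central-sulcus dipole, the activity-weighted mean distance
Σ wᵢ‖r_test − rᵢ‖, EEG-to-BOLD peak-to-peak and COG-to-COG distances, and
the three ROI ratios (ROI-AR on the thresholded map; ROI-SHR and ROI-BHR
on the raw magnitudes — ratios of mean ROI activity to same- and
both-hemisphere means). Missing BOLD positions are flagged and excluded
from group means rather than fatal. Group summaries report mean ± SEM
(sd/√n, ddof = 1) with an explicit, recorded drop list for outlier
sessions.

## Synthetic benchmark

`simulate_session` generates a self-paced button-press session: events
every 2 s, default 180 trials at 1 kHz (the ballpark of the 164–197
artifact-free trials per condition a real session yields). Sources are
patches emitting carrier × envelope: beta ERD drops to (1 − depth) of its
baseline amplitude from −500 ms to +300 ms around the response
(depth 0.5 ⇒ a −75 % power change); ERS is a Gaussian burst over a small
baseline amplitude. Carriers are band-limited Gaussian noise by default
("broadband" — physiologically, beta ERD spans the band) or a fixed
sinusoid with fresh uniform random phase each trial, so the effect is
induced, not evoked; a phase-locked switch exists for theta-like tests.
Background is 1/f (power exponent 1.0) activity generated *in source
space* on up to 200 random patches and projected through the lead field,
so inverse-stage noise has realistic spatial correlation, plus 2 µV white
sensor noise. Source amplitude is set so the best sensor sees an in-band
SNR of 5 by default. Artifact injection: 3 % of trials get a 400 µV, 2 Hz
drifting electrode (exercises the 200 µV/80 ms rule) and 3 % a 300 µV
step-like frontal blink (exercises the ±25 µV transient rule — though when
a blink covers several channels the bad-channel stage may legitimately
repair it first).

What the benchmark shows: depth-calibrated recovery (−75 % ± a few points
at the true patch), exact peak localization at SNR 5, correct ERD/ERS
signs, and exact BOLD patch-set recovery for noise-free blobs. What it
does not show: performance under realistic cortical geometry (the sphere
has no sulci; patch orientations are jittered radial vectors), under
correlated multi-source activity, head-model error, or real artifact
morphology. The paper-scale distance and ROI-ratio values from human
sessions are not reproducible from synthetic data and are not targets
here; the synthetic distances are near zero because the generator's truth
is exactly representable.

Desk-scale defaults: 64 sensors and 80 patches for the full recovery
experiment (the 256-sensor layout and 1200 patches/hemisphere model are
available for full-scale runs); 32 sensors / 40 patches for the fixture
suite. Runtime of the full recovery experiment is about a minute on one
core.

## Degenerate inputs and tie-breaks

All-zero activity maps, zero baselines, empty ROI sets, all-rejected trial
sets, dimension mismatches and non-finite file contents raise typed errors
(`bandloc.errors`) naming the offending quantity. Argmax ties resolve to
the lowest index; voxel-assignment ties to the lowest patch id; the
boxcar's edge windows shrink rather than pad.
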