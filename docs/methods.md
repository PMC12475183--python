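# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not show
about real recordings.

## Synthetic movement model

Passive wrist flexion/extension is modeled as a sequence of half-cycles.
Half-cycle k runs from one displacement extremum to the next; within it the
displacement is `(-1)^k · A · cos(π τ / d_k)`, which keeps velocity zero at
every extremum so the trajectory is C¹. The acceleration used for the
simulated sensor is the exact second derivative of this shape.

**Duty asymmetry.** Flexion takes `flexion_fraction` (default 0.45) of the
period and extension the remainder. Real passive wrist movement is not
time-symmetric, and the asymmetry matters analytically: the Euclidean-norm
("Magnitude") acceleration summary rectifies the signal, and a perfectly
time-symmetric waveform rectifies to even harmonics only — it would carry
*no* power at the fundamental, making 2 Hz coherence with the Magnitude
methods undefined in principle. A 0.45/0.55 duty split restores a clear
fundamental component (the flexion and extension acceleration amplitudes
differ by ~50%) while keeping the motion visually plausible.

**Timing jitter with metronome correction.** Half-cycle durations are
`nominal + e_k − g·φ_k`, with `e_k ~ N(0, σ²)`, `φ_k` the accumulated phase
error, and correction gain `g` (default 0.8). This bounds long-run drift
(the mean period equals the nominal period to < 1 ms at any jitter) and
reproduces compensation within roughly one movement cycle, matching how a
human following a visual metronome behaves. σ is calibrated in closed form
so the stationary interquartile range of peak-to-peak periods equals
`period_jitter_ms` (default 22 ms, in the range observed for
physiotherapist-imposed movement). The IQR of a normal variable is 1.349 sd,
and the period variance under the correction dynamics is
`σ²[(1−g)² + 1 + g²(2−g)²/(1−(1−g)²)]`.

**Accelerometer.** The 1-d acceleration is projected onto a random fixed
orthonormal device frame; 1 g gravity is added to the raw z axis; samples
are quantized to the 16-bit ±4 g resolution (1 step ≈ 1.197·10⁻³ m/s²).
Device timestamps carry a constant clock offset (13.7 ms) and a relative
rate error (2·10⁻⁵) so the TTL synchronization path is exercised. 8th-bit
flips toggle bit 7 (±128 steps) per sample/axis with probability
`bitflip_prob` (default 10⁻⁴).

A consequence of taking the published flip-detection rule literally
(consecutive differences exceeding 127 steps in opposite directions): a
±128-step flip riding a movement slope steeper than ~1 step/sample fails one
of the two inequalities and passes through undetected. The repair therefore
catches flips near movement extrema and misses some on fast slopes; an
undetected flip perturbs a single sample by ~0.15 m/s² and is immaterial
after the 50 Hz low-pass or the double integration.

## Synthetic EEG model

Background EEG is independent 1/f^α noise per channel (α = 1, RMS 1 in
arbitrary units). The cortical source is
`cos(2πφ(t)) + harmonic_ratio · cos(4πφ(t))` where φ is the movement phase
in cycles — phase-locked to the jittered movement, not to an ideal clock.
It is projected to the scalp with a Gaussian falloff in 3-D electrode
distance (σ = 0.35 on the unit sphere) centered on `source_channel`
(default C3, contralateral to a moved right hand). No biophysical head
model is intended; a focal topography is all that recovery and
CSD-sharpening tests require.

Two free amplitudes have no published values and were fixed once on
realism grounds:

- `harmonic_ratio = 0.25`. The F1 line competes against a 1/f background
  that is half as strong at 4 Hz as at 2 Hz, so the EEG-side SNR ratio
  between F0 and F1 bins is `(1/hr²)·(bg₄/bg₂) ≈ 8`. This yields spectra
  whose global maximum is at 2 Hz with a clear secondary 4 Hz peak — the
  qualitative structure reported for this protocol — rather than two
  near-saturated peaks whose ordering is decided by estimator noise.
- `source_snr = 0.1` (broadband source/background power at the focal
  channel). This produces peak coherences of roughly 0.3–0.9 at 0.5 Hz
  resolution, in the range of EEG CKC measurements and safely below the
  estimator's saturation at 1.

Blinks are Poisson events (0.15 Hz) with a 350 ms Hann² waveform, frontal
Gaussian topography and 1.5×/0.3× copies in VEOG/HEOG. Gel bridges replace
both members of a pair by their average, making their difference exactly
zero — the extreme the electrical-distance detector is built for.

## Kinematics numerics

- The timestamped stream is linearly interpolated onto a uniform grid
  before filtering (the regularization step is unstated in descriptions of
  such pipelines; linear interpolation is the minimal choice at 1094 Hz).
- The Kaiser FIR high-pass (12209 taps, 0.2 Hz cutoff, 0.2 Hz width, 40 dB)
  is applied zero-phase by reflect-padding and centered FFT convolution, so
  peak times are not delayed. The taps are additionally demeaned to give
  *exactly* zero DC gain: the nominal design leaves ~1% at DC, and 1% of
  1 g ramps through a double integrator to meters of spurious displacement,
  swamping the centimeter-scale movement. A symmetric zero-DC FIR
  annihilates constants and linear ramps away from the edges, which is what
  makes the chain stable; the median subtraction after each integration
  then only recenters. (Subtracting the median *before* integration is
  harmful here: the velocity of duty-asymmetric periodic motion has a
  genuinely nonzero median, and removing it injects a DC that integrates
  into a ramp.)
- Bit-flip repair replaces flagged samples by interpolation between the
  nearest unflagged neighbors and iterates detection+repair to a fixpoint,
  making the operation idempotent; runs of adjacent flags are repaired as a
  unit. Same-direction adjacent flips are invisible to the rule (documented
  above) and left untouched.
- PCA sign is pinned by positive correlation with the raw axis of largest
  variance. The recovered polarity relative to the *true* displacement is
  still arbitrary, so maxima of the projection may correspond to
  displacement minima; period statistics are computed for both polarities,
  and truth-comparison tests align polarity explicitly.
- Ties in the compensation-run statistic: a period exactly equal to the
  block median closes the current run and belongs to no run ("above or
  below" excludes equality). If all periods equal the median there are no
  runs and NaN is returned.
- The 100-sample moving-average smoothing before peak detection biases
  detected peak times toward lobe centers and compresses the measured
  period IQR by ~15% relative to ground truth on this waveform family;
  tests budget for this.

## EEG numerics

- **Electrical distance**: variance of the pairwise difference signal,
  median across 2 s windows. Bridged pairs are flagged below 1/16 of the
  across-pairs median distance (relative cutoff ⇒ amplitude-scale
  invariant), at most 10 pairs per recording. Of each pair, the member with
  higher broadband variance relative to its nearest non-bridged neighbors
  is re-estimated.
- **Blink regression**: blink intervals are detected on the EOG by a robust
  amplitude threshold (5 robust SDs, ±150 ms padding); the EOG projection
  is fitted and subtracted on those intervals only. Independent 1/f
  processes have non-negligible finite-sample correlation, so a *global*
  regression would leak background EOG noise into every channel and a
  blink-free recording would not pass through unchanged. The delegated-ICA
  path (MNE, fastica, components selected by |corr| with EOG > 0.5) exists
  for users who prefer it; the regression path keeps the suite free of ICA
  convergence behavior.
- **Spherical splines**: Perrin-style kernels
  `g(x) = Σ (2n+1)/(n(n+1))^m P_n(x) / 4π` (and `h` with exponent m−1) with
  m = 3 and 50 Legendre terms, constrained solve with λ on the diagonal of
  G. The CSD operator agrees with MNE's implementation to machine precision
  up to the 1/r² head-radius scale (unit sphere here), which the test suite
  verifies as an independent cross-check.
- **λ cross-validation** is performed in the voltage domain (the quantity
  observable at a left-out electrode); the winning λ is then used in the
  CSD operator. The four 50 ms windows sit at 45/48/52/55% of the block.
  RMSE ties prefer the larger λ (more smoothing, more conservative). On a
  noiseless smooth field the smallest λ wins; added sensor noise pushes the
  selection monotonically upward — both are asserted over seed ensembles.
- The CV electrode subset follows the explicit centro-parietal label list
  (Fz/F1–F6, FCz/FC1–FC6, Cz/C1–C6, CPz/CP1–CP6, Pz/P1–P6; 35 labels).

## Coherence numerics

- Hann window, constant detrend, 80% overlap, trailing partial segments
  discarded, segments aligned to the block start. Mean aggregation is
  bit-identical to `scipy.signal.coherence` under the same segmentation
  (asserted); the median variant aggregates P_xx, P_yy and the real and
  imaginary parts of P_xy by their medians across segments — a complex
  median is not otherwise defined, and this convention is what makes the
  estimator robust to minority-segment transients. No small-sample median
  bias correction is applied; the median estimate can exceed 1 in rare
  bins and is clipped with a warning.
- Frequency lookup is by exact bin match; 2, 3 and 4 Hz are exact multiples
  of all four resolutions, so no interpolation is ever needed. Zero-power
  bins yield coherence 0 with a warning.
- Clock sync is a two-point linear fit through the first and last TTL
  events (exact for an affine clock model); interior residuals warn above
  1 ms and fail above 5 ms.
- A strong spectral line leaks into bins inside its Hann main lobe. Two
  practical consequences, both visible in tests: at 1 Hz resolution the
  3 Hz baseline is adjacent to the 2 Hz line, capping achievable SNR for
  strong coupling; and the ±0.5 Hz neighbor bins carry some *coherent*
  leakage, so frequency-specificity contrasts are large but neighbor
  coherence is not at the noise floor.

## Group statistics

Test internals are delegated (scipy Shapiro–Wilk, Wilcoxon signed-rank,
paired t, Spearman; statsmodels AnovaRM): the package's contribution is the
construction of their exact inputs. The normality screen at α = 0.05 picks
paired-t vs signed-rank, both statistics are always reported. P-values are
uncorrected by default (a Holm helper exists). Dominant hand is mapped from
the Edinburgh laterality quotient by sign (a quotient slightly below zero
maps to left dominance, covering the ambidextrous case); the conventional
right-handed classification threshold (> 40) is exported separately. Peak
CKC is pooled over blocks by the maximum by default (mean optional); the
table keeps block identity so either pooling can be chosen.

## Problem sizes

The protocol block is 140 s (EEG 2000 Hz, accelerometer 1094 Hz). The
end-to-end recovery tests and the acceptance script run one full-length
block; Monte-Carlo property tests (null coherence, bridge false positives,
lateralization replicates, cohort contrasts) use 10–40 s blocks and 6–15
replicates, sizes chosen so each property is decided by a comfortable margin
at fixed seeds.

## What passing tests do and do not show

The generator reproduces the *structure* the pipeline relies on: focal
phase-locked coupling at F0/F1, 1/f background, blink topographies, bridge
degeneracy, quantization and clock artifacts. It does not emulate real
spatial noise correlations, non-stationarity of cortical rhythms, movement
artifacts in EEG, volume-conduction geometry, or inter-subject anatomical
variability. Passing tests therefore validate the estimators and their
wiring — not claims about effect sizes in real populations, which require
the real recordings.

## Known limitations

- The montage uses idealized template positions on a unit sphere; no
  per-subject digitization is supported.
- ICA blink removal delegates to fastica rather than picard and is not part
  of the tested default path.
- The bit-flip detector inherits the published rule's blindness to flips on
  steep slopes and to same-direction adjacent flips.
- Coherence values from the median estimator are clipped at 1 rather than
  bias-corrected.
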