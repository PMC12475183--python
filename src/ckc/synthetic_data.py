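"""Synthetic coupled EEG + accelerometer recordings with known ground truth.

The generator emulates the physiotherapist-assisted passive-wrist-movement
protocol: a 2 Hz quasi-periodic flexion/extension whose half-cycle durations
jitter around the nominal 250 ms but are steered back toward the metronome
phase (drift-corrected, "compensation within about a cycle" behavior), a focal
cortical source phase-locked to the movement with power at the fundamental
(F0) and its first harmonic (F1) riding on 1/f background EEG, blink
transients mirrored into EOG channels, optional gel-bridged electrode pairs,
and optional 8th-bit flip artifacts in the 16-bit accelerometer stream.

Every downstream stage of the pipeline is testable against the returned
ground truth (true peak times, clean source waveform, spatial weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AccelTrace, Recording, SimulationTruth, G_MS2, STEP_MS2
from .montage import Montage, default_montage


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated movement block.

    Defaults follow the protocol: 2 Hz passive wrist movement in 140 s blocks,
    EEG at 2000 Hz (61 channels, 10-10 cap) and a 16-bit +/-4 g accelerometer
    at 1094 Hz.  ``period_jitter_ms`` is the target interquartile range of the
    peak-to-peak movement periods (the study observed ~20-26 ms);
    ``correction_gain`` is the fraction of accumulated phase error removed per
    half-cycle, which makes drift compensation happen within roughly one cycle.
    """

    movement_rate_hz: float = 2.0
    period_jitter_ms: float = 22.0
    correction_gain: float = 0.8
    flexion_fraction: float = 0.45  # share of the period spent flexing
    amplitude_m: float = 0.025  # half peak-to-peak displacement (~5 cm total)
    harmonic_ratio: float = 0.25  # source amplitude at F1 relative to F0
    source_channel: str = "C3"
    source_snr: float = 0.1  # coupled source power / background power at focus
    source_sigma: float = 0.35  # Gaussian falloff width (unit-sphere chord)
    n_channels: int = 61
    eeg_fs_hz: float = 2000.0
    accel_fs_hz: float = 1094.0
    duration_s: float = 140.0
    background_alpha: float = 1.0  # 1/f^alpha background EEG
    background_rms: float = 1.0
    blink_rate_hz: float = 0.15
    blink_amplitude: float = 8.0  # frontal blink peak, in background-RMS units
    bridged_pairs: tuple[tuple[str, str], ...] = ()
    bitflip_prob: float = 1e-4  # per sample and axis
    gravity_g: float = 1.0
    clock_offset_s: float = 0.0137  # accel device clock minus EEG clock
    clock_drift: float = 2e-5  # relative rate error of the accel clock
    moved_hand: str = "right"
    block_id: str = "1"
    keep_truth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.movement_rate_hz > 0:
            raise ValueError("movement_rate_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not (0.0 <= self.bitflip_prob < 0.01):
            raise ValueError("bitflip_prob must lie in [0, 0.01)")
        if self.period_jitter_ms < 0:
            raise ValueError("period_jitter_ms must be non-negative")
        if not (0.0 < self.correction_gain <= 1.0):
            raise ValueError("correction_gain must lie in (0, 1]")
        if self.moved_hand not in ("left", "right"):
            raise ValueError("moved_hand must be 'left' or 'right'")
        if not (0.0 < self.flexion_fraction < 1.0):
            raise ValueError("flexion_fraction must lie in (0, 1)")
        shortest = min(self.flexion_fraction, 1.0 - self.flexion_fraction) / self.movement_rate_hz
        if self._half_cycle_sigma_s() * 5.0 >= shortest:
            raise ValueError("period_jitter_ms too large: half-cycles could become non-positive")

    def _half_cycle_sigma_s(self) -> float:
        """Half-cycle duration SD that yields the configured period IQR.

        With half-cycle errors e_k ~ N(0, s^2) and phase-correction gain g the
        stationary peak-to-peak period variance is s^2 * F(g) with
        F(g) = (1-g)^2 + 1 + g^2 (2-g)^2 / (1 - (1-g)^2); the IQR of a normal
        variable is 1.349 sd.
        """
        g = self.correction_gain
        a = 1.0 - g
        factor = (a**2 + 1.0) + (g**2 * (2.0 - g) ** 2) / (1.0 - a**2)
        return (self.period_jitter_ms / 1000.0) / 1.349 / np.sqrt(factor)

    def montage(self) -> Montage:
        return default_montage(self.n_channels)


def _half_cycles(config: SimulationConfig, rng: np.random.Generator):
    """Extremum times and half-cycle durations of the drift-corrected movement.

    Returns (times, durations): times[k] is the k-th extremum (k even: maximum),
    durations[k] = times[k+1] - times[k].  Even half-cycles (flexion, peak ->
    trough) take ``flexion_fraction`` of the period, odd ones the remainder:
    passive wrist movement is not time-symmetric, which is what puts odd
    harmonics into the rectified (Euclidean-norm) acceleration.
    """
    period = 1.0 / config.movement_rate_hz
    nominal = (
        config.flexion_fraction * period,
        (1.0 - config.flexion_fraction) * period,
    )
    sigma = config._half_cycle_sigma_s()
    g = config.correction_gain
    n_half = int(np.ceil(2.0 * config.duration_s / period)) + 2
    errs = rng.normal(0.0, sigma, size=n_half) if sigma > 0 else np.zeros(n_half)
    durations = np.empty(n_half)
    phase_err = 0.0  # accumulated lag behind the metronome
    for k in range(n_half):
        d = nominal[k % 2] + errs[k] - g * phase_err
        if d <= 0:
            raise ValueError("drawn half-cycle duration is non-positive")
        durations[k] = d
        phase_err += d - nominal[k % 2]
    times = np.concatenate([[0.0], np.cumsum(durations)])
    return times, durations


def _piecewise_cosine(t: np.ndarray, times: np.ndarray, durations: np.ndarray):
    """Displacement shape (unit amplitude) and phase in cycles at times t.

    Within half-cycle k the displacement is (-1)^k cos(pi tau / d_k) and the
    movement phase advances linearly by half a cycle.
    """
    k = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(durations) - 1)
    tau = t - times[k]
    frac = np.clip(tau / durations[k], 0.0, 1.0)
    sign = np.where(k % 2 == 0, 1.0, -1.0)
    disp = sign * np.cos(np.pi * frac)
    phase = 0.5 * (k + frac)
    curvature = (np.pi / durations[k]) ** 2
    return disp, phase, curvature


def simulate_movement(
    config: SimulationConfig,
) -> tuple[np.ndarray, AccelTrace, np.ndarray]:
    """Simulate the passive wrist movement of one block.

    Returns ``(displacement_1d, accel_trace, true_peak_times)``: displacement
    in meters on the accelerometer sample grid, a raw ``AccelTrace`` in
    resolution steps (gravity offset on the device z axis, optional 8th-bit
    flips, TTL sync events), and the ground-truth times of displacement maxima
    (EEG clock).
    """
    rng = np.random.default_rng(config.seed)
    times, durations = _half_cycles(config, rng)

    n = int(round(config.duration_s * config.accel_fs_hz))
    t = np.arange(n) / config.accel_fs_hz  # true (EEG-clock) sample times
    shape, _, curvature = _piecewise_cosine(t, times, durations)
    displacement = config.amplitude_m * shape
    accel_1d = -curvature * displacement  # second derivative, m/s^2

    # fixed random device orientation: motion along one axis of a random
    # orthonormal frame, gravity as a constant offset on the raw z axis
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    motion_axis = q[:, 0]
    axes_ms2 = np.outer(motion_axis, accel_1d)
    axes_ms2[2] += config.gravity_g * G_MS2
    steps = np.rint(axes_ms2 / STEP_MS2).astype(np.int32)

    n_flips = 0
    if config.bitflip_prob > 0:
        mask = rng.random(steps.shape) < config.bitflip_prob
        n_flips = int(mask.sum())
        steps[mask] ^= 128  # flip the 8th bit

    device_ts = t * (1.0 + config.clock_drift) + config.clock_offset_s
    eeg_events = np.array([1.0, config.duration_s - 1.0])
    sync_events = eeg_events * (1.0 + config.clock_drift) + config.clock_offset_s

    trace = AccelTrace(
        samples=steps,
        timestamps=device_ts,
        fs_hz=config.accel_fs_hz,
        range_g=4.0,
        units="steps",
        sync_events=sync_events,
    )
    peak_times = times[: -1 : 2]  # even extrema are maxima
    peak_times = peak_times[peak_times < config.duration_s]
    # stash for simulate_recording so both streams share one movement draw
    trace._sim_state = (times, durations, motion_axis, displacement, n_flips)  # type: ignore[attr-defined]
    return displacement, trace, peak_times


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float,
    alpha: float, rms: float,
) -> np.ndarray:
    """Independent 1/f^alpha noise per channel, normalized to target RMS."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    for ch in range(n_channels):
        spec = gain * (
            rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
        )
        x = np.fft.irfft(spec, n=n_samples)
        x *= rms / np.sqrt(np.mean(x**2))
        out[ch] = x
    return out


def _blink_template(fs: float, width_s: float = 0.35) -> np.ndarray:
    n = int(round(width_s * fs))
    return np.hanning(n) ** 2


def simulate_recording(config: SimulationConfig) -> Recording:
    """Simulate one synchronized EEG + EOG + accelerometer block.

    EEG = per-channel 1/f background + movement-locked source (components at
    F0 and F1, Gaussian spatial falloff around ``source_channel``) + frontal
    blink transients mirrored into the EOG channels.  Channels listed in
    ``bridged_pairs`` are replaced by their pairwise average (a gel bridge
    shorts the electrodes).  Identical config + seed gives bit-identical output.
    """
    montage = config.montage()
    if config.source_channel not in montage:
        raise KeyError(f"source_channel {config.source_channel!r} not in montage")
    for a, b in config.bridged_pairs:
        if a not in montage or b not in montage:
            raise KeyError(f"bridged pair ({a!r}, {b!r}) not in montage")

    displacement, trace, peak_times = simulate_movement(config)
    times, durations, motion_axis, _, n_flips = trace._sim_state  # type: ignore[attr-defined]
    del trace._sim_state  # type: ignore[attr-defined]

    rng = np.random.default_rng(config.seed + 1_000_003)
    n = int(round(config.duration_s * config.eeg_fs_hz))
    t = np.arange(n) / config.eeg_fs_hz

    eeg = _one_over_f_noise(
        rng, len(montage.labels), n, config.eeg_fs_hz,
        config.background_alpha, config.background_rms,
    )
    eog_labels = ("VEOG", "HEOG")
    eog = _one_over_f_noise(
        rng, 2, n, config.eeg_fs_hz, config.background_alpha, config.background_rms
    )

    # movement-locked cortical source
    _, phase, _ = _piecewise_cosine(t, times, durations)
    source = np.cos(2.0 * np.pi * phase) + config.harmonic_ratio * np.cos(
        4.0 * np.pi * phase
    )
    var_s = 0.5 * (1.0 + config.harmonic_ratio**2)
    scale = np.sqrt(config.source_snr / var_s) * config.background_rms
    src_pos = montage.position(config.source_channel)
    dist2 = ((montage.positions - src_pos) ** 2).sum(axis=1)
    weights = np.exp(-dist2 / (2.0 * config.source_sigma**2))
    source_scaled = (scale * source).astype(np.float32)
    eeg += np.outer(weights, source_scaled).astype(np.float32)

    eeg_pre_blink = eeg.copy() if config.keep_truth and config.blink_rate_hz > 0 else None

    # blink transients: frontal topography, mirrored (larger) into EOG
    if config.blink_rate_hz > 0:
        template = _blink_template(config.eeg_fs_hz)
        n_blinks = rng.poisson(config.blink_rate_hz * config.duration_s)
        onsets = np.sort(rng.uniform(0, n - template.size, size=n_blinks).astype(int))
        blink_sig = np.zeros(n, dtype=np.float32)
        for onset in onsets:
            amp = config.blink_amplitude * rng.uniform(0.8, 1.2)
            blink_sig[onset : onset + template.size] += (amp * template).astype(
                np.float32
            )
        fp_pos = montage.position("Fpz") if "Fpz" in montage else montage.positions[0]
        fdist2 = ((montage.positions - fp_pos) ** 2).sum(axis=1)
        fweights = np.exp(-fdist2 / (2.0 * 0.4**2))
        eeg += np.outer(fweights, blink_sig).astype(np.float32)
        eog[0] += 1.5 * blink_sig
        eog[1] += 0.3 * blink_sig

    for a, b in config.bridged_pairs:
        ia, ib = montage.index(a), montage.index(b)
        avg = 0.5 * (eeg[ia] + eeg[ib])
        eeg[ia] = avg
        eeg[ib] = avg

    truth = None
    if config.keep_truth:
        truth = SimulationTruth(
            peak_times=peak_times,
            trough_times=times[1:-1:2][times[1:-1:2] < config.duration_s],
            displacement=displacement,
            motion_axis=motion_axis,
            source_waveform=source_scaled,
            source_weights=weights,
            eeg_pre_blink=eeg_pre_blink,
            clock_offset_s=config.clock_offset_s,
            clock_drift=config.clock_drift,
            n_bit_flips=n_flips,
        )

    return Recording(
        eeg=eeg,
        labels=montage.labels,
        fs_hz=config.eeg_fs_hz,
        montage=montage,
        eog=eog,
        eog_labels=eog_labels,
        accel=trace,
        events=np.array([1.0, config.duration_s - 1.0]),
        annotations={"hand": config.moved_hand, "block": config.block_id},
        truth=truth,
        provenance=[f"simulate_recording(seed={config.seed})"],
    )
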