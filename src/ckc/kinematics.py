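"""Accelerometer kinematics: artifact repair, double integration, and
movement-regularity statistics.

The chain mirrors how the passive-movement blocks are summarized: repair
single-sample 8th-bit flips in the raw 16-bit stream, estimate displacement by
filtered double integration (Kaiser-windowed FIR high-pass, cumulative
integration, median-drift subtraction — applied twice), reduce the three axes
to the main movement axis by PCA, detect displacement maxima/minima on a
smoothed copy, and characterize the peak-to-peak periods by their median and
interquartile range plus the median number of cycles the movement spends on
one side of the median period before drifting back ("cycles before
compensation").
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from .containers import AccelTrace, KinematicsSummary

#: Detection threshold for bit-flip excursions, in resolution steps.
BITFLIP_THRESHOLD = 127

#: High-pass FIR design used before each integration step.
FIR_NUMTAPS = 12209
FIR_CUTOFF_HZ = 0.2
FIR_ATTENUATION_DB = 40.0

#: Peak-detection parameters (samples at the accelerometer rate).
SMOOTH_SAMPLES = 100
PEAK_MIN_DISTANCE = 300
PEAK_MIN_PROMINENCE_FRAC = 0.01


def _flip_mask(x: np.ndarray) -> np.ndarray:
    """Single-sample excursions: consecutive first differences exceeding the
    threshold in opposite directions."""
    d = np.diff(x.astype(np.int64))
    up_down = (d[:-1] > BITFLIP_THRESHOLD) & (d[1:] < -BITFLIP_THRESHOLD)
    down_up = (d[:-1] < -BITFLIP_THRESHOLD) & (d[1:] > BITFLIP_THRESHOLD)
    mask = np.zeros(x.shape, dtype=bool)
    mask[1:-1] = up_down | down_up
    return mask


def _repair_pass(x: np.ndarray) -> int:
    """One detection + repair pass in place; returns number of replacements.

    Flagged samples (including runs of adjacent flags) are replaced by linear
    interpolation between the nearest unflagged neighbors.
    """
    mask = _flip_mask(x)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0
    good = np.flatnonzero(~mask)
    interp = np.interp(idx, good, x[good].astype(float))
    repl = np.rint(interp).astype(x.dtype)
    moved = repl != x[idx]
    x[idx[moved]] = repl[moved]
    return int(moved.sum())


def correct_bit_flips(
    trace: AccelTrace, max_passes: int = 64
) -> tuple[AccelTrace, int]:
    """Repair single-sample 8th-bit flip excursions in a raw trace.

    Flagged samples are replaced by interpolation between the nearest
    unflagged neighbors (for an isolated flip: the mean of its two
    neighbors).  Detection and repair iterate until no flags remain, so
    applying the operation twice changes nothing.  Runs of adjacent flipped
    samples are only partially visible to the single-sample rule
    (same-direction adjacent flips produce no opposite-direction difference
    pair and pass through undetected); the returned count reports every
    replacement made.

    Returns ``(repaired_trace, n_corrections)``.  A no-flip input passes
    through unchanged with a count of 0.
    """
    if trace.units != "steps":
        raise ValueError("bit-flip repair operates on raw resolution steps")
    samples = trace.samples.copy()
    total = 0
    for axis in range(3):
        x = samples[axis]
        for _ in range(max_passes):
            n = _repair_pass(x)
            if n == 0:
                break
            total += n
        else:
            warnings.warn("bit-flip repair did not converge; residual flags remain")
    out = trace.copy()
    out.samples = samples
    return out, total


def _highpass_taps(fs_hz: float) -> np.ndarray:
    """Kaiser-windowed high-pass FIR, normalized to exactly zero DC gain.

    The nominal design leaves ~1% (-40 dB) gain at DC; against a 1 g gravity
    offset that residual would ramp through the double integrator and swamp
    the centimeter-scale movement, so the taps are demeaned.  A symmetric FIR
    with exactly zero DC gain annihilates constants and linear ramps away
    from the edges, which is what makes the integration chain stable.
    """
    beta = signal.kaiser_beta(FIR_ATTENUATION_DB)
    taps = signal.firwin(
        FIR_NUMTAPS,
        FIR_CUTOFF_HZ,
        window=("kaiser", beta),
        pass_zero=False,
        fs=fs_hz,
    )
    return taps - taps.mean()


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric (linear-phase) FIR with zero net delay.

    Reflect-padding by half the filter length and a 'valid' FFT convolution
    keeps the output aligned with the input so that peak times feed period
    statistics and EEG alignment without group-delay compensation.
    """
    half = len(taps) // 2
    padded = np.pad(x, half, mode="reflect")
    return signal.fftconvolve(padded, taps, mode="valid")


def _resample_uniform(trace: AccelTrace) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of the timestamped stream onto a uniform grid."""
    ts = trace.timestamps
    n = trace.n_samples
    grid = ts[0] + np.arange(n) * (ts[-1] - ts[0]) / (n - 1)
    data = trace.in_ms2()
    out = np.vstack([np.interp(grid, ts, data[axis]) for axis in range(3)])
    return out, grid


def estimate_displacement(trace: AccelTrace) -> tuple[np.ndarray, np.ndarray]:
    """Displacement per axis by filtered double integration.

    Per axis and per integration step: high-pass filter, cumulative
    (trapezoidal) integration, then subtraction of the median signal to
    compensate for drift accumulated during the integration.  Applied twice;
    the trace is first resampled to a uniform grid on its own timestamps.
    Returns ``(displacement_3axis, times)`` with displacement in meters.
    """
    if trace.n_samples <= FIR_NUMTAPS:
        raise ValueError("trace shorter than the high-pass filter")
    data, grid = _resample_uniform(trace)
    fs = 1.0 / np.mean(np.diff(grid))
    taps = _highpass_taps(fs)
    out = np.empty_like(data)
    for axis in range(3):
        x = data[axis]
        for _ in range(2):
            x = _zero_phase_fir(x, taps)
            x = np.concatenate(
                [[0.0], np.cumsum(0.5 * (x[1:] + x[:-1]))]
            ) / fs
            x = x - np.median(x)
        out[axis] = x
    return out, grid


def main_axis(
    signal_3axis: np.ndarray, return_axis: bool = False
):
    """Project a 3-axis signal onto its first principal axis.

    The sign is pinned so the projection correlates positively with the raw
    axis of largest variance (PCA signs are otherwise arbitrary).
    """
    data = np.asarray(signal_3axis, dtype=float)
    if data.ndim != 2 or data.shape[0] != 3:
        raise ValueError("signal must have shape (3, N)")
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    variances = data.var(axis=1)
    if np.max(variances) == 0:
        raise ValueError("zero-variance input has no principal axis")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(data.T)[:, 0]
    axis = pca.components_[0].copy()
    ref = data[int(np.argmax(variances))]
    if np.dot(scores - scores.mean(), ref - ref.mean()) < 0:
        scores, axis = -scores, -axis
    if return_axis:
        return scores, axis, float(pca.explained_variance_ratio_[0])
    return scores


def detect_movement_peaks(
    signal_1d: np.ndarray, fs_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Detect displacement maxima and minima.

    The signal is smoothed with a 100-sample moving average; peaks (and peaks
    of the negated signal, for minima) must be at least 300 samples apart with
    prominence of at least 1% of the smoothed signal range.  Returned indices
    refer to the unsmoothed timeline.
    """
    x = np.asarray(signal_1d, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has no peaks")
    kernel = np.ones(SMOOTH_SAMPLES)
    # edge-normalized moving average (plain 'same' convolution dips at edges)
    smoothed = np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same"
    )
    rng = np.ptp(smoothed)
    prominence = PEAK_MIN_PROMINENCE_FRAC * rng
    max_peaks, _ = signal.find_peaks(
        smoothed, distance=PEAK_MIN_DISTANCE, prominence=prominence
    )
    min_peaks, _ = signal.find_peaks(
        -smoothed, distance=PEAK_MIN_DISTANCE, prominence=prominence
    )
    return max_peaks, min_peaks


def period_stats(peaks: np.ndarray, fs_hz: float) -> tuple[float, float]:
    """Median and interquartile range of peak-to-peak intervals, in ms."""
    peaks = np.asarray(peaks)
    if peaks.size < 3:
        raise ValueError("need at least 3 peaks for period statistics")
    periods_ms = np.diff(peaks) / fs_hz * 1000.0
    q25, q75 = np.percentile(periods_ms, [25, 75])
    return float(np.median(periods_ms)), float(q75 - q25)


def cycles_before_compensation(periods_ms: np.ndarray) -> float:
    """Median length of runs of periods strictly above or below the median.

    A period exactly equal to the block median terminates the current run and
    belongs to no run ("above or below" excludes equality).  If every period
    equals the median there are no runs and NaN is returned (degenerate
    input, e.g. a perfectly periodic synthetic block).
    """
    periods = np.asarray(periods_ms, dtype=float)
    if periods.size < 3:
        raise ValueError("need at least 3 periods")
    med = np.median(periods)
    signs = np.sign(periods - med)
    run_lengths: list[int] = []
    current_sign = 0.0
    current_len = 0
    for s in signs:
        if s == 0:
            if current_len:
                run_lengths.append(current_len)
            current_sign, current_len = 0.0, 0
        elif s == current_sign:
            current_len += 1
        else:
            if current_len:
                run_lengths.append(current_len)
            current_sign, current_len = s, 1
    if current_len:
        run_lengths.append(current_len)
    if not run_lengths:
        return float("nan")
    return float(np.median(run_lengths))


def summarize_block(
    trace: AccelTrace, block_id: str = "1", hand: str = "right"
) -> KinematicsSummary:
    """Run the full kinematics chain on one block and summarize it.

    Movement periods are estimated from maximum as well as minimum peaks so
    that lateral asymmetries of the movement do not bias comparisons; the
    compensation statistic uses the maximum-peak periods.
    """
    repaired, _ = correct_bit_flips(trace) if trace.units == "steps" else (trace, 0)
    disp, grid = estimate_displacement(repaired)
    fs = 1.0 / np.mean(np.diff(grid))
    main = main_axis(disp)
    max_peaks, min_peaks = detect_movement_peaks(main, fs)
    med_max, iqr_max = period_stats(max_peaks, fs)
    med_min, iqr_min = period_stats(min_peaks, fs)
    periods_ms = np.diff(max_peaks) / fs * 1000.0
    comp = cycles_before_compensation(periods_ms)
    return KinematicsSummary(
        block_id=block_id,
        hand=hand,
        median_period_ms_max=med_max,
        iqr_period_ms_max=iqr_max,
        median_period_ms_min=med_min,
        iqr_period_ms_min=iqr_min,
        median_cycles_before_compensation=comp,
        n_peaks=int(max_peaks.size),
    )
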