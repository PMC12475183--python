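"""Corticokinematic coherence between CSD-transformed EEG and acceleration.

Coherence is Welch magnitude-squared coherence,

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f)),

estimated from Hann-windowed, constant-detrended segments at 80% overlap.
Besides the standard mean across segment periodograms, a median-across-
segments variant is provided to blunt the influence of transient artifacts on
the spectral density estimates: the median is taken over P_xx, P_yy and over
the real and imaginary parts of P_xy separately (a complex median is not
otherwise defined).  Segment lengths of 1/2/4/8 s give frequency resolutions
of 1/0.5/0.25/0.125 Hz, so the 2 Hz fundamental (F0), 3 Hz baseline and 4 Hz
first harmonic (F1) fall on exact bins at every resolution.

Acceleration is synchronized to the EEG clock through the shared TTL events,
low-pass filtered at 50 Hz, up-sampled to 2000 Hz, and summarized either as
the Euclidean norm of the median-subtracted axes ("magnitude", removing
gravity) or as the first principal component of the three axes ("pca").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import AccelTrace, CKCMetrics, CoherenceSpectrum, Recording
from .kinematics import main_axis
from .montage import Montage

F0_HZ = 2.0
F1_HZ = 4.0
BASELINE_HZ = 3.0

SEGMENT_LENGTHS_S = (1.0, 2.0, 4.0, 8.0)
ACCEL_METHODS = ("magnitude", "pca")
AVERAGINGS = ("mean", "median")

#: Clock-sync residual thresholds (two-point linear fit on TTL events).
SYNC_WARN_S = 1e-3
SYNC_ERROR_S = 5e-3


@dataclass
class AccelSummary:
    """1-d acceleration summary on the EEG timebase."""

    signal_1d: np.ndarray
    method: str
    fs_hz: float
    provenance: list[str]


def sync_clock_map(accel_events: np.ndarray, eeg_events: np.ndarray):
    """Linear device-clock -> EEG-clock mapping from shared TTL events.

    Fits a two-point line through the first and last event pair; with more
    than two events the interior residuals are checked (warn above 1 ms,
    error above 5 ms).
    """
    accel_events = np.asarray(accel_events, dtype=float)
    eeg_events = np.asarray(eeg_events, dtype=float)
    if accel_events.size < 2 or accel_events.size != eeg_events.size:
        raise ValueError("need the same >= 2 sync events in both streams")
    slope = (eeg_events[-1] - eeg_events[0]) / (accel_events[-1] - accel_events[0])
    offset = eeg_events[0] - slope * accel_events[0]
    if accel_events.size > 2:
        resid = np.abs(slope * accel_events[1:-1] + offset - eeg_events[1:-1])
        worst = float(resid.max())
        if worst > SYNC_ERROR_S:
            raise ValueError(f"sync residual {worst * 1e3:.2f} ms exceeds tolerance")
        if worst > SYNC_WARN_S:
            warnings.warn(f"sync residual {worst * 1e3:.2f} ms above 1 ms")
    return lambda t: slope * np.asarray(t, dtype=float) + offset


def prepare_accel(
    trace: AccelTrace,
    eeg_events: np.ndarray,
    n_samples: int,
    target_fs: float = 2000.0,
    method: str = "magnitude",
    lowpass_hz: float = 50.0,
) -> AccelSummary:
    """Synchronize, low-pass, up-sample and summarize a 3-axis trace.

    ``eeg_events`` are the TTL times on the EEG clock matching
    ``trace.sync_events``; the output covers ``n_samples`` samples at
    ``target_fs`` starting at EEG time zero.
    """
    if method not in ACCEL_METHODS:
        raise ValueError("method must be 'magnitude' or 'pca'")
    to_eeg = sync_clock_map(trace.sync_events, eeg_events)
    times = to_eeg(trace.timestamps)
    data = trace.in_ms2()
    sos = signal.butter(4, lowpass_hz, btype="low", fs=trace.fs_hz, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    grid = np.arange(n_samples) / target_fs
    resampled = np.vstack([np.interp(grid, times, data[a]) for a in range(3)])
    if method == "magnitude":
        med = np.median(resampled, axis=1, keepdims=True)
        out = np.linalg.norm(resampled - med, axis=0)
    else:
        out = main_axis(resampled)
    return AccelSummary(
        signal_1d=out,
        method=method,
        fs_hz=target_fs,
        provenance=[f"prepare_accel(method={method}, lowpass={lowpass_hz})"],
    )


def _segment_spectra(
    x: np.ndarray, nperseg: int, step: int, window: np.ndarray, n_keep: int
) -> np.ndarray:
    """Windowed rFFT of constant-detrended overlapping segments: (K, n_keep)."""
    n = x.shape[-1]
    n_seg = 1 + (n - nperseg) // step
    segs = np.lib.stride_tricks.sliding_window_view(x, nperseg)[::step][:n_seg]
    segs = segs - segs.mean(axis=-1, keepdims=True)
    return np.fft.rfft(segs * window, axis=-1)[:, :n_keep]


def _coherence_from_spectra(
    X: np.ndarray, Y: np.ndarray, averaging: str
) -> np.ndarray:
    """Magnitude-squared coherence from per-segment spectra (K, F)."""
    pxx = np.abs(X) ** 2
    pyy = np.abs(Y) ** 2
    pxy = X * np.conj(Y)
    if averaging == "mean":
        pxx_a = pxx.mean(axis=0)
        pyy_a = pyy.mean(axis=0)
        pxy_a = pxy.mean(axis=0)
    elif averaging == "median":
        pxx_a = np.median(pxx, axis=0)
        pyy_a = np.median(pyy, axis=0)
        pxy_a = np.median(pxy.real, axis=0) + 1j * np.median(pxy.imag, axis=0)
    else:
        raise ValueError("averaging must be 'mean' or 'median'")
    denom = pxx_a * pyy_a
    coh = np.zeros_like(denom)
    good = denom > 0
    coh[good] = np.abs(pxy_a[good]) ** 2 / denom[good]
    if not np.all(good):
        warnings.warn("zero-power frequency bins: coherence reported as 0")
    n_over = int(np.sum(coh > 1.0))
    if n_over and averaging == "median":
        warnings.warn(f"median-averaged coherence clipped at 1 in {n_over} bins")
    return np.clip(coh, 0.0, 1.0)


def _welch_plan(n: int, fs: float, segment_s: float, overlap: float, fmax):
    nperseg = int(round(segment_s * fs))
    noverlap = int(round(overlap * nperseg))
    step = nperseg - noverlap
    if n < nperseg + step:
        raise ValueError("need at least 2 segments")
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    n_keep = freqs.size if fmax is None else int(np.searchsorted(freqs, fmax, "right"))
    window = signal.get_window("hann", nperseg)
    return nperseg, step, window, freqs[:n_keep], n_keep


def welch_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    segment_s: float,
    overlap: float = 0.8,
    averaging: str = "mean",
    fmax: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch magnitude-squared coherence of two 1-d signals.

    With ``averaging="mean"`` this matches the conventional Welch estimate
    (identical to ``scipy.signal.coherence`` with the same segmentation); with
    ``averaging="median"`` the segment periodograms are aggregated by medians.
    Values are clipped to [0, 1]; zero-power bins are reported as 0 with a
    warning.  Returns ``(freqs_hz, coherence)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signals must be 1-d and the same length")
    nperseg, step, window, freqs, n_keep = _welch_plan(
        x.size, fs, segment_s, overlap, fmax
    )
    X = _segment_spectra(x, nperseg, step, window, n_keep)
    Y = _segment_spectra(y, nperseg, step, window, n_keep)
    return freqs, _coherence_from_spectra(X, Y, averaging)


def channel_coherence(
    rec: Recording,
    accel: AccelSummary,
    segment_s: float,
    overlap: float = 0.8,
    averaging: str = "mean",
    fmax: float = 50.0,
) -> CoherenceSpectrum:
    """Coherence of every EEG channel with the acceleration summary."""
    y = np.asarray(accel.signal_1d, dtype=float)
    if y.size != rec.n_samples:
        raise ValueError("acceleration summary must share the EEG timebase")
    nperseg, step, window, freqs, n_keep = _welch_plan(
        rec.n_samples, rec.fs_hz, segment_s, overlap, fmax
    )
    Y = _segment_spectra(y, nperseg, step, window, n_keep)
    values = np.empty((rec.n_channels, n_keep))
    for ch in range(rec.n_channels):
        X = _segment_spectra(
            np.asarray(rec.eeg[ch], dtype=float), nperseg, step, window, n_keep
        )
        values[ch] = _coherence_from_spectra(X, Y, averaging)
    return CoherenceSpectrum(
        values=values,
        freqs_hz=freqs,
        channels=rec.labels,
        resolution_hz=1.0 / segment_s,
        segment_s=segment_s,
        overlap=overlap,
        averaging=averaging,
        accel_method=accel.method,
    )


def ckc_grid(
    csd_rec: Recording,
    accel_trace: AccelTrace,
    segments_s=SEGMENT_LENGTHS_S,
    methods=ACCEL_METHODS,
    averagings=AVERAGINGS,
    overlap: float = 0.8,
    fmax: float = 50.0,
) -> list[CoherenceSpectrum]:
    """The full method x resolution grid of coherence spectra for one block.

    Default grid: (magnitude | pca) x (mean | median) x (1 | 2 | 4 | 8) s
    segments = 16 spectra.  Deterministic given the inputs.
    """
    summaries = {
        m: prepare_accel(
            accel_trace, csd_rec.events, csd_rec.n_samples, csd_rec.fs_hz, method=m
        )
        for m in methods
    }
    return [
        channel_coherence(
            csd_rec, summaries[m], seg, overlap=overlap, averaging=avg, fmax=fmax
        )
        for m, avg, seg in itertools.product(methods, averagings, segments_s)
    ]


def snr_db(
    spectrum: CoherenceSpectrum, f_target: float, f_baseline: float = BASELINE_HZ
) -> np.ndarray:
    """Per-channel SNR: 20 log10(C(f_target) / C(f_baseline)) in dB.

    The baseline bin sits exactly at 3 Hz, which is present at every tested
    resolution.  Channels with zero baseline coherence get +/-inf with a
    warning.
    """
    target = spectrum.at(f_target)
    base = spectrum.at(f_baseline)
    if np.any(base == 0):
        warnings.warn("zero baseline coherence: SNR is infinite for some channels")
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(target / base)


def _subset_indices(spectrum: CoherenceSpectrum, labels) -> list[int]:
    missing = [l for l in labels if l not in spectrum.channels]
    if missing:
        raise KeyError(f"subset channels missing from spectrum: {missing}")
    return [spectrum.channels.index(l) for l in labels]


def peak_metrics(
    spectrum: CoherenceSpectrum,
    montage: Montage,
    hand: str,
    block: str = "1",
    f0: float = F0_HZ,
    f1: float = F1_HZ,
) -> CKCMetrics:
    """Peak, SNR and lateralization metrics for one coherence spectrum.

    The peak channel is the argmax of coherence over the analysis subset at F0
    and F1 independently; SNR (vs 3 Hz) is reported at the respective peak
    channel.  ``contra``/``ipsi`` follow the moved hand: for a left-hand block
    the contralateral set is the right 12-channel set and vice versa.
    """
    if hand not in ("left", "right"):
        raise ValueError("hand must be 'left' or 'right'")
    analysis = montage.subsets["analysis"]
    left_set = montage.subsets["left"]
    right_set = montage.subsets["right"]
    idx = _subset_indices(spectrum, analysis)
    snrs = {f: snr_db(spectrum, f) for f in (f0, f1)}
    peaks = {}
    for f in (f0, f1):
        vals = spectrum.at(f)[idx]
        k = int(np.argmax(vals))
        peaks[f] = (float(vals[k]), analysis[k])
    li = _subset_indices(spectrum, left_set)
    ri = _subset_indices(spectrum, right_set)
    means = {
        (f, side): float(spectrum.at(f)[ix].mean())
        for f in (f0, f1)
        for side, ix in (("left", li), ("right", ri))
    }
    contra_side = "right" if hand == "left" else "left"
    ipsi_side = "left" if hand == "left" else "right"
    return CKCMetrics(
        hand=hand,
        block=block,
        accel_method=spectrum.accel_method,
        averaging=spectrum.averaging,
        resolution_hz=spectrum.resolution_hz,
        f0_hz=f0,
        f1_hz=f1,
        peak_f0=peaks[f0][0],
        peak_channel_f0=peaks[f0][1],
        peak_f1=peaks[f1][0],
        peak_channel_f1=peaks[f1][1],
        snr_f0_db=float(snrs[f0][spectrum.channels.index(peaks[f0][1])]),
        snr_f1_db=float(snrs[f1][spectrum.channels.index(peaks[f1][1])]),
        mean_left_f0=means[(f0, "left")],
        mean_right_f0=means[(f0, "right")],
        mean_left_f1=means[(f1, "left")],
        mean_right_f1=means[(f1, "right")],
        contra_f0=means[(f0, contra_side)],
        ipsi_f0=means[(f0, ipsi_side)],
        contra_f1=means[(f1, contra_side)],
        ipsi_f1=means[(f1, ipsi_side)],
    )
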