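"""Shared data containers for the coherence pipeline.

Conventions: 0-based sample indexing, half-open intervals, all times in
seconds internally; milliseconds appear only at reporting boundaries.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .montage import Montage

#: LSB of a 16-bit accelerometer spanning +/-4 g, in m/s^2 per resolution step.
G_MS2 = 9.80665
STEP_MS2 = 8.0 * G_MS2 / 65536.0
STEP_G = 8.0 / 65536.0


@dataclass
class AccelTrace:
    """Timestamped 3-axis accelerometer block.

    ``samples`` is (3, N).  ``units`` is ``"steps"`` (raw resolution steps of
    the 16-bit +/-4 g converter) or ``"m/s2"``.  ``timestamps`` are device-clock
    seconds per sample; ``sync_events`` are TTL event times on the same clock,
    shared with the EEG stream for off-line alignment.
    """

    samples: np.ndarray
    timestamps: np.ndarray
    fs_hz: float = 1094.0
    range_g: float = 4.0
    units: str = "steps"
    sync_events: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.sync_events = np.asarray(self.sync_events, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise ValueError("samples must have shape (3, N)")
        if self.samples.shape[1] != self.timestamps.size:
            raise ValueError("timestamps length must match samples")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.units not in ("steps", "m/s2"):
            raise ValueError("units must be 'steps' or 'm/s2'")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def in_ms2(self) -> np.ndarray:
        """Samples converted to m/s^2 (identity if already physical units)."""
        if self.units == "m/s2":
            return np.asarray(self.samples, dtype=float)
        return np.asarray(self.samples, dtype=float) * STEP_MS2

    def copy(self) -> "AccelTrace":
        return replace(
            self,
            samples=self.samples.copy(),
            timestamps=self.timestamps.copy(),
            sync_events=self.sync_events.copy(),
        )


@dataclass
class SimulationTruth:
    """Ground truth kept by the simulator for oracle tests."""

    peak_times: np.ndarray  # EEG-clock times of displacement maxima
    trough_times: np.ndarray
    displacement: np.ndarray  # 1-d displacement on the accelerometer grid, m
    motion_axis: np.ndarray  # unit vector of motion in the device frame
    source_waveform: Optional[np.ndarray] = None  # (N_eeg,), source units
    source_weights: Optional[np.ndarray] = None  # per-channel spatial gain
    eeg_pre_blink: Optional[np.ndarray] = None  # EEG before blink injection
    clock_offset_s: float = 0.0
    clock_drift: float = 0.0
    n_bit_flips: int = 0


@dataclass
class Recording:
    """Synchronized multi-channel EEG + EOG + 3-axis acceleration."""

    eeg: np.ndarray  # (n_channels, N)
    labels: tuple[str, ...]
    fs_hz: float
    montage: Montage
    eog: np.ndarray  # (n_eog, N)
    eog_labels: tuple[str, ...]
    accel: Optional[AccelTrace] = None
    events: np.ndarray = field(default_factory=lambda: np.empty(0))  # EEG clock
    annotations: dict = field(default_factory=dict)  # e.g. hand / block labels
    reference: str = "nose"
    truth: Optional[SimulationTruth] = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg)
        self.eog = np.asarray(self.eog)
        self.events = np.asarray(self.events, dtype=float)
        if self.eeg.shape[0] != len(self.labels):
            raise ValueError("eeg row count must match labels")
        if tuple(self.labels) != tuple(self.montage.labels):
            raise ValueError("labels must match montage labels")
        if self.eog.size and self.eog.shape[1] != self.eeg.shape[1]:
            raise ValueError("eog length must match eeg")

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        return self.eeg[self.montage.index(label)]

    def copy(self, deep_eeg: bool = True) -> "Recording":
        return replace(
            self,
            eeg=self.eeg.copy() if deep_eeg else self.eeg,
            eog=self.eog.copy(),
            events=self.events.copy(),
            annotations=dict(self.annotations),
            provenance=list(self.provenance),
        )

    def with_eeg(self, eeg: np.ndarray, note: str) -> "Recording":
        """New Recording with replaced EEG data and a provenance note."""
        rec = copy.copy(self)
        rec.eeg = eeg
        rec.provenance = self.provenance + [note]
        return rec


@dataclass
class KinematicsSummary:
    """Per-block movement-regularity statistics (per peak polarity)."""

    block_id: str
    hand: str
    median_period_ms_max: float
    iqr_period_ms_max: float
    median_period_ms_min: float
    iqr_period_ms_min: float
    median_cycles_before_compensation: float
    n_peaks: int

    def __post_init__(self) -> None:
        for v in (self.median_period_ms_max, self.median_period_ms_min):
            if not v > 0:
                raise ValueError("median period must be positive")
        for v in (self.iqr_period_ms_max, self.iqr_period_ms_min):
            if v < 0:
                raise ValueError("IQR must be non-negative")


@dataclass
class CoherenceSpectrum:
    """Channels x frequencies coherence with its estimation metadata."""

    values: np.ndarray  # (n_channels, n_freqs), in [0, 1]
    freqs_hz: np.ndarray
    channels: tuple[str, ...]
    resolution_hz: float
    segment_s: float
    overlap: float
    averaging: str  # "mean" | "median"
    accel_method: str  # "magnitude" | "pca"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.values.shape != (len(self.channels), self.freqs_hz.size):
            raise ValueError("values shape must be (n_channels, n_freqs)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("coherence values must lie in [0, 1]")
        if self.averaging not in ("mean", "median"):
            raise ValueError("averaging must be 'mean' or 'median'")
        if self.accel_method not in ("magnitude", "pca"):
            raise ValueError("accel_method must be 'magnitude' or 'pca'")
        if self.freqs_hz.size > 1:
            df = np.diff(self.freqs_hz)
            if not np.allclose(df, self.resolution_hz, rtol=1e-9, atol=1e-12):
                raise ValueError("frequency spacing must equal resolution_hz")
        if not np.isclose(self.segment_s * self.resolution_hz, 1.0):
            raise ValueError("segment_s * resolution_hz must equal 1")

    def bin_index(self, f_hz: float) -> int:
        idx = np.flatnonzero(np.isclose(self.freqs_hz, f_hz, rtol=0, atol=1e-9))
        if idx.size != 1:
            raise ValueError(f"{f_hz} Hz is not on the frequency grid")
        return int(idx[0])

    def at(self, f_hz: float) -> np.ndarray:
        """Per-channel coherence at an exact grid frequency."""
        return self.values[:, self.bin_index(f_hz)]


@dataclass
class CKCMetrics:
    """Peak / lateralization / SNR summary of one coherence spectrum."""

    hand: str
    block: str
    accel_method: str
    averaging: str
    resolution_hz: float
    f0_hz: float
    f1_hz: float
    peak_f0: float
    peak_channel_f0: str
    peak_f1: float
    peak_channel_f1: str
    snr_f0_db: float
    snr_f1_db: float
    mean_left_f0: float
    mean_right_f0: float
    mean_left_f1: float
    mean_right_f1: float
    contra_f0: float
    ipsi_f0: float
    contra_f1: float
    ipsi_f1: float


@dataclass
class CsdParams:
    """Spherical-spline surface-Laplacian parameters.

    ``lambda_grid`` is the candidate regularization grid searched by
    leave-one-out cross-validation; ``stiffness_m`` and ``n_legendre_terms``
    parameterize the Legendre expansion of the spline kernels.
    """

    lambda_grid: tuple[float, ...] = (1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
    stiffness_m: int = 3
    n_legendre_terms: int = 50
    cv_window_s: float = 0.050
    cv_window_centers: tuple[float, ...] = (0.45, 0.48, 0.52, 0.55)  # block fractions
    selected_lambda: Optional[float] = None
    rmse_per_lambda: Optional[dict[float, float]] = None

    def __post_init__(self) -> None:
        if self.selected_lambda is not None and self.selected_lambda not in self.lambda_grid:
            raise ValueError("selected_lambda must come from lambda_grid")
        if self.rmse_per_lambda is not None:
            vals = np.array(list(self.rmse_per_lambda.values()))
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError("RMSE values must be finite and non-negative")
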