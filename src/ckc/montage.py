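"""Idealized 10-10 electrode geometry on the unit sphere.

The montage is the geometric substrate for everything spatial in the
pipeline: spherical-spline interpolation and the surface Laplacian, gel-bridge
bookkeeping, and the named electrode subsets used for coherence metrics
(28-channel analysis set, centro-parietal cross-validation set, and the
left/right 12-channel lateralization sets).

Positions come from MNE's standard 10-05 template, re-centered by a
least-squares sphere fit and normalized to unit radius, so that inter-electrode
cosine angles are well defined for the Legendre expansions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Full 63-channel cap (10-10 layout). O1/O2 were only present in a subset of
#: recordings; the standard configuration drops them (-> 61 channels).
LABELS_63: tuple[str, ...] = (
    "Fpz", "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

LABELS_61: tuple[str, ...] = tuple(l for l in LABELS_63 if l not in ("O1", "O2"))

#: Channels excluded from analysis because of noise (behind-the-ear sites).
NOISY_CHANNELS: tuple[str, ...] = ("TP9", "TP10")

#: 28-channel fronto-central/centro-parietal analysis subset.
ANALYSIS_28: tuple[str, ...] = (
    "Fz", "F1", "F2", "F3", "F4", "F5", "F6",
    "FCz", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6",
    "Cz", "C1", "C2", "C3", "C4", "C5", "C6",
    "CPz", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
)

#: Centro-parietal/midline subset used for leave-one-out selection of the
#: spline regularization constant (the analysis set plus the parietal row).
CV_SUBSET: tuple[str, ...] = ANALYSIS_28 + ("Pz", "P1", "P2", "P3", "P4", "P5", "P6")

LEFT_12: tuple[str, ...] = (
    "F5", "F3", "F1", "FC5", "FC3", "FC1", "C5", "C3", "C1", "CP5", "CP3", "CP1",
)
RIGHT_12: tuple[str, ...] = (
    "F2", "F4", "F6", "FC2", "FC4", "FC6", "C2", "C4", "C6", "CP2", "CP4", "CP6",
)


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit; returns (center, radius)."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


_POSITION_CACHE: dict[str, np.ndarray] = {}


def _standard_positions() -> dict[str, np.ndarray]:
    """Unit-sphere positions for the 10-05 label set (cached)."""
    if _POSITION_CACHE:
        return _POSITION_CACHE
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    pts = np.array([ch_pos[l] for l in LABELS_63])
    center, _ = _fit_sphere(pts)
    for label, p in ch_pos.items():
        v = np.asarray(p, dtype=float) - center
        _POSITION_CACHE[label] = v / np.linalg.norm(v)
    return _POSITION_CACHE


@dataclass(frozen=True)
class Montage:
    """Electrode labels with unit-sphere 3-D positions and named subsets."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3), unit norm rows
    subsets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions length mismatch")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        for name, subset in self.subsets.items():
            unknown = set(subset) - set(self.labels)
            if unknown:
                raise ValueError(f"subset {name!r} has unknown labels {sorted(unknown)}")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label {label!r}") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def positions_for(self, labels) -> np.ndarray:
        return self.positions[[self.index(l) for l in labels]]

    def drop(self, labels) -> "Montage":
        """Montage without *labels*; subsets are restricted accordingly."""
        labels = set(labels)
        unknown = labels - set(self.labels)
        if unknown:
            raise KeyError(f"unknown electrode labels {sorted(unknown)}")
        keep = [i for i, l in enumerate(self.labels) if l not in labels]
        new_labels = tuple(self.labels[i] for i in keep)
        subsets = {
            name: tuple(l for l in subset if l in new_labels)
            for name, subset in self.subsets.items()
        }
        return Montage(new_labels, self.positions[keep], subsets)


def default_subsets(labels) -> dict[str, tuple[str, ...]]:
    present = set(labels)
    return {
        "analysis": tuple(l for l in ANALYSIS_28 if l in present),
        "cv": tuple(l for l in CV_SUBSET if l in present),
        "left": tuple(l for l in LEFT_12 if l in present),
        "right": tuple(l for l in RIGHT_12 if l in present),
    }


def default_montage(n_channels: int = 61) -> Montage:
    """Standard cap layout with 61 (default) or 63 channels."""
    if n_channels == 61:
        labels = LABELS_61
    elif n_channels == 63:
        labels = LABELS_63
    else:
        raise ValueError("n_channels must be 61 or 63")
    pos = _standard_positions()
    positions = np.array([pos[l] for l in labels])
    return Montage(labels, positions, default_subsets(labels))
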