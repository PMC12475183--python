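"""Shared fixtures: small synthetic recordings reused across test modules.

Monte-Carlo style tests use short blocks (10-40 s instead of the protocol's
140 s) to keep the suite fast; the full-length condition is exercised once by
the end-to-end fixtures below.
"""

import numpy as np
import pytest

import ckc
from ckc import coherence as coh
from ckc import eeg_preprocess as ep
from ckc import kinematics as kin


def quick_config(**kw) -> ckc.SimulationConfig:
    """Short default-coupling block for fast tests."""
    kw.setdefault("duration_s", 20.0)
    kw.setdefault("seed", 7)
    return ckc.SimulationConfig(**kw)


def run_pipeline(rec: ckc.Recording, averaging="median", method="magnitude",
                 segment_s=2.0, fmax=10.0):
    """Preprocess + CSD + coherence for one simulated recording."""
    rec2 = ep.exclude_channels(rec, [l for l in ("TP9", "TP10") if l in rec.labels])
    rec3 = ep.bandpass(ep.remove_blinks(rec2))
    bridges = ep.detect_bridges(rec3)
    rec3 = ep.repair_bridges(rec3, bridges)
    params = ep.select_lambda(rec3)
    rec5 = ep.csd_transform(rec3, params)
    trace, _ = kin.correct_bit_flips(rec.accel)
    acc = coh.prepare_accel(trace, rec.events, rec5.n_samples, rec5.fs_hz, method=method)
    spec = coh.channel_coherence(rec5, acc, segment_s, averaging=averaging, fmax=fmax)
    return spec, rec5, params


@pytest.fixture(scope="session")
def default_recording():
    """One medium default-condition block shared by read-only tests."""
    return ckc.simulate_recording(quick_config(duration_s=40.0, seed=3))


@pytest.fixture(scope="session")
def full_length_spectrum():
    """Full 140 s protocol block through the whole chain (Magnitude-Median,
    0.5 Hz resolution), shared by the end-to-end recovery tests."""
    cfg = ckc.SimulationConfig(duration_s=140.0, seed=20260921)
    rec = ckc.simulate_recording(cfg)
    spec, rec5, params = run_pipeline(rec)
    return cfg, spec, rec5.montage


def subset_argmax_freq(spec, montage, f_lo, f_hi):
    """Frequency of the coherence maximum over the analysis subset in a band."""
    idx = [spec.channels.index(l) for l in montage.subsets["analysis"]]
    band = np.flatnonzero((spec.freqs_hz >= f_lo) & (spec.freqs_hz <= f_hi))
    vals = spec.values[np.ix_(idx, band)]
    j = np.unravel_index(np.argmax(vals), vals.shape)[1]
    return float(spec.freqs_hz[band][j])
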