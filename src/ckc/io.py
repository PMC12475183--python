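"""Readers and writers for the pipeline's containers.

Recordings go to a self-describing HDF5 layout (groups /eeg, /eog, /accel,
/events, /meta); accelerometer logs are read from/written to timestamped CSV
(columns t, ax, ay, az, event); kinematics summaries and subject tables are
tidy CSV; simulation configs round-trip through YAML.  A converter to an MNE
Raw object is provided for cross-tool checks (FIF export via Raw.save).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import yaml

from .containers import AccelTrace, CsdParams, KinematicsSummary, Recording
from .montage import Montage, default_subsets
from .synthetic_data import SimulationConfig


def save_recording_h5(rec: Recording, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("eeg")
        g.create_dataset("data", data=rec.eeg, compression="gzip")
        g.attrs["labels"] = json.dumps(list(rec.labels))
        g.attrs["fs_hz"] = rec.fs_hz
        g.attrs["reference"] = rec.reference
        g.create_dataset("positions", data=rec.montage.positions)
        g.attrs["subsets"] = json.dumps(
            {k: list(v) for k, v in rec.montage.subsets.items()}
        )
        e = f.create_group("eog")
        e.create_dataset("data", data=rec.eog, compression="gzip")
        e.attrs["labels"] = json.dumps(list(rec.eog_labels))
        if rec.accel is not None:
            a = f.create_group("accel")
            a.create_dataset("samples", data=rec.accel.samples, compression="gzip")
            a.create_dataset("timestamps", data=rec.accel.timestamps)
            a.create_dataset("sync_events", data=rec.accel.sync_events)
            a.attrs["fs_hz"] = rec.accel.fs_hz
            a.attrs["range_g"] = rec.accel.range_g
            a.attrs["units"] = rec.accel.units
        ev = f.create_group("events")
        ev.create_dataset("ttl", data=rec.events)
        m = f.create_group("meta")
        m.attrs["annotations"] = json.dumps(rec.annotations)
        m.attrs["provenance"] = json.dumps(rec.provenance)


def load_recording_h5(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["eeg"]
        labels = tuple(json.loads(g.attrs["labels"]))
        subsets = {k: tuple(v) for k, v in json.loads(g.attrs["subsets"]).items()}
        montage = Montage(labels, g["positions"][()], subsets)
        accel = None
        if "accel" in f:
            a = f["accel"]
            accel = AccelTrace(
                samples=a["samples"][()],
                timestamps=a["timestamps"][()],
                fs_hz=float(a.attrs["fs_hz"]),
                range_g=float(a.attrs["range_g"]),
                units=str(a.attrs["units"]),
                sync_events=a["sync_events"][()],
            )
        return Recording(
            eeg=g["data"][()],
            labels=labels,
            fs_hz=float(g.attrs["fs_hz"]),
            montage=montage,
            eog=f["eog"]["data"][()],
            eog_labels=tuple(json.loads(f["eog"].attrs["labels"])),
            accel=accel,
            events=f["events"]["ttl"][()],
            annotations=json.loads(f["meta"].attrs["annotations"]),
            reference=str(g.attrs["reference"]),
            provenance=json.loads(f["meta"].attrs["provenance"]),
        )


def read_accel_csv(path, fs_hz: float = 1094.0, range_g: float = 4.0) -> AccelTrace:
    """Timestamped accelerometer log: columns t, ax, ay, az, event (0/1)."""
    df = pd.read_csv(path)
    required = {"t", "ax", "ay", "az"}
    if not required <= set(df.columns):
        raise ValueError(f"accelerometer CSV needs columns {sorted(required)}")
    sync = (
        df.loc[df["event"] != 0, "t"].to_numpy()
        if "event" in df.columns
        else np.empty(0)
    )
    return AccelTrace(
        samples=df[["ax", "ay", "az"]].to_numpy().T,
        timestamps=df["t"].to_numpy(),
        fs_hz=fs_hz,
        range_g=range_g,
        units="steps",
        sync_events=sync,
    )


def write_accel_csv(trace: AccelTrace, path) -> None:
    event = np.zeros(trace.n_samples, dtype=int)
    for t in trace.sync_events:
        event[int(np.argmin(np.abs(trace.timestamps - t)))] = 1
    pd.DataFrame(
        {
            "t": trace.timestamps,
            "ax": trace.samples[0],
            "ay": trace.samples[1],
            "az": trace.samples[2],
            "event": event,
        }
    ).to_csv(path, index=False)


def kinematics_summary_table(summaries) -> pd.DataFrame:
    """Tidy table: one row per block x peak polarity."""
    rows = []
    for s in summaries:
        for polarity in ("max", "min"):
            rows.append(
                {
                    "block_id": s.block_id,
                    "hand": s.hand,
                    "polarity": polarity,
                    "median_period_ms": getattr(s, f"median_period_ms_{polarity}"),
                    "iqr_period_ms": getattr(s, f"iqr_period_ms_{polarity}"),
                    "median_cycles_before_compensation": s.median_cycles_before_compensation,
                    "n_peaks": s.n_peaks,
                }
            )
    return pd.DataFrame(rows)


def config_to_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    if "bridged_pairs" in raw:
        raw["bridged_pairs"] = tuple(tuple(p) for p in raw["bridged_pairs"])
    return SimulationConfig(**raw)


def csd_params_to_json(params: CsdParams, path) -> None:
    with open(path, "w") as f:
        json.dump(dataclasses.asdict(params), f, indent=2)


def to_mne_raw(rec: Recording):
    """Convert to an MNE Raw object (standard EEG interchange)."""
    import mne

    n_eog = rec.eog.shape[0] if rec.eog.size else 0
    info = mne.create_info(
        list(rec.labels) + list(rec.eog_labels[:n_eog]),
        rec.fs_hz,
        ch_types=["eeg"] * rec.n_channels + ["eog"] * n_eog,
        verbose="error",
    )
    arrays = [np.asarray(rec.eeg, float)]
    if n_eog:
        arrays.append(np.asarray(rec.eog, float))
    raw = mne.io.RawArray(np.vstack(arrays), info, verbose="error")
    std = mne.channels.make_dig_montage(
        ch_pos={l: rec.montage.position(l) * 0.095 for l in rec.labels},
        coord_frame="head",
    )
    raw.set_montage(std, on_missing="ignore", verbose="error")
    return raw
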