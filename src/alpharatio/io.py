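"""Reading and writing recordings, cohorts and feature tables.

Recordings travel in a self-describing HDF5 container: one dataset for the
samples, one per reference trace, and attributes for the sampling rate,
channel table (JSON) and bad-segment annotations.  Subject tables and feature
tables are plain CSV.  A thin optional adapter maps MNE raw objects (FIF,
CTF, ...) onto the Recording contract.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .cohortsim import Recording
from .exceptions import InvalidArgumentError

__all__ = [
    "save_recording",
    "load_recording",
    "save_cohort",
    "load_cohort",
    "recording_from_raw",
]


def save_recording(rec: Recording, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", compression_opts=4)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["channel_meta"] = rec.channel_meta.to_json(orient="records")
        f.attrs["annotations"] = json.dumps(
            [[float(s), float(e), str(k)] for s, e, k in rec.annotations]
        )
        grp = f.create_group("reference")
        for name, trace in rec.reference_channels.items():
            grp.create_dataset(name, data=np.asarray(trace), compression="gzip")


def load_recording(path) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["sampling_rate"])
        from io import StringIO

        meta = pd.read_json(StringIO(f.attrs["channel_meta"]), orient="records")
        annotations = [(s, e, k) for s, e, k in json.loads(f.attrs["annotations"])]
        refs = {name: f["reference"][name][()] for name in f.get("reference", {})}
    return Recording(
        data=data,
        sampling_rate=fs,
        channel_meta=meta,
        reference_channels=refs,
        annotations=annotations,
    )


def save_cohort(recordings: Sequence[Recording], table: pd.DataFrame, out_dir) -> None:
    """One HDF5 container per subject plus a subjects.csv aligned by row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(recordings) != len(table):
        raise InvalidArgumentError("recordings and subject table rows must align")
    for rec, sid in zip(recordings, table["subject_id"]):
        save_recording(rec, out_dir / f"{sid}.h5")
    table.to_csv(out_dir / "subjects.csv", index=False)


def load_cohort(in_dir) -> tuple[list[Recording], pd.DataFrame]:
    in_dir = Path(in_dir)
    table_path = in_dir / "subjects.csv"
    if not table_path.exists():
        raise InvalidArgumentError(f"no subjects.csv in {in_dir}")
    table = pd.read_csv(table_path)
    recordings = [load_recording(in_dir / f"{sid}.h5") for sid in table["subject_id"]]
    return recordings, table


def recording_from_raw(raw, load: bool = True) -> Recording:
    """Map an ``mne.io.Raw`` (FIF/CTF/...) onto the Recording contract.

    Data channels become rows of ``data``; ECG/EOG channels become reference
    traces; raw annotations become bad-segment annotations.  Requires the
    optional ``mne`` dependency.
    """
    import mne  # optional dependency; imported lazily

    if load:
        raw.load_data()
    picks = mne.pick_types(raw.info, meg=True, eeg=True, ref_meg=False)
    if len(picks) == 0:
        raise InvalidArgumentError("raw object has no MEG/EEG data channels")
    data = raw.get_data(picks=picks)
    rows = []
    for p in picks:
        ch = raw.info["chs"][p]
        loc = ch["loc"][:2]
        x = float(loc[0]) if np.isfinite(loc[0]) else 0.0
        y = float(loc[1]) if np.isfinite(loc[1]) else 0.0
        hemi = "R" if x > 1e-9 else ("L" if x < -1e-9 else "midline")
        rows.append({"label": ch["ch_name"], "x": x, "y": y, "hemisphere": hemi, "region": ""})
    refs = {}
    ecg = mne.pick_types(raw.info, meg=False, ecg=True)
    if len(ecg):
        refs["cardiac"] = raw.get_data(picks=[ecg[0]])[0]
    eog = mne.pick_types(raw.info, meg=False, eog=True)
    if len(eog):
        refs["ocular"] = raw.get_data(picks=[eog[0]])[0]
    annotations = [
        (float(on), float(on + dur), str(desc))
        for on, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
        if dur > 0
    ]
    return Recording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_meta=pd.DataFrame(rows),
        reference_channels=refs,
        annotations=annotations,
    )
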