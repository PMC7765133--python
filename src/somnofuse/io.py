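"""File formats: EEG matrix + JSON sidecar, NIfTI-1 BOLD, TSV tables.

EEG travels as a ``.npy`` signal matrix (channels x samples, microvolts)
with a JSON sidecar carrying rate, labels, positions and events. BOLD uses
NIfTI-1 through nibabel with a diagonal affine built from the voxel size.
Event tables, motion traces and band-power series are tab-separated text.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BandPowerSeries, EEGRecording, EventTable, MotionTrace, VolumeSeries


def save_eeg(eeg: EEGRecording, base_path) -> None:
    """Write ``<base>.npy`` + ``<base>.json`` for one recording."""
    base = Path(base_path)
    np.save(base.with_suffix(".npy"), eeg.signal)
    sidecar = {
        "rate": eeg.rate,
        "labels": eeg.labels,
        "positions": None if eeg.positions is None else eeg.positions.tolist(),
        "events": [[int(s), c] for s, c in eeg.events],
        "reference": eeg.reference,
        "units": "microvolts",
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_eeg(base_path) -> EEGRecording:
    base = Path(base_path)
    signal = np.load(base.with_suffix(".npy"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    return EEGRecording(
        signal=signal,
        rate=sidecar["rate"],
        labels=sidecar["labels"],
        positions=None if sidecar.get("positions") is None
        else np.asarray(sidecar["positions"], float),
        events=[(int(s), c) for s, c in sidecar.get("events", [])],
        reference=sidecar.get("reference", "unknown"),
    )


def save_bold(series: VolumeSeries, path) -> None:
    affine = np.diag(list(series.voxel_size) + [1.0])
    affine[:3, 3] = series.origin
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr,))
    nib.save(img, str(path))


def load_bold(path) -> VolumeSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VolumeSeries(
        data=np.asanyarray(img.dataobj, dtype=float),
        tr=tr,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        origin=tuple(float(v) for v in img.affine[:3, 3]),
    )


def save_stat_map(t_values: np.ndarray, voxel_size, path, df: int | None = None) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(t_values, np.float32), affine)
    nib.save(img, str(path))
    if df is not None:
        Path(str(path)).with_suffix(".json").write_text(json.dumps({"df": df}))


def save_motion(trace: MotionTrace, path, rotations_in_radians: bool = True) -> None:
    """6-column TSV in SPM order; rotations stored in radians in the file
    (degrees in reports), matching the common parameter-file convention."""
    cols = trace.as_columns().copy()
    if rotations_in_radians:
        cols[:, 3:] = np.deg2rad(cols[:, 3:])
    pd.DataFrame(
        cols, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    ).to_csv(path, sep="\t", index=False)


def load_motion(path, rotations_in_radians: bool = True) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    trans = df.iloc[:, :3].to_numpy(float)
    rots = df.iloc[:, 3:6].to_numpy(float)
    if rotations_in_radians:
        rots = np.rad2deg(rots)
    return MotionTrace(translations=trans, rotations=rots)


def save_band_power(series: BandPowerSeries, labels, base_path) -> None:
    base = Path(base_path)
    series.to_long_frame(labels).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    meta = {
        "window_length": series.window_length,
        "step": series.step,
        "taper_params": list(series.taper_params),
        "bands": list(series.bands),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def save_events(events: EventTable, path) -> None:
    events.to_tsv(path)


def load_events(path) -> EventTable:
    return EventTable.from_tsv(path)
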