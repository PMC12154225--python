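"""Readers and writers for the package's on-disk formats.

Label volumes travel as multi-page TIFF or HDF5 stacks with a JSON sidecar
(voxel size, label table, optional ground truth); spike trains and session
logs as CSV; epochs, observers and reports as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import LabeledVolume, SpikeTrain, VibrationEpoch
from .synthetic.observer import ObserverModel
from .synthetic.phantoms import ContactTruth, GroundTruth


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "surface_area_um2": {str(k): v for k, v in truth.surface_area_um2.items()},
        "contacts": [asdict(c) for c in truth.contacts.values()],
        "nucleus_centroids_um": {
            str(k): list(v) for k, v in truth.nucleus_centroids_um.items()
        },
    }


def _truth_from_json(d: dict) -> GroundTruth:
    truth = GroundTruth(
        surface_area_um2={int(k): float(v) for k, v in d.get("surface_area_um2", {}).items()},
        nucleus_centroids_um={
            int(k): tuple(v) for k, v in d.get("nucleus_centroids_um", {}).items()
        },
    )
    for c in d.get("contacts", []):
        pair = tuple(c["pair"])
        truth.contacts[pair] = ContactTruth(
            pair=pair,
            separation_nm=float(c["separation_nm"]),
            arc_per_slice_um=float(c["arc_per_slice_um"]),
            area_um2=float(c["area_um2"]),
        )
    return truth


def save_labeled_volume(
    path: str | Path,
    volume: LabeledVolume,
    truth: GroundTruth | None = None,
) -> Path:
    """Write a label stack (.tif/.tiff or .h5) plus its JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.labels, photometric="minisblack")
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=volume.labels, compression="gzip")
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    sidecar = {
        "voxel_size_nm": list(volume.voxel_size_nm),
        "label_table": {str(k): v for k, v in volume.label_table.items()},
    }
    if truth is not None:
        sidecar["ground_truth"] = _truth_to_json(truth)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_labeled_volume(path: str | Path) -> tuple[LabeledVolume, GroundTruth | None]:
    """Read a label stack and its sidecar; returns (volume, ground truth or None)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            labels = f["labels"][()]
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    sidecar = json.loads(_sidecar_path(path).read_text())
    volume = LabeledVolume(
        np.asarray(labels),
        tuple(sidecar["voxel_size_nm"]),
        {int(k): v for k, v in sidecar["label_table"].items()},
    )
    truth = None
    if "ground_truth" in sidecar:
        truth = _truth_from_json(sidecar["ground_truth"])
    return volume, truth


# ---------------------------------------------------------------------------
# spike trains and epochs
# ---------------------------------------------------------------------------

def save_spike_trains(path: str | Path, trains: list[SpikeTrain]) -> Path:
    """Write spike trains as a two-column CSV (time_s, unit_id)."""
    path = Path(path)
    frames = [
        pd.DataFrame({"time_s": t.times, "unit_id": t.unit_id}) for t in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def load_spike_trains(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(np.sort(sub["time_s"].to_numpy(float)), unit_id=uid)
        for uid, sub in df.groupby("unit_id", sort=True)
    ]


def save_epoch(path: str | Path, epoch: VibrationEpoch) -> Path:
    Path(path).write_text(json.dumps(asdict(epoch), indent=2))
    return Path(path)


def load_epoch(path: str | Path) -> VibrationEpoch:
    return VibrationEpoch(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# observers and session logs
# ---------------------------------------------------------------------------

def load_observer(path: str | Path) -> ObserverModel:
    return ObserverModel(**json.loads(Path(path).read_text()))


def save_session_log(path: str | Path, log) -> Path:
    """Write a psychophysics session log as CSV (one row per trial)."""
    rows = [
        {
            "index": t.index,
            "trial_type": t.trial_type,
            "amplitude_um": t.amplitude_um,
            "amplitude_step": t.amplitude_step,
            "correct": int(t.correct),
        }
        for t in log.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_json_report(path: str | Path, report: dict) -> Path:
    """Write a JSON report, converting numpy scalars/arrays along the way."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=default))
    return path
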