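"""Epoch-container I/O, archive serialization, and run manifests.

An epoch set lives as a pair of files: `<stem>.npy` holding the
trials x channels x samples array, and `<stem>.json` holding labels,
sampling rate, channel names and any extra metadata. Pareto archives are
written as CSV (one row per member: selected channel names and objective
scores) with a JSON manifest alongside.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import EpochSet, StimulusSpec, names_from_mask
from .pareto import ParetoArchive

_VIEW_COLUMNS = {
    "mi": ("mar", "nc"),
    "ssvep": ("sar", "nc"),
    "final": ("mar", "sar", "nc"),
}


def write_epochs(epochs: EpochSet, stem: str | Path,
                 extra: Optional[dict] = None) -> Path:
    """Write an epoch set as <stem>.npy + <stem>.json; returns the .npy path."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    npy_path = stem.with_suffix(".npy")
    np.save(npy_path, epochs.data)
    sidecar = {
        "labels": [int(v) for v in epochs.labels],
        "fs": float(epochs.fs),
        "channel_names": list(epochs.channel_names),
    }
    if extra:
        sidecar.update(extra)
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return npy_path


def read_epochs(stem: str | Path) -> EpochSet:
    """Load an epoch set written by write_epochs, validating the sidecar."""
    stem = Path(stem)
    npy_path = stem.with_suffix(".npy")
    json_path = stem.with_suffix(".json")
    if not npy_path.exists():
        raise FileNotFoundError(f"missing array file {npy_path}")
    if not json_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {json_path}")
    sidecar = json.loads(json_path.read_text())
    for field in ("labels", "fs", "channel_names"):
        if field not in sidecar:
            raise ValueError(f"sidecar {json_path} lacks required field '{field}'")
    data = np.load(npy_path)
    if data.ndim != 3:
        raise ValueError(f"{npy_path}: expected 3-D (trials, channels, samples) "
                         f"array, got shape {data.shape}")
    if len(sidecar["channel_names"]) != data.shape[1]:
        raise ValueError(
            f"sidecar lists {len(sidecar['channel_names'])} channel names but "
            f"the array has {data.shape[1]} channels")
    if len(sidecar["labels"]) != data.shape[0]:
        raise ValueError(
            f"sidecar lists {len(sidecar['labels'])} labels but the array has "
            f"{data.shape[0]} trials")
    return EpochSet(data=data, labels=np.asarray(sidecar["labels"]),
                    fs=float(sidecar["fs"]),
                    channel_names=tuple(sidecar["channel_names"]))


def read_stimulus(stem: str | Path) -> StimulusSpec:
    """Read the stimulus specification stored in an SSVEP sidecar."""
    sidecar = json.loads(Path(stem).with_suffix(".json").read_text())
    if "stim_freqs" not in sidecar:
        raise ValueError("sidecar lacks 'stim_freqs'")
    return StimulusSpec(frequencies=tuple(sidecar["stim_freqs"]),
                        n_harmonics=int(sidecar.get("n_harmonics", 2)))


def archive_to_frame(archive: ParetoArchive,
                     channel_names: tuple[str, ...]) -> pd.DataFrame:
    """Tabulate an archive: selected channels, count, objective columns.

    Rows are sorted deterministically (ascending channel count, descending
    first objective, then mask bits) so repeated runs produce identical
    files.
    """
    cols = _VIEW_COLUMNS[archive.objective_view]
    rows = []
    for m in archive:
        row = {
            "channels": ";".join(names_from_mask(m.mask, channel_names)),
            "n_selected": m.n_selected,
        }
        row.update({c: m.objectives[i] for i, c in enumerate(cols)})
        row["_key"] = m.key()
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["channels", "n_selected", *cols, "_key"])
    if len(frame):
        frame = frame.sort_values(
            ["n_selected", cols[0], "_key"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return frame.drop(columns="_key")


def write_archive(archive: ParetoArchive, stem: str | Path,
                  channel_names: tuple[str, ...],
                  manifest_extra: Optional[dict] = None) -> Path:
    """Write an archive as <stem>.csv plus <stem>.manifest.json."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    csv_path = stem.with_suffix(".csv")
    archive_to_frame(archive, channel_names).to_csv(
        csv_path, index=False, float_format="%.6f")
    manifest = {"cap": archive.cap, "objective_view": archive.objective_view,
                "size": len(archive)}
    if manifest_extra:
        manifest.update(manifest_extra)
    Path(str(stem) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
    return csv_path


def write_run_manifest(path: str | Path, manifest: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
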