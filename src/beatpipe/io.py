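"""Array-container serialization: one .npy per object plus a JSON sidecar.

A recording ``name`` is stored as ``name.npy`` (channels x samples,
float64) and ``name.json`` (fs, channel names, trigger samples, condition,
ground truth). Epochs use the same scheme with the epoch window in the
sidecar. This keeps every deliverable text-inspectable apart from the raw
sample arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synth import SyntheticRecording

__all__ = ["save_recording", "load_recording", "save_epochs", "load_epochs"]


def _write_sidecar(path: Path, meta: dict) -> None:
    path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def save_recording(rec: SyntheticRecording, directory: str | Path, name: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", rec.data)
    _write_sidecar(
        directory / f"{name}.json",
        {
            "kind": "recording",
            "fs": rec.fs,
            "channel_names": rec.channel_names,
            "trigger_samples": [int(s) for s in rec.trigger_samples],
            "condition": rec.condition,
            "ground_truth": rec.ground_truth,
        },
    )
    return directory / f"{name}.npy"


def load_recording(directory: str | Path, name: str) -> SyntheticRecording:
    directory = Path(directory)
    meta = json.loads((directory / f"{name}.json").read_text())
    if meta.get("kind") != "recording":
        raise ValueError(f"{name} is not a recording container")
    return SyntheticRecording(
        data=np.load(directory / f"{name}.npy"),
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        trigger_samples=np.asarray(meta["trigger_samples"], dtype=int),
        condition=meta["condition"],
        ground_truth=meta["ground_truth"],
    )


def save_epochs(epochs, directory: str | Path, name: str) -> Path:
    from .preprocess import Epochs  # local import: avoid cycle

    if not isinstance(epochs, Epochs):
        raise TypeError("save_epochs expects an Epochs container")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", epochs.data)
    _write_sidecar(
        directory / f"{name}.json",
        {
            "kind": "epochs",
            "fs": epochs.fs,
            "window": list(epochs.window),
            "channel_names": epochs.channel_names,
            "condition": epochs.condition,
        },
    )
    return directory / f"{name}.npy"


def load_epochs(directory: str | Path, name: str):
    from .preprocess import Epochs

    directory = Path(directory)
    meta = json.loads((directory / f"{name}.json").read_text())
    if meta.get("kind") != "epochs":
        raise ValueError(f"{name} is not an epochs container")
    return Epochs(
        data=np.load(directory / f"{name}.npy"),
        fs=meta["fs"],
        window=tuple(meta["window"]),
        channel_names=meta["channel_names"],
        condition=meta["condition"],
    )
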