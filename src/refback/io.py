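"""HDF5-backed persistence for epoch sets and source-space artifacts."""

from __future__ import annotations

import numpy as np

from .simulate import EpochSet
from .task_design import ConditionLabel

__all__ = ["save_epochs", "load_epochs"]


def save_epochs(path, epochs: EpochSet) -> None:
    """Persist an EpochSet: /data (float32), /times, /labels, /correct,
    /channels plus sfreq and subject_id attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times)
        labels = [str(l) if l is not None else "n/a" for l in epochs.trial_labels]
        f.create_dataset("labels", data=np.array(labels, dtype="S"))
        f.create_dataset("correct", data=epochs.correct.astype(np.uint8))
        f.create_dataset(
            "channels", data=np.array(epochs.channel_labels, dtype="S")
        )
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["subject_id"] = epochs.subject_id


def load_epochs(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        labels = [
            None if s == "n/a" else ConditionLabel.parse(s)
            for s in (b.decode() for b in f["labels"][()])
        ]
        return EpochSet(
            subject_id=str(f.attrs["subject_id"]),
            data=f["data"][()].astype(float),
            sfreq=float(f.attrs["sfreq"]),
            times=f["times"][()],
            channel_labels=tuple(b.decode() for b in f["channels"][()]),
            trial_labels=labels,
            correct=f["correct"][()].astype(bool),
        )
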