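"""Epoch hygiene: Kaiser FIR filtering, baseline correction, peak-to-peak
artifact rejection, and per-condition averaging."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, signal

from .simulate import EpochSet
from .task_design import ALL_LABELS, ConditionLabel

__all__ = [
    "FilterSpec",
    "Evoked",
    "FilterDesignError",
    "TooFewEpochsError",
    "design_kaiser_fir",
    "apply_zero_phase",
    "filter_epochs",
    "baseline_correct",
    "reject_artifacts",
    "average_conditions",
    "preprocess_subject",
]


class FilterDesignError(ValueError):
    pass


class TooFewEpochsError(RuntimeError):
    """A subject lacks usable epochs in a required condition (the analogue
    of a participant exclusion for too few valid epochs)."""

    def __init__(self, subject_id: str, missing: Sequence[ConditionLabel]):
        self.subject_id = subject_id
        self.missing = list(missing)
        super().__init__(
            f"subject {subject_id}: no usable epochs in condition(s) "
            + ", ".join(str(m) for m in missing)
        )


@dataclass(frozen=True)
class FilterSpec:
    """Kaiser-window FIR specification.

    Defaults are the low-pass used on the EEG: 30 Hz cutoff, beta 12.2653
    (~120 dB design attenuation), 10 Hz transition bandwidth.
    """

    kind: str = "lowpass"
    cutoff: float = 30.0
    kaiser_beta: float = 12.2653
    transition_bandwidth: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise FilterDesignError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0 or self.transition_bandwidth <= 0:
            raise FilterDesignError("cutoff and transition bandwidth must be > 0")


#: the high-pass applied to continuous recordings (too long for one epoch,
#: so the direct-epoch simulation path never applies it)
HIGHPASS_SPEC = FilterSpec("highpass", 0.1, 5.6533, 0.2)


def _kaiser_attenuation(beta: float) -> float:
    """Invert the Kaiser beta formula to the design attenuation in dB."""
    if beta <= 0:
        return 21.0
    if beta >= signal.kaiser_beta(50.0):
        return beta / 0.1102 + 8.7
    f = lambda a: signal.kaiser_beta(a) - beta
    return float(optimize.brentq(f, 21.0, 50.0))


def design_kaiser_fir(spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Design the odd-length, symmetric (linear-phase) Kaiser FIR kernel.

    The kernel length follows the Kaiser design formula for the given beta
    and transition bandwidth; the cutoff is the half-amplitude (-6 dB)
    point of the frequency response.
    """
    nyq = sfreq / 2.0
    if spec.cutoff >= nyq:
        raise FilterDesignError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist {nyq} Hz"
        )
    atten = _kaiser_attenuation(spec.kaiser_beta)
    delta_omega = 2 * np.pi * spec.transition_bandwidth / sfreq
    numtaps = int(np.ceil((atten - 7.95) / (2.285 * delta_omega))) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(
        numtaps,
        spec.cutoff,
        window=("kaiser", spec.kaiser_beta),
        pass_zero=(spec.kind == "lowpass"),
        fs=sfreq,
    )


def apply_zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase filtering along the last axis.

    The kernel is symmetric, so plain convolution with the group delay
    compensated is zero-phase; edges are padded by reflection.
    """
    data = np.asarray(data, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if data.shape[-1] <= kernel.size:
        raise ValueError(
            f"data length {data.shape[-1]} must exceed kernel length {kernel.size}"
        )
    return ndimage.convolve1d(data, kernel, axis=-1, mode="reflect")


def filter_epochs(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    kernel = design_kaiser_fir(spec, epochs.sfreq)
    return EpochSet(
        subject_id=epochs.subject_id,
        data=apply_zero_phase(epochs.data, kernel),
        sfreq=epochs.sfreq,
        times=epochs.times,
        channel_labels=epochs.channel_labels,
        trial_labels=list(epochs.trial_labels),
        correct=epochs.correct,
    )


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-100.0, 0.0)
) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over [start, end) ms."""
    start, end = window
    mask = (epochs.times >= start) & (epochs.times < end)
    if not mask.any():
        raise ValueError(f"baseline window {window} lies outside the epoch")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        subject_id=epochs.subject_id,
        data=epochs.data - baseline,
        sfreq=epochs.sfreq,
        times=epochs.times,
        channel_labels=epochs.channel_labels,
        trial_labels=list(epochs.trial_labels),
        correct=epochs.correct,
    )


def reject_artifacts(
    epochs: EpochSet, threshold: float = 100.0
) -> tuple[EpochSet, np.ndarray]:
    """Reject epochs whose min-to-max voltage change exceeds ``threshold``
    microvolts on any channel.  Returns (kept epochs, rejected mask)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    rejected = (ptp > threshold).any(axis=1)
    return epochs.subset(~rejected), rejected


@dataclass
class Evoked:
    """Per-condition (or contrast) average waveform for one subject."""

    condition: ConditionLabel | str
    data: np.ndarray  # channels x samples, microvolts
    n_epochs: int
    subject_id: str
    times: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("evoked data must be finite")


def average_conditions(
    epochs: EpochSet,
    correct_only: bool = True,
    required: Sequence[ConditionLabel] = ALL_LABELS,
) -> dict[ConditionLabel, Evoked]:
    """Average surviving (and, by default, correct) epochs per condition.

    Raises :class:`TooFewEpochsError` if any required condition ends up
    empty, mirroring participant exclusion for too few valid epochs.
    """
    out: dict[ConditionLabel, Evoked] = {}
    labels = epochs.trial_labels
    for cond in required:
        mask = np.array(
            [
                l == cond and (epochs.correct[i] or not correct_only)
                for i, l in enumerate(labels)
            ]
        )
        n = int(mask.sum())
        if n == 0:
            continue
        out[cond] = Evoked(
            condition=cond,
            data=epochs.data[mask].mean(axis=0),
            n_epochs=n,
            subject_id=epochs.subject_id,
            times=epochs.times,
            channel_labels=epochs.channel_labels,
        )
    missing = [c for c in required if c not in out]
    if missing:
        raise TooFewEpochsError(epochs.subject_id, missing)
    return out


def preprocess_subject(
    epochs: EpochSet,
    lowpass: FilterSpec = FilterSpec(),
    baseline: tuple[float, float] = (-100.0, 0.0),
    reject_threshold: float = 100.0,
    correct_only: bool = True,
) -> tuple[dict[ConditionLabel, Evoked], np.ndarray]:
    """Filter -> baseline -> reject -> average, returning the per-condition
    evokeds and the rejection mask."""
    filtered = filter_epochs(epochs, lowpass)
    corrected = baseline_correct(filtered, baseline)
    kept, rejected = reject_artifacts(corrected, reject_threshold)
    return average_conditions(kept, correct_only=correct_only), rejected
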