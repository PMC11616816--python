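"""Synthetic reference-back behaviour and ERP epochs.

Every downstream stage of the pipeline (preprocessing, subprocess
decomposition, inferential statistics, source analysis) is exercised on
data from this module, which emulates the statistical structure the
analysis assumes: per-trial reaction times built from additive subprocess
costs with a shifted-lognormal noise model, and stimulus-locked epochs
built from Gaussian-in-time components with condition-specific weights,
1/f-like background noise and occasional high-amplitude artifacts.

The subprocess costs are parameterised as *orthogonal* contrasts on the
latent mean RT: updating loads on all reference trials, gate opening on
switch-reference, gate closing on switch-comparison, and substitution as a
+/- half-cost split between different- and same-response reference trials.
Under this parameterisation each Table-style difference estimator is
unbiased for the cost of the same name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task_design import (
    COMPARISON,
    DIFFERENT,
    REFERENCE,
    SAME,
    SWITCH,
    ConditionLabel,
    SessionDesign,
    TrialRecord,
    classify_trials,
    generate_session,
)

__all__ = [
    "DEFAULT_CHANNELS",
    "MIDLINE_CHANNELS",
    "BehaviourParams",
    "ErpComponent",
    "ErpTemplate",
    "EpochSet",
    "simulate_behaviour",
    "simulate_epochs",
    "simulate_cohort_behaviour",
    "default_erp_template",
    "channel_weights",
]

#: the 12 electrode sites used in the mass-univariate analyses
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "Oz", "O2",
)
#: midline subset entering the anteriority ANOVAs
MIDLINE_CHANNELS: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")

#: responses faster than this are initiation errors, not valid RTs (ms)
MIN_VALID_RT = 150.0


@dataclass
class BehaviourParams:
    """Generative parameters of one subject's (or group's) behaviour.

    Costs are in ms on the latent mean RT.  ``rt_sd`` is the log-scale
    spread of the shifted lognormal (shift 150 ms).  ``p_incorrect`` and
    ``p_miss`` are trial-wise lapse probabilities on top of deadline
    misses.
    """

    base_rt: float = 450.0
    age_slowing: float = 0.0
    cost_updating: float = 45.0
    cost_substitution: float = 90.0
    cost_gate_opening: float = 35.0
    cost_gate_closing: float = 75.0
    rt_sd: float = 0.35
    p_incorrect: float = 0.11
    p_miss: float = 0.031
    rt_shift: float = MIN_VALID_RT

    def validate(self) -> None:
        if self.base_rt <= MIN_VALID_RT:
            raise ValueError(
                f"base_rt must exceed {MIN_VALID_RT} ms: faster responses "
                "are invalid by design (initiated before the stimulus)"
            )
        if self.p_incorrect + self.p_miss >= 1.0:
            raise ValueError("p_incorrect + p_miss must be < 1")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be non-negative")
        for name in (
            "cost_updating",
            "cost_substitution",
            "cost_gate_opening",
            "cost_gate_closing",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def latent_mean_rt(label: ConditionLabel | None, params: BehaviourParams) -> float:
    """Latent mean RT of a trial given its condition label."""
    mu = params.base_rt + params.age_slowing
    if label is None:
        return mu
    if label.trial_type == REFERENCE:
        mu += params.cost_updating
        mu += (0.5 if label.response == DIFFERENT else -0.5) * params.cost_substitution
        if label.gate_switch == SWITCH:
            mu += params.cost_gate_opening
    else:
        if label.gate_switch == SWITCH:
            mu += params.cost_gate_closing
    return mu


def simulate_behaviour(
    trials: Sequence[TrialRecord],
    params: BehaviourParams,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate per-trial responses for one subject.

    Returns a data frame with one row per trial: condition label, the
    drawn RT (NaN for misses), correctness, and validity (responded,
    RT >= 150 ms).  RTs exceeding the trial's response deadline
    (stimulus + following fixation, 1900 +/- 150 ms) become misses.
    Deterministic given ``seed``.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [t.label for t in trials]
    if all(l is None for l in labels) and len(trials) > 0:
        # caller passed raw, unclassified trials: classify in place
        labels = classify_trials(trials)

    rows = []
    for t, label in zip(trials, labels):
        mu = latent_mean_rt(label, params)
        if params.rt_sd == 0.0:
            rt = mu
        else:
            m = np.log(mu - params.rt_shift) - params.rt_sd**2 / 2.0
            rt = params.rt_shift + float(
                np.exp(rng.normal(m, params.rt_sd))
            )
        u = rng.random()
        missed = u < params.p_miss
        incorrect = (not missed) and u < params.p_miss + params.p_incorrect
        if not missed and rt > t.response_deadline:
            missed = True
            incorrect = False
        rows.append(
            {
                "block": t.block_index,
                "trial": t.trial_index_in_block,
                "label": str(label) if label is not None else "n/a",
                "rt_ms": np.nan if missed else rt,
                "correct": (not missed) and (not incorrect),
                "missed": missed,
                "valid": (not missed) and rt >= MIN_VALID_RT,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort_behaviour(
    n_subjects: int,
    design: SessionDesign,
    params: BehaviourParams,
    seed: int = 0,
    base_rt_between_sd: float = 40.0,
) -> dict[str, pd.DataFrame]:
    """Behaviour tables for a cohort with between-subject base-RT variance.

    Each subject gets an independent session (seeded from ``seed``) and a
    base RT drawn from N(params.base_rt, base_rt_between_sd), truncated
    above the 150 ms validity floor.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for s in range(n_subjects):
        base = float(rng.normal(params.base_rt, base_rt_between_sd))
        base = max(base, MIN_VALID_RT + 50.0)
        subj_params = replace(params, base_rt=base)
        sess = generate_session(
            replace(design, seed=int(rng.integers(2**31 - 1)))
        )
        out[f"sub-{s + 1:03d}"] = simulate_behaviour(
            sess, subj_params, int(rng.integers(2**31 - 1))
        )
    return out


# ---------------------------------------------------------------------------
# ERP epochs


@dataclass
class ErpComponent:
    """One Gaussian-in-time ERP component.

    ``width`` is the temporal standard deviation (ms); ``channel_weights``
    scales the component across channels; ``condition_weights`` maps
    condition labels to signed coefficients (labels absent from the map
    contribute zero).
    """

    label: str
    latency: float
    width: float
    amplitude: float
    channel_weights: np.ndarray
    condition_weights: Mapping[ConditionLabel, float]

    def waveform(self, times: np.ndarray) -> np.ndarray:
        if self.width <= 0:
            raise ValueError("component width must be positive")
        return self.amplitude * np.exp(-0.5 * ((times - self.latency) / self.width) ** 2)


@dataclass
class ErpTemplate:
    """Generative recipe for one subject's epochs."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    components: list[ErpComponent] = field(default_factory=list)
    noise_sd: float = 8.0
    noise_spectrum: str = "one_over_f"  # or "white"
    artifact_rate: float = 0.05
    artifact_amplitude: float = 200.0

    def validate(self) -> None:
        n_ch = len(self.channels)
        for c in self.components:
            if len(np.asarray(c.channel_weights)) != n_ch:
                raise ValueError(
                    f"component {c.label!r}: channel_weights length "
                    f"{len(np.asarray(c.channel_weights))} != {n_ch} channels"
                )
        if self.noise_spectrum not in ("white", "one_over_f"):
            raise ValueError(f"unknown noise_spectrum {self.noise_spectrum!r}")


@dataclass
class EpochSet:
    """Trials x channels x samples voltage array with timing metadata."""

    subject_id: str
    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    sfreq: float
    times: np.ndarray  # ms, strictly increasing
    channel_labels: tuple[str, ...]
    trial_labels: list[ConditionLabel | None]
    correct: np.ndarray  # bool per trial

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)
        n_trials, n_ch, n_samp = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ValueError("channel_labels length does not match data")
        if n_samp != self.times.size:
            raise ValueError("times length does not match data")
        if len(self.trial_labels) != n_trials or self.correct.size != n_trials:
            raise ValueError("per-trial metadata length does not match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            subject_id=self.subject_id,
            data=self.data[mask],
            sfreq=self.sfreq,
            times=self.times,
            channel_labels=self.channel_labels,
            trial_labels=[l for l, m in zip(self.trial_labels, mask) if m],
            correct=self.correct[mask],
        )


def default_times(sfreq: float = 1000.0, tmin: float = -100.0, tmax: float = 1000.0) -> np.ndarray:
    """Epoch time axis in ms: -100..1000 inclusive at 1 kHz -> 1101 samples."""
    step = 1000.0 / sfreq
    return np.arange(tmin, tmax + step / 2, step)


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sfreq: float
) -> np.ndarray:
    """Gaussian noise with ~1/f amplitude spectrum, unit standard deviation."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC drift
    spec = (
        rng.normal(size=shape[:-1] + (freqs.size,))
        + 1j * rng.normal(size=shape[:-1] + (freqs.size,))
    ) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_epochs(
    trials: Sequence[TrialRecord],
    template: ErpTemplate,
    behaviour: pd.DataFrame,
    seed: int = 0,
    sfreq: float = 1000.0,
) -> EpochSet:
    """Simulate stimulus-locked epochs for one subject.

    Each epoch is the sum over components of (Gaussian bump in time) x
    (channel weights) x (this trial's condition weight), plus noise, plus
    (with probability ``artifact_rate``) a step of ``artifact_amplitude``
    microvolts on one random channel.  Per-trial randomness is seeded from
    (seed, block, trial), so trial order does not affect any epoch's
    content.
    """
    template.validate()
    times = default_times(sfreq)
    labels = [t.label for t in trials]
    if all(l is None for l in labels) and len(trials) > 0:
        labels = classify_trials(trials)
    n_ch, n_samp = len(template.channels), times.size

    # deterministic signal part: per-label channel x sample template
    signal_for: dict[ConditionLabel | None, np.ndarray] = {}
    uniq = set(labels)
    for lab in uniq:
        sig = np.zeros((n_ch, n_samp))
        if lab is not None:
            for comp in template.components:
                w = comp.condition_weights.get(lab, 0.0)
                if w != 0.0:
                    sig += w * np.outer(
                        np.asarray(comp.channel_weights, dtype=float),
                        comp.waveform(times),
                    )
        signal_for[lab] = sig

    data = np.empty((len(trials), n_ch, n_samp))
    for i, (t, lab) in enumerate(zip(trials, labels)):
        rng_t = np.random.default_rng(
            [int(seed), int(t.block_index), int(t.trial_index_in_block)]
        )
        epoch = signal_for[lab].copy()
        if template.noise_sd > 0:
            if template.noise_spectrum == "white":
                noise = rng_t.normal(size=(n_ch, n_samp))
            else:
                noise = _one_over_f_noise(rng_t, (n_ch, n_samp), sfreq)
            epoch += template.noise_sd * noise
        if rng_t.random() < template.artifact_rate:
            ch = int(rng_t.integers(n_ch))
            start = int(rng_t.integers(1, n_samp))
            sign = 1.0 if rng_t.random() < 0.5 else -1.0
            epoch[ch, start:] += sign * template.artifact_amplitude
        data[i] = epoch

    correct = behaviour["correct"].to_numpy(dtype=bool)
    subject_id = behaviour.attrs.get("subject_id", "sub-001")
    return EpochSet(
        subject_id=subject_id,
        data=data,
        sfreq=sfreq,
        times=times,
        channel_labels=tuple(template.channels),
        trial_labels=labels,
        correct=correct,
    )


# ---------------------------------------------------------------------------
# topographies and a default template


def channel_weights(
    channels: Sequence[str] = DEFAULT_CHANNELS, focus: str = "Oz", spread: float = 1.0
) -> np.ndarray:
    """Smooth scalp weighting peaking at ``focus``.

    Electrodes are placed on a crude anterior-posterior x left-right grid;
    weights fall off as a Gaussian of the grid distance to the focus.
    """
    grid = {
        "F3": (-1, 2), "Fz": (0, 2), "F4": (1, 2),
        "C3": (-1, 1), "Cz": (0, 1), "C4": (1, 1),
        "P3": (-1, 0), "Pz": (0, 0), "P4": (1, 0),
        "O1": (-1, -1), "Oz": (0, -1), "O2": (1, -1),
    }
    if focus not in grid:
        raise ValueError(f"unknown focus electrode {focus!r}")
    fx, fy = grid[focus]
    w = np.array(
        [
            np.exp(-((x - fx) ** 2 + (y - fy) ** 2) / (2 * spread**2))
            for x, y in (grid[c] for c in channels)
        ]
    )
    return w


def _labels_where(**conditions) -> dict[ConditionLabel, float]:
    """Condition-weight map: +1 for labels matching all given attributes."""
    from .task_design import ALL_LABELS

    out = {}
    for lab in ALL_LABELS:
        if all(getattr(lab, k) == v for k, v in conditions.items()):
            out[lab] = 1.0
    return out


def default_erp_template(
    channels: Sequence[str] = DEFAULT_CHANNELS,
    amplitude_scale: float = 1.0,
    late_updating_amplitude: float = -1.8,
) -> ErpTemplate:
    """Template with one component per subprocess, mimicking the component
    structure the window analyses target: an occipital late updating
    negativity (400-1,000 ms), a frontal substitution positivity
    (250-600 ms), a parieto-occipital gate-opening positivity
    (300-500 ms) and a frontal gate-closing positivity (300-600 ms)."""
    channels = tuple(channels)
    comps = [
        ErpComponent(
            label="updating_late_negativity",
            latency=650.0,
            width=180.0,
            amplitude=late_updating_amplitude * amplitude_scale,
            channel_weights=channel_weights(channels, "Oz"),
            # loads on every reference trial so that the gate-opening
            # contrast (switch ref - no-switch ref) cancels it cleanly
            condition_weights=_labels_where(trial_type=REFERENCE),
        ),
        ErpComponent(
            label="substitution_frontal_positivity",
            latency=420.0,
            width=90.0,
            amplitude=0.8 * amplitude_scale,
            channel_weights=channel_weights(channels, "Fz"),
            condition_weights={
                **{
                    k: +0.5
                    for k in _labels_where(
                        trial_type=REFERENCE, gate_switch="no_switch", response=DIFFERENT
                    )
                },
                **{
                    k: -0.5
                    for k in _labels_where(
                        trial_type=REFERENCE, gate_switch="no_switch", response=SAME
                    )
                },
            },
        ),
        ErpComponent(
            label="gate_opening_posterior_positivity",
            latency=400.0,
            width=100.0,
            amplitude=1.6 * amplitude_scale,
            channel_weights=channel_weights(channels, "Pz"),
            condition_weights=_labels_where(trial_type=REFERENCE, gate_switch=SWITCH),
        ),
        ErpComponent(
            label="gate_closing_frontal_positivity",
            latency=430.0,
            width=120.0,
            amplitude=0.7 * amplitude_scale,
            channel_weights=channel_weights(channels, "Fz"),
            condition_weights=_labels_where(trial_type=COMPARISON, gate_switch=SWITCH),
        ),
    ]
    return ErpTemplate(channels=channels, components=comps)
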