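"""The four working-memory subprocess contrasts on RTs and ERPs.

The reference-back design crosses trial type (reference/comparison), gate
switch (switch/no-switch) and required response (same/different).  Four
signed combinations of the resulting cell means isolate the subprocesses:

* updating      = no-switch reference - no-switch comparison
* substitution  = (different - same | no-switch reference)
                  - (different - same | no-switch comparison)
* gate opening  = switch reference - no-switch reference
* gate closing  = switch comparison - no-switch comparison

Switch trials never enter updating or substitution, so gate toggling does
not contaminate them.  Where a contrast collapses over same/different
sub-cells, the two sub-cell means are averaged unweighted (cell-means
convention), not weighted by trial counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocessing import Evoked
from .simulate import MIN_VALID_RT
from .task_design import (
    COMPARISON,
    DIFFERENT,
    NO_SWITCH,
    REFERENCE,
    SAME,
    SWITCH,
    ConditionLabel,
)

__all__ = [
    "SUBPROCESSES",
    "SubprocessContrast",
    "DifferencePotential",
    "standard_contrasts",
    "condition_cell_means",
    "subprocess_cost",
    "costs_from_cell_means",
    "rt_costs",
    "difference_potentials",
    "window_mean",
]

SUBPROCESSES = ("updating", "substitution", "gate_opening", "gate_closing")


def _cell(t: str, g: str, r: str) -> ConditionLabel:
    return ConditionLabel(t, g, r)


@dataclass(frozen=True)
class SubprocessContrast:
    """Signed condition weights of one subprocess.

    Weights must sum to zero.  Sub-cell collapses use +-1/2 so that the
    contrast value equals a difference of unweighted cell-mean averages.
    """

    name: str
    weights: Mapping[ConditionLabel, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total) > 1e-12:
            raise ValueError(
                f"contrast {self.name!r} weights sum to {total}, expected 0"
            )

    def apply(self, values: Mapping[ConditionLabel, float]) -> float:
        missing = [c for c in self.weights if c not in values]
        if missing:
            raise KeyError(
                f"contrast {self.name!r}: missing condition(s) "
                + ", ".join(str(m) for m in missing)
            )
        return float(sum(w * values[c] for c, w in self.weights.items()))


def standard_contrasts() -> dict[str, SubprocessContrast]:
    half = 0.5
    return {
        "updating": SubprocessContrast(
            "updating",
            {
                _cell(REFERENCE, NO_SWITCH, SAME): +half,
                _cell(REFERENCE, NO_SWITCH, DIFFERENT): +half,
                _cell(COMPARISON, NO_SWITCH, SAME): -half,
                _cell(COMPARISON, NO_SWITCH, DIFFERENT): -half,
            },
        ),
        "substitution": SubprocessContrast(
            "substitution",
            {
                _cell(REFERENCE, NO_SWITCH, DIFFERENT): +1.0,
                _cell(REFERENCE, NO_SWITCH, SAME): -1.0,
                _cell(COMPARISON, NO_SWITCH, DIFFERENT): -1.0,
                _cell(COMPARISON, NO_SWITCH, SAME): +1.0,
            },
        ),
        "gate_opening": SubprocessContrast(
            "gate_opening",
            {
                _cell(REFERENCE, SWITCH, SAME): +half,
                _cell(REFERENCE, SWITCH, DIFFERENT): +half,
                _cell(REFERENCE, NO_SWITCH, SAME): -half,
                _cell(REFERENCE, NO_SWITCH, DIFFERENT): -half,
            },
        ),
        "gate_closing": SubprocessContrast(
            "gate_closing",
            {
                _cell(COMPARISON, SWITCH, SAME): +half,
                _cell(COMPARISON, SWITCH, DIFFERENT): +half,
                _cell(COMPARISON, NO_SWITCH, SAME): -half,
                _cell(COMPARISON, NO_SWITCH, DIFFERENT): -half,
            },
        ),
    }


# ---------------------------------------------------------------------------
# behavioural costs


def condition_cell_means(behaviour: pd.DataFrame) -> dict[ConditionLabel, float]:
    """Mean RT per condition over correct, valid (>=150 ms) trials."""
    ok = behaviour["correct"] & behaviour["valid"] & (behaviour["label"] != "n/a")
    ok &= behaviour["rt_ms"] >= MIN_VALID_RT
    sub = behaviour[ok]
    means: dict[ConditionLabel, float] = {}
    for label_str, grp in sub.groupby("label"):
        means[ConditionLabel.parse(label_str)] = float(grp["rt_ms"].mean())
    return means


def _collapse(
    means: Mapping[ConditionLabel, float], trial_type: str, gate: str
) -> float:
    """Unweighted average of the same/different sub-cell means."""
    cells = [_cell(trial_type, gate, SAME), _cell(trial_type, gate, DIFFERENT)]
    missing = [c for c in cells if c not in means]
    if missing:
        raise KeyError("missing condition(s): " + ", ".join(map(str, missing)))
    return float(np.mean([means[c] for c in cells]))


def _ratio(a: float, b: float) -> float:
    """Difference over the average of the two condition means."""
    return (a - b) / ((a + b) / 2.0)


def subprocess_cost(
    means: Mapping[ConditionLabel, float], name: str
) -> dict[str, float]:
    """One subprocess's cost (ms) and RT-ratio index from condition means.

    Raises KeyError if a needed cell is missing.
    """
    if name == "updating":
        a = _collapse(means, REFERENCE, NO_SWITCH)
        b = _collapse(means, COMPARISON, NO_SWITCH)
    elif name == "substitution":
        cells = [
            _cell(REFERENCE, NO_SWITCH, DIFFERENT),
            _cell(REFERENCE, NO_SWITCH, SAME),
            _cell(COMPARISON, NO_SWITCH, DIFFERENT),
            _cell(COMPARISON, NO_SWITCH, SAME),
        ]
        missing = [c for c in cells if c not in means]
        if missing:
            raise KeyError("missing condition(s): " + ", ".join(map(str, missing)))
        dr, sr, dc, sc = (means[c] for c in cells)
        return {
            "cost": (dr - sr) - (dc - sc),
            "ratio": _ratio(dr, sr) - _ratio(dc, sc),
        }
    elif name == "gate_opening":
        a = _collapse(means, REFERENCE, SWITCH)
        b = _collapse(means, REFERENCE, NO_SWITCH)
    elif name == "gate_closing":
        a = _collapse(means, COMPARISON, SWITCH)
        b = _collapse(means, COMPARISON, NO_SWITCH)
    else:
        raise ValueError(f"unknown subprocess {name!r}")
    return {"cost": a - b, "ratio": _ratio(a, b)}


def costs_from_cell_means(
    means: Mapping[ConditionLabel, float]
) -> dict[str, dict[str, float]]:
    """All four subprocess costs (ms) and RT-ratio indices from the 8
    condition means.

    The ratio divides the condition difference by the mean of the two
    condition means, discounting general slowing; the substitution ratio
    is the reference-cell ratio minus the comparison-cell ratio.
    """
    return {name: subprocess_cost(means, name) for name in SUBPROCESSES}


def rt_costs(behaviour_by_subject: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-subject subprocess costs and ratios.

    Subjects lacking a required condition cell are excluded from that
    subprocess only (cost and ratio recorded as NaN, ``excluded`` True).
    """
    rows = []
    for subject, beh in behaviour_by_subject.items():
        means = condition_cell_means(beh)
        for name in SUBPROCESSES:
            try:
                res = subprocess_cost(means, name)
                rows.append(
                    {
                        "subject": subject,
                        "subprocess": name,
                        "cost_ms": res["cost"],
                        "ratio": res["ratio"],
                        "excluded": False,
                    }
                )
            except KeyError:
                rows.append(
                    {
                        "subject": subject,
                        "subprocess": name,
                        "cost_ms": np.nan,
                        "ratio": np.nan,
                        "excluded": True,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# difference potentials


@dataclass
class DifferencePotential:
    """Sample-wise signed combination of condition evokeds."""

    subject_id: str
    subprocess: str
    data: np.ndarray  # channels x samples
    times: np.ndarray
    channel_labels: tuple[str, ...]


def difference_potentials(
    evokeds: Mapping[ConditionLabel, Evoked],
    contrasts: Mapping[str, SubprocessContrast] | None = None,
) -> dict[str, DifferencePotential]:
    """Apply the subprocess contrasts to a subject's condition evokeds."""
    if contrasts is None:
        contrasts = standard_contrasts()
    out: dict[str, DifferencePotential] = {}
    any_ev = next(iter(evokeds.values()))
    for name, contrast in contrasts.items():
        missing = [c for c in contrast.weights if c not in evokeds]
        if missing:
            raise KeyError(
                f"{name}: missing evoked condition(s) "
                + ", ".join(str(m) for m in missing)
            )
        data = np.zeros_like(any_ev.data, dtype=float)
        for cond, w in contrast.weights.items():
            data += w * evokeds[cond].data
        out[name] = DifferencePotential(
            subject_id=any_ev.subject_id,
            subprocess=name,
            data=data,
            times=any_ev.times,
            channel_labels=any_ev.channel_labels,
        )
    return out


def window_mean(
    diff: DifferencePotential,
    window: tuple[float, float],
    electrodes: Sequence[str],
) -> pd.Series:
    """Mean amplitude over [start, end) ms per electrode (microvolts)."""
    start, end = window
    mask = (diff.times >= start) & (diff.times < end)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    idx = []
    for e in electrodes:
        if e not in diff.channel_labels:
            raise KeyError(f"electrode {e!r} not in {diff.channel_labels}")
        idx.append(diff.channel_labels.index(e))
    vals = diff.data[idx][:, mask].mean(axis=1)
    return pd.Series(vals, index=list(electrodes), name=f"{start:g}-{end:g}ms")
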