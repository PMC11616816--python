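"""Reference-cohort summary statistics.

Group-level condition mean reaction times (ms, with SDs) reported for a
younger (n = 24) and an older (n = 23) adult cohort performing the
reference-back task.  These printed cell means are the input for the
group-level subprocess-cost arithmetic: the raw single-trial recordings
behind them are not public, but the cost and ratio estimators are pure
functions of these eight cell means per group.
"""

from __future__ import annotations

import pandas as pd

from .task_design import ConditionLabel

__all__ = [
    "YOUNGER_N",
    "OLDER_N",
    "reference_cohort_rt_means",
    "rt_cell_means",
]

YOUNGER_N = 24
OLDER_N = 23

_ROWS = [
    # trial_type, gate_switch, response, younger mean (sd), older mean (sd)
    ("reference", "no_switch", "same", 476.76, 91.22, 577.61, 113.75),
    ("reference", "no_switch", "different", 591.57, 109.49, 775.32, 148.79),
    ("reference", "switch", "same", 508.87, 125.89, 616.38, 128.51),
    ("reference", "switch", "different", 625.23, 147.91, 846.95, 170.70),
    ("comparison", "no_switch", "same", 451.32, 82.91, 578.25, 106.35),
    ("comparison", "no_switch", "different", 510.72, 83.95, 652.72, 114.83),
    ("comparison", "switch", "same", 526.05, 120.78, 613.73, 122.36),
    ("comparison", "switch", "different", 620.00, 157.48, 742.30, 140.36),
]


def reference_cohort_rt_means() -> pd.DataFrame:
    """Condition mean RTs (ms) per age group, long format."""
    rows = []
    for tt, gs, resp, ym, ysd, om, osd in _ROWS:
        rows.append(
            {
                "group": "younger",
                "trial_type": tt,
                "gate_switch": gs,
                "response": resp,
                "mean_rt_ms": ym,
                "sd_ms": ysd,
                "n": YOUNGER_N,
            }
        )
        rows.append(
            {
                "group": "older",
                "trial_type": tt,
                "gate_switch": gs,
                "response": resp,
                "mean_rt_ms": om,
                "sd_ms": osd,
                "n": OLDER_N,
            }
        )
    return pd.DataFrame(rows)


def rt_cell_means(group: str) -> dict[ConditionLabel, float]:
    """The 8 condition cell means of one group as a label -> ms mapping."""
    df = reference_cohort_rt_means()
    sub = df[df["group"] == group]
    if sub.empty:
        raise KeyError(f"unknown group {group!r}")
    return {
        ConditionLabel(r.trial_type, r.gate_switch, r.response): float(r.mean_rt_ms)
        for r in sub.itertuples(index=False)
    }
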