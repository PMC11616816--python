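"""Study orchestration: simulate -> preprocess -> decompose -> test.

`run_study` executes the whole pipeline for a two-group cohort and
returns a bundle of report tables shaped like the standard reporting of a
reference-back ageing study: condition mean RTs per group, window mean
amplitudes, behavioural subprocess statistics (presence, group
difference, effect-size comparison) and window ANOVA results, plus the
tmax permutation maps and, optionally, synthetic-lead-field source
contrasts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import (
    SUBPROCESSES,
    condition_cell_means,
    costs_from_cell_means,
    difference_potentials,
    rt_costs,
    window_mean,
)
from .inference import (
    bf_inclusion_approx,
    jzs_bf_ttest,
    mann_whitney,
    mixed_anova,
    tmax_test,
)
from .preprocessing import FilterSpec, TooFewEpochsError, preprocess_subject
from .simulate import (
    DEFAULT_CHANNELS,
    MIDLINE_CHANNELS,
    BehaviourParams,
    ErpTemplate,
    default_erp_template,
    simulate_behaviour,
    simulate_epochs,
)
from .sources import compare_group_sources, make_synthetic_leadfield, sloreta_inverse
from .task_design import (
    COMPARISON,
    DIFFERENT,
    NO_SWITCH,
    REFERENCE,
    SAME,
    SWITCH,
    ConditionLabel,
    SessionDesign,
    generate_session,
)

__all__ = ["StudyConfig", "ReportBundle", "run_study", "accuracy_summary",
           "DEFAULT_WINDOWS"]

#: analysis windows (ms) per subprocess
DEFAULT_WINDOWS: dict[str, list[tuple[float, float]]] = {
    "updating": [(80, 180), (300, 400), (400, 1000)],
    "substitution": [(250, 600), (550, 750)],
    "gate_opening": [(150, 250), (300, 500), (500, 700)],
    "gate_closing": [(150, 300), (300, 600)],
}


def _default_behaviour_younger() -> BehaviourParams:
    return BehaviourParams(
        base_rt=455.0,
        age_slowing=0.0,
        cost_updating=48.7,
        cost_substitution=55.4,
        cost_gate_opening=30.4,
        cost_gate_closing=91.8,
        p_incorrect=0.11,
        p_miss=0.031,
    )


def _default_behaviour_older() -> BehaviourParams:
    return BehaviourParams(
        base_rt=455.0,
        age_slowing=130.0,
        cost_updating=44.3,
        cost_substitution=123.2,
        cost_gate_opening=42.5,
        cost_gate_closing=62.9,
        p_incorrect=0.141,
        p_miss=0.05,
    )


@dataclass
class StudyConfig:
    """Full configuration of a simulated two-group study."""

    n_younger: int = 24
    n_older: int = 23
    design: SessionDesign = field(default_factory=SessionDesign)
    behaviour_younger: BehaviourParams = field(
        default_factory=_default_behaviour_younger
    )
    behaviour_older: BehaviourParams = field(default_factory=_default_behaviour_older)
    erp_younger: ErpTemplate = field(default_factory=default_erp_template)
    erp_older: ErpTemplate = field(
        default_factory=lambda: default_erp_template(late_updating_amplitude=-0.9)
    )
    windows: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_WINDOWS.items()}
    )
    n_perm: int = 10_000
    alpha: float = 0.05
    prior_scale: float = 0.707
    base_rt_between_sd: float = 40.0
    erp_amplitude_between_sd: float = 0.3
    reject_threshold: float = 100.0
    lowpass: FilterSpec = field(default_factory=FilterSpec)
    n_sources: int = 60
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_younger, self.n_older) < 2:
            raise ValueError("cohort sizes must be >= 2")
        self.design.validate()
        self.behaviour_younger.validate()
        self.behaviour_older.validate()
        from .simulate import default_times

        times = default_times()
        for name, wins in self.windows.items():
            for lo, hi in wins:
                if lo < times[0] or hi > times[-1] + 1:
                    raise ValueError(f"window {lo}-{hi} for {name} outside epoch")

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


@dataclass
class ReportBundle:
    rt_table: pd.DataFrame
    accuracy: pd.DataFrame
    costs: pd.DataFrame
    behav_stats: pd.DataFrame
    amplitude_table: pd.DataFrame | None
    erp_stats: pd.DataFrame | None
    tmax_summary: pd.DataFrame | None
    source_contrasts: pd.DataFrame | None
    provenance: dict

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.rt_table.to_csv(out / "rt_table.csv", index=False)
        self.accuracy.to_csv(out / "accuracy.csv", index=False)
        self.costs.to_csv(out / "costs.csv", index=False)
        self.behav_stats.to_csv(out / "behavioural_stats.csv", index=False)
        if self.amplitude_table is not None:
            self.amplitude_table.to_csv(out / "amplitude_table.csv", index=False)
        if self.erp_stats is not None:
            self.erp_stats.to_csv(out / "erp_stats.csv", index=False)
        if self.tmax_summary is not None:
            self.tmax_summary.to_csv(out / "tmax_summary.csv", index=False)
        if self.source_contrasts is not None:
            self.source_contrasts.to_csv(out / "source_contrasts.csv", index=False)
        with open(out / "provenance.json", "w") as f:
            json.dump(self.provenance, f, indent=2, default=str)


# ---------------------------------------------------------------------------
# behavioural report pieces


def accuracy_summary(
    behaviour_by_group: Mapping[str, Mapping[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Overall accuracy, incorrect and miss percentages per group.

    The three rates partition all trials: accuracy + incorrect + miss = 100.
    """
    rows = []
    for group, subjects in behaviour_by_group.items():
        per_subj = []
        for subject, beh in subjects.items():
            n = len(beh)
            miss = beh["missed"].sum() / n
            correct = beh["correct"].sum() / n
            per_subj.append((correct, 1.0 - correct - miss, miss))
        arr = np.array(per_subj)
        rows.append(
            {
                "group": group,
                "n_subjects": len(subjects),
                "accuracy_pct": 100 * arr[:, 0].mean(),
                "incorrect_pct": 100 * arr[:, 1].mean(),
                "miss_pct": 100 * arr[:, 2].mean(),
            }
        )
    return pd.DataFrame(rows)


_COLLAPSED_CELLS = {
    "updating": [(REFERENCE, NO_SWITCH), (COMPARISON, NO_SWITCH)],
    "gate_opening": [(REFERENCE, SWITCH), (REFERENCE, NO_SWITCH)],
    "gate_closing": [(COMPARISON, SWITCH), (COMPARISON, NO_SWITCH)],
}


def _behav_long_table(
    cell_means_by_subject: Mapping[str, dict[ConditionLabel, float]],
    group_of: Mapping[str, str],
    subprocess: str,
) -> pd.DataFrame:
    """Per-subject two-level within table whose main effect tests the
    subprocess: the two collapsed condition means, or for substitution the
    two halves of the trial-type x response interaction contrast."""
    rows = []
    for subject, means in cell_means_by_subject.items():
        try:
            if subprocess == "substitution":
                dr = means[ConditionLabel(REFERENCE, NO_SWITCH, DIFFERENT)]
                sr = means[ConditionLabel(REFERENCE, NO_SWITCH, SAME)]
                dc = means[ConditionLabel(COMPARISON, NO_SWITCH, DIFFERENT)]
                sc = means[ConditionLabel(COMPARISON, NO_SWITCH, SAME)]
                levels = {"interaction_plus": (dr + sc) / 2, "interaction_minus": (sr + dc) / 2}
            else:
                levels = {}
                for i, (tt, gs) in enumerate(_COLLAPSED_CELLS[subprocess]):
                    pair = [
                        means[ConditionLabel(tt, gs, SAME)],
                        means[ConditionLabel(tt, gs, DIFFERENT)],
                    ]
                    levels[f"level_{i}"] = float(np.mean(pair))
        except KeyError:
            continue  # subject lacks a cell for this effect
        for lev, val in levels.items():
            rows.append(
                {
                    "subject": subject,
                    "group": group_of[subject],
                    "condition": lev,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def behavioural_stats(
    behaviour_by_group: Mapping[str, Mapping[str, pd.DataFrame]],
    prior_scale: float = 0.707,
    include_bf_incl: bool = True,
    group_order: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subprocess presence / group-difference statistics plus per-subject
    costs, from raw behaviour tables.

    Returns (stats table, per-subject costs table).  The stats table has
    one block per subprocess: the within-condition main effect (presence
    of the effect), the between-group main effect, their interaction
    (difference in the effect), and nonparametric / Bayesian comparisons
    of the per-subject cost and ratio between groups.
    """
    group_of: dict[str, str] = {}
    all_beh: dict[str, pd.DataFrame] = {}
    cm_by_subject: dict[str, dict[ConditionLabel, float]] = {}
    for group, subjects in behaviour_by_group.items():
        for subject, beh in subjects.items():
            key = f"{group}:{subject}"
            group_of[key] = group
            all_beh[key] = beh
            cm_by_subject[key] = condition_cell_means(beh)

    costs = rt_costs(all_beh)
    costs["group"] = costs["subject"].map(group_of)

    rows = []
    for name in SUBPROCESSES:
        long = _behav_long_table(cm_by_subject, group_of, name)
        anova = mixed_anova(
            long, dv="value", within="condition", between="group", subject="subject"
        )
        bf = (
            bf_inclusion_approx(
                long, dv="value", within="condition", between="group",
                subject="subject",
            )
            if include_bf_incl
            else {}
        )
        sub = costs[(costs["subprocess"] == name) & ~costs["excluded"]]
        by_group = {g: grp for g, grp in sub.groupby("group")}
        # group differences are reported as second-listed minus first-listed
        groups = (
            [g for g in group_order if g in by_group]
            if group_order is not None
            else sorted(by_group)
        )
        cost_means = {g: by_group[g]["cost_ms"].mean() for g in groups}
        n_by_group = {g: len(by_group[g]) for g in groups}
        total_n = sum(n_by_group.values())
        weighted_cost = (
            sum(n_by_group[g] * cost_means[g] for g in groups) / total_n
        )
        # substitution's derived-factor difference is half the full
        # interaction contrast; report the cost scale everywhere
        for _, r in anova.iterrows():
            effect = str(r["effect"])
            if effect == "condition":
                label, ms = "presence", weighted_cost
            elif effect == "group":
                label, ms = "group_main", np.nan
            else:
                label = "group_x_condition"
                ms = cost_means[groups[1]] - cost_means[groups[0]] if len(groups) == 2 else np.nan
            rows.append(
                {
                    "subprocess": name,
                    "effect": label,
                    "ms": ms,
                    "F": r["F"],
                    "df1": r["df1"],
                    "df2": r["df2"],
                    "p": r["p_gg"] if effect != "group" else r["p"],
                    "partial_eta_sq": r["partial_eta_sq"],
                    "bf_incl": bf.get(
                        {"condition": "condition", "group": "group"}.get(
                            effect, "group * condition"
                        ),
                        np.nan,
                    ),
                    "U": np.nan,
                    "rank_biserial": np.nan,
                    "bf10": np.nan,
                }
            )
        if len(groups) == 2:
            for measure in ("cost_ms", "ratio"):
                a = by_group[groups[0]][measure].to_numpy()
                b = by_group[groups[1]][measure].to_numpy()
                mw = mann_whitney(b, a)
                bf10 = jzs_bf_ttest(b, a, prior_scale=prior_scale).bf10
                rows.append(
                    {
                        "subprocess": name,
                        "effect": f"group_size_of_effect_{measure}",
                        "ms": float(np.mean(b) - np.mean(a)),
                        "F": np.nan,
                        "df1": np.nan,
                        "df2": np.nan,
                        "p": mw.p,
                        "partial_eta_sq": np.nan,
                        "bf_incl": np.nan,
                        "U": mw.U,
                        "rank_biserial": mw.rank_biserial,
                        "bf10": bf10,
                    }
                )
    return pd.DataFrame(rows), costs


def _rt_table(
    behaviour_by_group: Mapping[str, Mapping[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Condition mean (SD over subjects) RT table per group."""
    rows = []
    for group, subjects in behaviour_by_group.items():
        per_subject = {
            s: condition_cell_means(beh) for s, beh in subjects.items()
        }
        conditions = sorted(
            {c for m in per_subject.values() for c in m}, key=str
        )
        for cond in conditions:
            vals = [m[cond] for m in per_subject.values() if cond in m]
            rows.append(
                {
                    "group": group,
                    "trial_type": cond.trial_type,
                    "gate_switch": cond.gate_switch,
                    "response": cond.response,
                    "mean_rt_ms": float(np.mean(vals)),
                    "sd_ms": float(np.std(vals, ddof=1)),
                    "n_subjects": len(vals),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full study


def run_study(
    config: StudyConfig,
    include_erp: bool = True,
    include_sources: bool = True,
    include_bf_incl: bool = True,
) -> ReportBundle:
    """Execute the full pipeline.  Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    cohorts = {
        "younger": (config.n_younger, config.behaviour_younger, config.erp_younger),
        "older": (config.n_older, config.behaviour_older, config.erp_older),
    }

    behaviour_by_group: dict[str, dict[str, pd.DataFrame]] = {}
    diff_waves: dict[tuple[str, str], list[np.ndarray]] = {}
    window_amps: list[dict] = []
    excluded_subjects: list[str] = []
    times = channel_labels = None

    for group, (n_subj, beh_params, erp_template) in cohorts.items():
        behaviour_by_group[group] = {}
        for s in range(n_subj):
            subject = f"{group}-{s + 1:03d}"
            base = max(
                float(rng.normal(beh_params.base_rt, config.base_rt_between_sd)),
                200.0,
            )
            subj_params = replace(beh_params, base_rt=base)
            sess = generate_session(
                replace(config.design, seed=int(rng.integers(2**31 - 1)))
            )
            beh = simulate_behaviour(sess, subj_params, int(rng.integers(2**31 - 1)))
            beh.attrs["subject_id"] = subject
            behaviour_by_group[group][subject] = beh

            if not include_erp:
                continue
            amp_scale = max(
                float(rng.normal(1.0, config.erp_amplitude_between_sd)), 0.1
            )
            template = dataclasses.replace(erp_template)
            template.components = [
                dataclasses.replace(c, amplitude=c.amplitude * amp_scale)
                for c in erp_template.components
            ]
            epochs = simulate_epochs(
                sess, template, beh, seed=int(rng.integers(2**31 - 1))
            )
            try:
                evokeds, _ = preprocess_subject(
                    epochs,
                    lowpass=config.lowpass,
                    reject_threshold=config.reject_threshold,
                )
            except TooFewEpochsError:
                excluded_subjects.append(subject)
                continue
            diffs = difference_potentials(evokeds)
            for name, dp in diffs.items():
                diff_waves.setdefault((group, name), []).append(dp.data)
                times = dp.times
                channel_labels = dp.channel_labels
                for window in config.windows[name]:
                    amps = window_mean(dp, tuple(window), MIDLINE_CHANNELS)
                    for electrode, amp in amps.items():
                        window_amps.append(
                            {
                                "group": group,
                                "subject": subject,
                                "subprocess": name,
                                "window": f"{window[0]:g}-{window[1]:g}",
                                "electrode": electrode,
                                "amplitude_uv": float(amp),
                            }
                        )

    behav_stats, costs = behavioural_stats(
        behaviour_by_group,
        prior_scale=config.prior_scale,
        include_bf_incl=include_bf_incl,
        group_order=("younger", "older"),
    )
    rt_table = _rt_table(behaviour_by_group)
    accuracy = accuracy_summary(behaviour_by_group)

    amplitude_table = erp_stats = tmax_summary = source_contrasts = None
    if include_erp and window_amps:
        amp_df = pd.DataFrame(window_amps)
        amplitude_table = (
            amp_df.groupby(["group", "subprocess", "window", "electrode"])
            ["amplitude_uv"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

        # window ANOVAs: AGE x ANTERIORITY per subprocess and window
        erp_rows = []
        for (name, window), sub in amp_df.groupby(["subprocess", "window"]):
            table = sub.rename(columns={"amplitude_uv": "value"})
            anova = mixed_anova(
                table, dv="value", within="electrode", between="group",
                subject="subject",
            )
            bf = (
                bf_inclusion_approx(
                    table, dv="value", within="electrode", between="group",
                    subject="subject",
                )
                if include_bf_incl
                else {}
            )
            for _, r in anova.iterrows():
                erp_rows.append(
                    {
                        "subprocess": name,
                        "window": window,
                        "effect": r["effect"],
                        "F": r["F"],
                        "df1": r["df1"],
                        "df2": r["df2"],
                        "p": r["p"],
                        "p_gg": r["p_gg"],
                        "gg_epsilon": r["gg_epsilon"],
                        "partial_eta_sq": r["partial_eta_sq"],
                        "bf_incl": bf.get(str(r["effect"]), np.nan),
                    }
                )
        erp_stats = pd.DataFrame(erp_rows)

        # within-group tmax permutation tests on the post-stimulus samples
        tmax_rows = []
        post = times >= 0
        for (group, name), waves in sorted(diff_waves.items()):
            stack = np.stack(waves)[:, :, post]
            res = tmax_test(
                stack,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=int(rng.integers(2**31 - 1)),
            )
            tmax_rows.append(
                {
                    "group": group,
                    "subprocess": name,
                    "n_subjects": stack.shape[0],
                    "n_significant_points": int(res.significant_mask.sum()),
                    "n_clusters": len(res.clusters()),
                    "critical_t": res.critical_value,
                    "min_p": float(np.nanmin(res.p_map)),
                }
            )
        tmax_summary = pd.DataFrame(tmax_rows)

        if include_sources and channel_labels is not None:
            lf = make_synthetic_leadfield(
                len(channel_labels), config.n_sources,
                seed=int(rng.integers(2**31 - 1)),
            )
            lam = 1e-4 * np.trace(lf.matrix @ lf.matrix.T) / lf.n_channels
            src_rows = []
            for name in SUBPROCESSES:
                window = config.windows[name][-1]
                wmask = (times >= window[0]) & (times < window[1])
                powers = {}
                for group in cohorts:
                    waves = diff_waves.get((group, name), [])
                    powers[group] = np.array(
                        [
                            sloreta_inverse(
                                lf, w[:, wmask].mean(axis=1), lam=lam
                            ).power
                            for w in waves
                        ]
                    )
                cmp_df = compare_group_sources(
                    powers["younger"],
                    powers["older"],
                    seed=int(rng.integers(2**31 - 1)),
                )
                cmp_df.insert(0, "subprocess", name)
                cmp_df.insert(1, "window", f"{window[0]:g}-{window[1]:g}")
                src_rows.append(cmp_df)
            source_contrasts = pd.concat(src_rows, ignore_index=True)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "excluded_subjects": excluded_subjects,
    }
    return ReportBundle(
        rt_table=rt_table,
        accuracy=accuracy,
        costs=costs,
        behav_stats=behav_stats,
        amplitude_table=amplitude_table,
        erp_stats=erp_stats,
        tmax_summary=tmax_summary,
        source_contrasts=source_contrasts,
        provenance=provenance,
    )
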