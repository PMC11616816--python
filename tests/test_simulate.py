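"""Synthetic behaviour and epoch generators."""

import numpy as np
import pytest

from refback.decomposition import difference_potentials
from refback.preprocessing import average_conditions, reject_artifacts
from refback.simulate import (
    BehaviourParams,
    EpochSet,
    ErpComponent,
    ErpTemplate,
    channel_weights,
    default_erp_template,
    default_times,
    simulate_behaviour,
    simulate_epochs,
)
from refback.task_design import (
    ALL_LABELS,
    REFERENCE,
    ConditionLabel,
    SessionDesign,
    generate_session,
)


def _noise_free(costs=False):
    kw = dict(rt_sd=0.0, p_incorrect=0.0, p_miss=0.0)
    if not costs:
        kw.update(
            cost_updating=0.0,
            cost_substitution=0.0,
            cost_gate_opening=0.0,
            cost_gate_closing=0.0,
        )
    return BehaviourParams(base_rt=400.0, age_slowing=50.0, **kw)


def test_zero_noise_zero_cost_rt_is_base_plus_slowing(small_session):
    beh = simulate_behaviour(small_session, _noise_free(), seed=0)
    assert (beh.loc[beh["correct"], "rt_ms"] == 450.0).all()
    assert beh["correct"].all()
    assert not beh["missed"].any()


def test_latent_means_follow_condition_costs(small_session):
    params = _noise_free(costs=True)
    params = BehaviourParams(
        base_rt=400.0, age_slowing=0.0, rt_sd=0.0, p_incorrect=0.0, p_miss=0.0,
        cost_updating=40.0, cost_substitution=80.0,
        cost_gate_opening=30.0, cost_gate_closing=60.0,
    )
    beh = simulate_behaviour(small_session, params, seed=0)
    for row in beh.itertuples():
        if row.label == "n/a":
            continue
        lab = ConditionLabel.parse(row.label)
        expect = 400.0
        if lab.trial_type == REFERENCE:
            expect += 40.0
            expect += 40.0 if lab.response == "different" else -40.0
            if lab.gate_switch == "switch":
                expect += 30.0
        elif lab.gate_switch == "switch":
            expect += 60.0
        assert row.rt_ms == pytest.approx(expect)


def test_sub_150ms_base_rt_rejected(small_session):
    with pytest.raises(ValueError, match="150"):
        simulate_behaviour(small_session, BehaviourParams(base_rt=140.0), seed=0)


def test_shifted_lognormal_mean_is_unbiased(small_session):
    params = BehaviourParams(
        base_rt=450.0, rt_sd=0.35, p_incorrect=0.0, p_miss=0.0,
        cost_updating=0.0, cost_substitution=0.0,
        cost_gate_opening=0.0, cost_gate_closing=0.0,
    )
    rts = []
    for seed in range(40):
        beh = simulate_behaviour(small_session, params, seed=seed)
        rts.append(beh["rt_ms"].dropna().to_numpy())
    rts = np.concatenate(rts)
    assert rts.mean() == pytest.approx(450.0, abs=3 * rts.std() / np.sqrt(len(rts)))
    assert (rts > 150.0).all()


def test_miss_rate_recovered(small_session):
    params = BehaviourParams(p_miss=0.05, p_incorrect=0.0)
    missed = []
    for seed in range(30):
        beh = simulate_behaviour(small_session, params, seed=seed)
        missed.append(beh["missed"].mean())
    n = 30 * len(small_session)
    se = np.sqrt(0.05 * 0.95 / n)
    assert np.mean(missed) == pytest.approx(0.05, abs=3 * se + 1e-3)


def test_rt_beyond_deadline_becomes_miss(small_session):
    # enormous spread pushes a fraction of draws over the ~1,900 ms deadline
    params = BehaviourParams(base_rt=1500.0, rt_sd=1.0, p_incorrect=0.0, p_miss=0.0,
                             cost_updating=0.0, cost_substitution=0.0,
                             cost_gate_opening=0.0, cost_gate_closing=0.0)
    beh = simulate_behaviour(small_session, params, seed=0)
    assert beh["missed"].any()
    dead = np.array([t.response_deadline for t in small_session])
    responded = ~beh["missed"].to_numpy()
    assert (beh.loc[responded, "rt_ms"].to_numpy() <= dead[responded]).all()


# ---------------------------------------------------------------------------
# epochs


def test_epoch_geometry(small_session):
    beh = simulate_behaviour(small_session, _noise_free(), seed=0)
    tmpl = default_erp_template()
    ep = simulate_epochs(small_session, tmpl, beh, seed=1)
    assert ep.data.shape == (len(small_session), 12, 1101)
    assert ep.times[0] == -100.0 and ep.times[-1] == 1000.0
    assert ep.times.size == 1101
    np.testing.assert_allclose(np.diff(ep.times), 1.0)


def test_noiseless_single_component_reproduced_in_updating_wave(small_session):
    """A component loaded only on no-switch reference trials appears exactly
    in the updating difference wave; the other three waves stay zero."""
    tmpl = default_erp_template()
    times = default_times()
    comp = ErpComponent(
        label="probe",
        latency=300.0,
        width=50.0,
        amplitude=2.0,
        channel_weights=channel_weights(tmpl.channels, "Oz"),
        condition_weights={
            lab: 1.0
            for lab in ALL_LABELS
            if lab.trial_type == REFERENCE and lab.gate_switch == "no_switch"
        },
    )
    tmpl = ErpTemplate(components=[comp], noise_sd=0.0, artifact_rate=0.0)
    beh = simulate_behaviour(small_session, _noise_free(), seed=0)
    ep = simulate_epochs(small_session, tmpl, beh, seed=0)
    diffs = difference_potentials(average_conditions(ep))
    expected = np.outer(comp.channel_weights, comp.waveform(times))
    np.testing.assert_allclose(diffs["updating"].data, expected, atol=1e-12)
    for name in ("substitution", "gate_closing"):
        np.testing.assert_allclose(diffs[name].data, 0.0, atol=1e-12)
    # gate opening subtracts the component entirely (it loads on the
    # no-switch side only), giving minus the waveform
    np.testing.assert_allclose(diffs["gate_opening"].data, -expected, atol=1e-12)


def test_artifact_rate_drives_rejection_fraction():
    design = SessionDesign(n_blocks=3, seed=2)
    trials = generate_session(design)
    beh = simulate_behaviour(trials, _noise_free(), seed=0)
    tmpl = ErpTemplate(components=[], noise_sd=1.0, artifact_rate=0.1,
                       artifact_amplitude=200.0)
    ep = simulate_epochs(trials, tmpl, beh, seed=3)
    _, rejected = reject_artifacts(ep, threshold=100.0)
    n = len(trials)
    se = np.sqrt(0.1 * 0.9 / n)
    assert rejected.mean() == pytest.approx(0.1, abs=3 * se)


def test_trialwise_independence_under_shuffling(small_session):
    """Epoch content is tied to trial identity, not presentation order."""
    beh = simulate_behaviour(small_session, _noise_free(), seed=0)
    tmpl = default_erp_template()
    tmpl.noise_sd = 2.0
    ep = simulate_epochs(small_session, tmpl, beh, seed=9)
    perm = np.random.default_rng(0).permutation(len(small_session))
    shuffled_trials = [small_session[i] for i in perm]
    beh_shuffled = beh.iloc[perm].reset_index(drop=True)
    ep_shuffled = simulate_epochs(shuffled_trials, tmpl, beh_shuffled, seed=9)
    unshuffled = np.empty_like(ep.data)
    unshuffled[perm] = ep_shuffled.data
    np.testing.assert_array_equal(unshuffled, ep.data)


def test_window_anova_detects_simulated_group_amplitude_difference():
    """Two cohorts generated with different late occipital amplitudes show
    the group x anteriority interaction in the window ANOVA with power
    above .8 at the simulated effect size (a 3 uV Oz difference; Monte
    Carlo over 16 replicate two-group cohorts at reduced sampling rate)."""
    import pandas as pd

    from refback.decomposition import difference_potentials, window_mean
    from refback.inference import mixed_anova
    from refback.preprocessing import preprocess_subject
    from refback.simulate import MIDLINE_CHANNELS

    def cohort(n, amp, seed, group):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            sess = generate_session(
                SessionDesign(n_blocks=3, seed=int(rng.integers(2**31 - 1)))
            )
            beh = simulate_behaviour(
                sess, BehaviourParams(), int(rng.integers(2**31 - 1))
            )
            scale = max(float(rng.normal(1.0, 0.3)), 0.1)
            tmpl = default_erp_template(
                MIDLINE_CHANNELS, late_updating_amplitude=amp * scale
            )
            ep = simulate_epochs(
                sess, tmpl, beh, seed=int(rng.integers(2**31 - 1)), sfreq=250.0
            )
            evokeds, _ = preprocess_subject(ep)
            dp = difference_potentials(evokeds)["updating"]
            for e, v in window_mean(dp, (400, 1000), MIDLINE_CHANNELS).items():
                rows.append(
                    dict(group=group, subject=f"{group}{seed}_{s}",
                         electrode=e, value=v)
                )
        return pd.DataFrame(rows)

    hits, n_rep = 0, 16
    for rep in range(n_rep):
        df = pd.concat(
            [cohort(12, -3.0, 100 + rep, "y"), cohort(12, 0.0, 500 + rep, "o")]
        )
        res = mixed_anova(df).set_index("effect")
        hits += int(res.loc["group * electrode", "p_gg"] < 0.05)
    assert hits / n_rep >= 0.8


def test_null_difference_waves_have_zero_expectation():
    """With noise but no components every subprocess difference wave has
    zero mean and the cohort tmax test rejects at no more than the
    nominal rate."""
    import pandas as pd

    from refback.decomposition import difference_potentials
    from refback.inference import tmax_test
    from refback.preprocessing import preprocess_subject
    from refback.simulate import MIDLINE_CHANNELS

    rng = np.random.default_rng(17)
    waves = []
    for s in range(10):
        sess = generate_session(
            SessionDesign(n_blocks=2, seed=int(rng.integers(2**31 - 1)))
        )
        beh = simulate_behaviour(sess, BehaviourParams(), int(rng.integers(2**31 - 1)))
        tmpl = ErpTemplate(channels=MIDLINE_CHANNELS, components=[],
                           noise_sd=8.0, artifact_rate=0.0)
        ep = simulate_epochs(sess, tmpl, beh,
                             seed=int(rng.integers(2**31 - 1)), sfreq=250.0)
        evokeds, _ = preprocess_subject(ep)
        waves.append(difference_potentials(evokeds)["updating"].data)
    res = tmax_test(np.stack(waves), n_perm=500, alpha=0.05, seed=0)
    assert not res.significant_mask.any()


def test_channel_weight_mismatch_raises(small_session):
    beh = simulate_behaviour(small_session, _noise_free(), seed=0)
    comp = ErpComponent("bad", 300, 50, 1.0, np.ones(5), {})
    tmpl = ErpTemplate(components=[comp])
    with pytest.raises(ValueError, match="channel_weights"):
        simulate_epochs(small_session, tmpl, beh, seed=0)


def test_epochset_validates_metadata():
    with pytest.raises(ValueError):
        EpochSet(
            subject_id="s",
            data=np.zeros((2, 3, 10)),
            sfreq=1000.0,
            times=np.arange(9.0),
            channel_labels=("a", "b", "c"),
            trial_labels=[None, None],
            correct=np.ones(2, dtype=bool),
        )
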