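"""Permutation tests, mixed ANOVA, Bayes factors, nonparametrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from refback.inference import (
    ZeroVarianceError,
    _orthonormal_contrasts,
    bf_inclusion_approx,
    bonferroni_posthoc,
    greenhouse_geisser_epsilon,
    jzs_bf_ttest,
    mann_whitney,
    mixed_anova,
    permutation_t_twosample,
    tmax_test,
)

# ---------------------------------------------------------------------------
# tmax permutation test


from .oracles import (
    brute_force_tmax_p as _brute_force_tmax_p,
    jzs_bf_one_sample_g_mixture as _oracle_jzs_one_sample,
    rss_mixed_anova as _oracle_mixed_anova,
    sample_with_t as _sample_with_t,
)


def test_tmax_small_family_matches_exhaustive_enumeration(rng):
    x = rng.normal(size=(8, 3, 5)) + 0.5
    res = tmax_test(x, n_perm=10_000, seed=0)
    assert res.exhaustive and res.n_permutations == 256
    t_exp, p_exp = _brute_force_tmax_p(x.reshape(8, -1))
    np.testing.assert_allclose(res.t_observed.ravel(), t_exp, rtol=1e-12)
    np.testing.assert_allclose(res.p_map.ravel(), p_exp, atol=1e-12)
    assert (res.significant_mask == (res.p_map <= 0.05)).all()


def test_tmax_agrees_with_mne_reference(rng):
    """Cross-check against the established tmax implementation; mne uses
    half the sign-flip group (exploiting symmetry), so corrected p-values
    agree only up to that discretisation."""
    from mne.stats import permutation_t_test

    x = rng.normal(size=(10, 4, 6)) + 0.4
    res = tmax_test(x, n_perm=10_000, seed=0)
    _, p_mne, _ = permutation_t_test(
        x.reshape(10, -1), n_permutations="all", tail=0, verbose=False
    )
    assert np.abs(res.p_map.ravel() - p_mne).max() < 0.01


def test_tmax_deterministic_given_seed(rng):
    x = rng.normal(size=(20, 2, 30))
    a = tmax_test(x, n_perm=500, seed=42)
    b = tmax_test(x, n_perm=500, seed=42)
    np.testing.assert_array_equal(a.p_map, b.p_map)
    np.testing.assert_array_equal(a.tmax_null, b.tmax_null)
    assert not a.exhaustive


def test_tmax_zero_variance_paths(rng):
    with pytest.raises(ZeroVarianceError):
        tmax_test(np.zeros((6, 2, 3)))
    # a single flat point is excluded from the family, the rest analysed
    x = rng.normal(size=(6, 2, 3))
    x[:, 0, 0] = 7.0
    res = tmax_test(x, n_perm=200, seed=1)
    assert res.excluded[0, 0]
    assert np.isnan(res.t_observed[0, 0])
    assert not res.significant_mask[0, 0]
    assert np.isfinite(res.t_observed[~res.excluded]).all()


def test_tmax_add_one_pvalues_valid(rng):
    x = rng.normal(size=(15, 2, 4))
    res = tmax_test(x, n_perm=199, seed=3)
    assert np.nanmin(res.p_map) >= 1.0 / 200.0
    assert np.nanmax(res.p_map) <= 1.0


def test_twosample_permutation_detects_shift(rng):
    a = rng.normal(1.5, 1.0, size=(15, 4))
    b = rng.normal(0.0, 1.0, size=(12, 4))
    t, p = permutation_t_twosample(a, b, n_perm=500, seed=0)
    assert (t > 0).all()
    assert (p < 0.05).all()


# ---------------------------------------------------------------------------
# mixed ANOVA


def _random_table(rng, n_a=10, n_b=9, k=4, interaction=0.0):
    rows = []
    for s in range(n_a + n_b):
        g = "a" if s < n_a else "b"
        base = rng.normal(0, 1)
        for lev in range(k):
            mu = 0.4 * lev + (0.8 if g == "b" else 0) + interaction * lev * (g == "b")
            rows.append(
                dict(subject=f"s{s}", group=g, electrode=f"e{lev}",
                     value=base + rng.normal(mu, 1))
            )
    return pd.DataFrame(rows)


@pytest.mark.parametrize("n_a,n_b", [(10, 10), (12, 9), (24, 23)])
def test_mixed_anova_matches_rss_oracle(rng, n_a, n_b):
    df = _random_table(rng, n_a=n_a, n_b=n_b, interaction=0.3)
    mine = mixed_anova(df).set_index("effect")
    oracle_f, oracle_eps = _oracle_mixed_anova(df)
    assert mine.loc["group", "F"] == pytest.approx(oracle_f["group"], rel=1e-8)
    assert mine.loc["electrode", "F"] == pytest.approx(
        oracle_f["electrode"], rel=1e-8
    )
    assert mine.loc["group * electrode", "F"] == pytest.approx(
        oracle_f["interaction"], rel=1e-8
    )
    assert mine.loc["electrode", "gg_epsilon"] == pytest.approx(
        oracle_eps, rel=1e-8
    )


def test_mixed_anova_agrees_with_pingouin_balanced(rng):
    import pingouin as pg

    df = _random_table(rng, n_a=12, n_b=12, interaction=0.2)
    mine = mixed_anova(df).set_index("effect")
    ref = pg.mixed_anova(
        df, dv="value", within="electrode", between="group", subject="subject"
    ).set_index("Source")
    for my_key, pg_key in [
        ("group", "group"), ("electrode", "electrode"),
        ("group * electrode", "Interaction"),
    ]:
        assert mine.loc[my_key, "F"] == pytest.approx(ref.loc[pg_key, "F"], rel=1e-9)
        assert mine.loc[my_key, "partial_eta_sq"] == pytest.approx(
            ref.loc[pg_key, "np2"], rel=1e-9
        )


def test_between_f_equals_oneway_on_subject_means(rng):
    df = _random_table(rng)
    mine = mixed_anova(df).set_index("effect")
    wide = df.pivot_table(index="subject", columns="electrode", values="value")
    groups = df.groupby("subject")["group"].first().loc[wide.index]
    means = wide.mean(axis=1)
    f_oneway = stats.f_oneway(
        means[groups == "a"].to_numpy(), means[groups == "b"].to_numpy()
    )
    assert mine.loc["group", "F"] == pytest.approx(f_oneway.statistic, rel=1e-10)
    assert mine.loc["group", "p"] == pytest.approx(f_oneway.pvalue, rel=1e-9)


def test_identical_groups_give_null_between_effect(rng):
    half = _random_table(rng, n_a=8, n_b=0)
    mirror = half.copy()
    mirror["group"] = "b"
    mirror["subject"] = mirror["subject"] + "_b"
    df = pd.concat([half, mirror], ignore_index=True)
    res = mixed_anova(df).set_index("effect")
    assert res.loc["group", "F"] == pytest.approx(0.0, abs=1e-18)
    assert res.loc["group", "p"] == pytest.approx(1.0)


def test_compound_symmetry_gives_epsilon_near_one(rng):
    # exchangeable correlation: equal variances, equal covariances
    k, n = 4, 400
    cov = 0.5 * np.ones((k, k)) + 0.5 * np.eye(k)
    y = rng.multivariate_normal(np.zeros(k), cov, size=n)
    rows = [
        dict(subject=f"s{s}", group="a" if s < n // 2 else "b",
             electrode=f"e{l}", value=y[s, l])
        for s in range(n) for l in range(k)
    ]
    res = mixed_anova(pd.DataFrame(rows)).set_index("effect")
    eps = res.loc["electrode", "gg_epsilon"]
    assert eps > 0.95
    assert 1.0 / 3.0 <= eps <= 1.0


def test_epsilon_bounds_for_four_levels(rng):
    for _ in range(20):
        cov = stats.wishart.rvs(6, np.eye(4), random_state=rng)
        eps = greenhouse_geisser_epsilon(cov)
        assert 1.0 / 3.0 - 1e-12 <= eps <= 1.0 + 1e-12


def test_gg_corrected_p_not_smaller_when_epsilon_below_one(rng):
    df = _random_table(rng, interaction=0.4)
    res = mixed_anova(df).set_index("effect")
    for eff in ("electrode", "group * electrode"):
        if res.loc[eff, "gg_epsilon"] < 1.0 and res.loc[eff, "F"] > 1.0:
            assert res.loc[eff, "p_gg"] >= res.loc[eff, "p"]


def test_unbalanced_within_raises():
    df = pd.DataFrame(
        dict(subject=["s1", "s1", "s2"], group=["a"] * 3,
             electrode=["e1", "e2", "e1"], value=[1.0, 2.0, 3.0])
    )
    with pytest.raises(ValueError, match="within"):
        mixed_anova(df)


# ---------------------------------------------------------------------------
# Bonferroni post-hocs


def test_bonferroni_single_comparison_unchanged():
    out = bonferroni_posthoc({"a": 1.0, "b": 2.0}, 10, ms_error=4.0, df_error=18)
    assert len(out) == 1
    assert out["p_bonferroni"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])


def test_bonferroni_four_levels_and_capping():
    means = {c: float(i) for i, c in enumerate("abcd")}
    out = bonferroni_posthoc(means, 5, ms_error=100.0, df_error=20)
    assert len(out) == 6  # C(4, 2)
    assert (out["p_bonferroni"] <= 1.0).all()
    weak = out[out["p_raw"] > 1.0 / 6.0]
    assert (weak["p_bonferroni"] == 1.0).all()
    strong = out[out["p_raw"] <= 1.0 / 6.0]
    np.testing.assert_allclose(
        strong["p_bonferroni"], 6.0 * strong["p_raw"]
    )


# ---------------------------------------------------------------------------
# JZS Bayes factor


def test_jzs_bf_matches_independent_quadrature_oracle(rng):
    """20 random (t, n) pairs agree with the g-mixture oracle to 4
    significant figures."""
    for _ in range(20):
        n = int(rng.integers(5, 60))
        t = float(rng.normal(0.0, 2.5))
        x = _sample_with_t(rng, t, n)
        mine = jzs_bf_ttest(x).bf10
        oracle = _oracle_jzs_one_sample(t, n)
        assert mine == pytest.approx(oracle, rel=5e-5), (t, n)


def test_bf_below_one_at_t_zero():
    for n in (5, 20, 100):
        x = _sample_with_t(np.random.default_rng(0), 0.0, n)
        assert jzs_bf_ttest(x).bf10 < 1.0


def test_bf_monotone_in_t(rng):
    n = 24
    ts = np.linspace(0.0, 6.0, 13)
    bfs = [jzs_bf_ttest(_sample_with_t(rng, t, n)).bf10 for t in ts]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))


def test_bf_paired_equals_one_sample_of_differences(rng):
    x = rng.normal(0.5, 1.0, 20)
    y = rng.normal(0.0, 1.0, 20)
    paired = jzs_bf_ttest(x, y, paired=True)
    direct = jzs_bf_ttest(x - y)
    assert paired.bf10 == pytest.approx(direct.bf10, rel=1e-12)


def test_bf_independent_matches_pingouin(rng):
    import pingouin as pg

    x = rng.normal(0.8, 1.0, 18)
    y = rng.normal(0.0, 1.0, 14)
    mine = jzs_bf_ttest(x, y)
    ref = float(
        pg.bayesfactor_ttest(mine.t, 18, 14, paired=False, r=0.707)
    )
    assert mine.bf10 == pytest.approx(ref, rel=1e-6)


def test_bf_zero_variance_raises():
    with pytest.raises(ZeroVarianceError):
        jzs_bf_ttest(np.ones(10))


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_complete_separation():
    res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0, 13.0])
    assert res.U == 0.0
    assert res.rank_biserial == -1.0
    res = mann_whitney([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
    assert res.U == 9.0
    assert res.rank_biserial == 1.0


def test_mann_whitney_identical_samples_zero_effect():
    x = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney(x, list(x))
    assert res.rank_biserial == pytest.approx(0.0)


def test_mann_whitney_exact_p_matches_enumeration(rng):
    """n1 = n2 = 6 tie-free data: the exact p equals enumeration over all
    C(12, 6) group assignments."""
    x = rng.normal(size=6)
    y = rng.normal(0.8, 1.0, size=6)
    res = mann_whitney(x, y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)

    def u_stat(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - 6 * 7 / 2

    u_obs = u_stat(range(6))
    us = np.array([u_stat(c) for c in itertools.combinations(range(12), 6)])
    mean_u = 6 * 6 / 2
    p_exact = np.mean(np.abs(us - mean_u) >= np.abs(u_obs - mean_u) - 1e-12)
    assert res.U == pytest.approx(u_obs)
    assert res.p == pytest.approx(p_exact, abs=1e-12)


def test_mann_whitney_u_range_invariant(rng):
    for _ in range(10):
        x = rng.normal(size=rng.integers(3, 20))
        y = rng.normal(size=rng.integers(3, 20))
        res = mann_whitney(x, y)
        assert 0 <= res.U <= len(x) * len(y)
        assert -1.0 <= res.rank_biserial <= 1.0


# ---------------------------------------------------------------------------
# inclusion Bayes factors


def _anova_table(rng, effect=0.0, n_per_group=12, k=4):
    rows = []
    for s in range(2 * n_per_group):
        g = "a" if s < n_per_group else "b"
        base = rng.normal(0, 0.5)
        for lev in range(k):
            rows.append(
                dict(subject=f"s{s}", group=g, electrode=f"e{lev}",
                     value=base + rng.normal(effect * lev * (g == "b"), 1))
            )
    return pd.DataFrame(rows)


def test_inclusion_bf_large_effect_strongly_supported(rng):
    df = _anova_table(rng, effect=1.5)
    bf = bf_inclusion_approx(df)
    assert bf["group * electrode"] > 3.0
    assert bf["electrode"] > 3.0


def test_inclusion_bf_null_data_favours_exclusion(rng):
    vals = []
    for _ in range(10):
        bf = bf_inclusion_approx(_anova_table(rng, effect=0.0))
        vals.append(bf["group * electrode"])
    assert np.median(vals) < 1.0
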