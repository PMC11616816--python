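"""Inferential machinery: tmax sign-flip permutation tests, split-plot
(mixed) ANOVA with Greenhouse-Geisser correction, Bonferroni post-hocs,
JZS Bayes-factor t-tests, Mann-Whitney U with rank-biserial correlation,
and BIC-approximated inclusion Bayes factors.

The tmax test controls the familywise error over an electrodes x samples
family by comparing each point's one-sample t-statistic against the
permutation distribution of the maximum |t| over the whole family, built
from random sign flips of the subject difference waves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

__all__ = [
    "PermutationResult",
    "BayesTTestResult",
    "NonparamResult",
    "ZeroVarianceError",
    "tmax_test",
    "mixed_anova",
    "greenhouse_geisser_epsilon",
    "bonferroni_posthoc",
    "jzs_bf_ttest",
    "mann_whitney",
    "bf_inclusion_approx",
    "permutation_t_twosample",
]


class ZeroVarianceError(ValueError):
    """All points in the family (or a required sample) have zero variance."""


# ---------------------------------------------------------------------------
# tmax sign-flip permutation test


@dataclass
class PermutationResult:
    t_observed: np.ndarray  # channels x samples (NaN at excluded points)
    tmax_null: np.ndarray  # length n_permutations
    critical_value: float
    p_map: np.ndarray  # corrected p-values, channels x samples
    significant_mask: np.ndarray  # p_map <= alpha (False at excluded points)
    excluded: np.ndarray  # zero-variance points dropped from the family
    n_permutations: int
    alpha: float
    exhaustive: bool
    tails: str = "two"

    def clusters(self) -> list[dict]:
        """Descriptive contiguous runs of significant samples per channel."""
        out = []
        for ch in range(self.significant_mask.shape[0]):
            row = self.significant_mask[ch]
            start = None
            for i, flag in enumerate(np.append(row, False)):
                if flag and start is None:
                    start = i
                elif not flag and start is not None:
                    out.append({"channel": ch, "start": start, "stop": i})
                    start = None
        return out


def _t_for_signs(signs: np.ndarray, x: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """One-sample t at every point for each sign pattern.

    ``signs``: (m, n) in {-1, +1}; ``x``: (n, P).  The per-point sum of
    squares is invariant under sign flips, so only the signed mean is
    recomputed: var = (sumsq - n*mean^2) / (n - 1).
    """
    n = x.shape[0]
    means = signs @ x / n
    var = (sumsq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    # var == 0 with mean == 0 -> 0/0; define as 0 (no evidence)
    t[~np.isfinite(t) & (means == 0)] = 0.0
    return t


def tmax_test(
    diffs: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """tmax-corrected one-sample test over a channels x samples family.

    ``diffs`` has shape (subjects, channels, samples); the null hypothesis
    of zero mean is exchangeable under sign flips of whole subjects.  When
    ``2**n_subjects <= n_perm`` the full sign-flip group is enumerated and
    p-values are exact (#{null >= |t|} / 2**n); otherwise ``n_perm``
    random flips are drawn and p = (1 + #{null >= |t|}) / (1 + n_perm).
    Points with zero variance across subjects are excluded from the
    family.  Two-tailed; deterministic given ``seed``.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim == 2:
        diffs = diffs[:, None, :]
    n, n_ch, n_samp = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(diffs)):
        raise ValueError("diffs must be finite")
    x = diffs.reshape(n, -1)
    var0 = x.var(axis=0, ddof=1)
    excluded_flat = var0 == 0
    if excluded_flat.all():
        raise ZeroVarianceError("every point has zero variance across subjects")
    xv = x[:, ~excluded_flat]
    sumsq = (xv**2).sum(axis=0)

    t_obs_valid = _t_for_signs(np.ones((1, n)), xv, sumsq)[0]

    exhaustive = 2**n <= n_perm
    if exhaustive:
        all_signs = np.array(
            list(itertools.product((-1.0, 1.0), repeat=n)), dtype=float
        )
        m = all_signs.shape[0]
        tmax_null = np.empty(m)
        for lo in range(0, m, 1024):
            chunk = all_signs[lo : lo + 1024]
            tmax_null[lo : lo + chunk.shape[0]] = np.abs(
                _t_for_signs(chunk, xv, sumsq)
            ).max(axis=1)
        counts = (tmax_null[None, :] >= np.abs(t_obs_valid)[:, None] - 1e-12).sum(
            axis=1
        )
        p_valid = counts / m
        n_used = m
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        tmax_null = np.empty(n_perm)
        chunk_size = max(1, int(4e6 // max(xv.shape[1], 1)))
        done = 0
        while done < n_perm:
            m = min(chunk_size, n_perm - done)
            signs = rng.integers(0, 2, size=(m, n)) * 2.0 - 1.0
            tmax_null[done : done + m] = np.abs(
                _t_for_signs(signs, xv, sumsq)
            ).max(axis=1)
            done += m
        sorted_null = np.sort(tmax_null)
        ge = n_perm - np.searchsorted(
            sorted_null, np.abs(t_obs_valid) - 1e-12, side="left"
        )
        p_valid = (1.0 + ge) / (1.0 + n_perm)
        n_used = n_perm

    t_observed = np.full(x.shape[1], np.nan)
    t_observed[~excluded_flat] = t_obs_valid
    p_map = np.full(x.shape[1], np.nan)
    p_map[~excluded_flat] = p_valid
    with np.errstate(invalid="ignore"):
        significant = p_map <= alpha
    significant[excluded_flat] = False

    return PermutationResult(
        t_observed=t_observed.reshape(n_ch, n_samp),
        tmax_null=tmax_null,
        critical_value=float(np.quantile(tmax_null, 1 - alpha)),
        p_map=p_map.reshape(n_ch, n_samp),
        significant_mask=significant.reshape(n_ch, n_samp),
        excluded=excluded_flat.reshape(n_ch, n_samp),
        n_permutations=n_used,
        alpha=alpha,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# split-plot (mixed) ANOVA with Greenhouse-Geisser correction


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (orthonormalised Helmert)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k repeated-measures covariance."""
    k = cov.shape[0]
    c = _orthonormal_contrasts(k)
    m = c @ cov @ c.T
    eps = np.trace(m) ** 2 / ((k - 1) * np.trace(m @ m))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "electrode",
    between: str = "group",
    subject: str = "subject",
) -> pd.DataFrame:
    """Classical split-plot ANOVA: one between- and one within-subject factor.

    Every subject must have exactly one observation at each within level.
    Returns one row per effect (between, within, interaction) with F, df,
    uncorrected p, Greenhouse-Geisser epsilon and corrected p for the
    within effects, and partial eta squared.  The between-subject F equals
    the one-way ANOVA F on subject means collapsed over the within factor.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced within factor: every subject needs all levels")
    groups = data.groupby(subject)[between].first().loc[wide.index]
    levels = list(wide.columns)
    k = len(levels)
    y = wide.to_numpy()  # subjects x levels
    n_total = y.shape[0]
    group_names = sorted(groups.unique())
    g_of = groups.to_numpy()
    n_g = {g: int((g_of == g).sum()) for g in group_names}
    G = len(group_names)
    if G < 2:
        raise ValueError("between factor needs at least 2 groups")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = {g: subj_means[g_of == g].mean() for g in group_names}
    level_means = y.mean(axis=0)
    cell_means = {g: y[g_of == g].mean(axis=0) for g in group_names}

    ss_a = k * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in group_names)
    ss_subj = k * sum(
        ((subj_means[g_of == g] - group_means[g]) ** 2).sum() for g in group_names
    )
    ss_b = n_total * ((level_means - grand) ** 2).sum()
    ss_ab = sum(
        n_g[g]
        * ((cell_means[g] - group_means[g] - level_means + grand) ** 2).sum()
        for g in group_names
    )
    resid = np.concatenate(
        [
            y[g_of == g]
            - subj_means[g_of == g][:, None]
            + group_means[g]
            - cell_means[g][None, :]
            for g in group_names
        ]
    )
    ss_err = (resid**2).sum()

    df_a, df_subj = G - 1, n_total - G
    df_b, df_ab = k - 1, (G - 1) * (k - 1)
    df_err = (n_total - G) * (k - 1)

    # pooled within-group covariance for the sphericity correction
    pooled = np.zeros((k, k))
    for g in group_names:
        yg = y[g_of == g]
        pooled += (n_g[g] - 1) * np.cov(yg, rowvar=False)
    pooled /= n_total - G
    eps = greenhouse_geisser_epsilon(pooled)

    def row(effect, ss, df1, df2, ss_error, within_effect):
        ms, ms_e = ss / df1, ss_error / df2
        F = ms / ms_e if ms_e > 0 else 0.0
        p = float(stats.f.sf(F, df1, df2))
        if within_effect:
            p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
            e = eps
        else:
            p_gg, e = p, np.nan
        return {
            "effect": effect,
            "SS": ss,
            "df1": df1,
            "df2": df2,
            "F": F,
            "p": p,
            "gg_epsilon": e,
            "p_gg": p_gg,
            "partial_eta_sq": ss / (ss + ss_error) if ss + ss_error > 0 else 0.0,
        }

    return pd.DataFrame(
        [
            row(between, ss_a, df_a, df_subj, ss_subj, False),
            row(within, ss_b, df_b, df_err, ss_err, True),
            row(f"{between} * {within}", ss_ab, df_ab, df_err, ss_err, True),
        ]
    )


def bonferroni_posthoc(
    cell_means: dict[str, float],
    n_per_cell: dict[str, int] | int,
    ms_error: float,
    df_error: float,
) -> pd.DataFrame:
    """Pairwise comparisons of cell means against a common error term,
    Bonferroni-adjusted over the m = C(k, 2) pairwise tests."""
    names = list(cell_means)
    if len(names) < 2:
        raise ValueError("need at least 2 cells")
    if isinstance(n_per_cell, int):
        n_per_cell = {c: n_per_cell for c in names}
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        nh = 2.0 / (1.0 / n_per_cell[a] + 1.0 / n_per_cell[b])
        se = np.sqrt(2.0 * ms_error / nh)
        t = (cell_means[a] - cell_means[b]) / se
        p_raw = 2.0 * float(stats.t.sf(abs(t), df_error))
        rows.append(
            {
                "a": a,
                "b": b,
                "t": t,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# JZS Bayes-factor t-test


@dataclass
class BayesTTestResult:
    bf10: float
    t: float
    n1: int
    n2: int | None
    df: float
    prior_scale: float


def _jzs_bf_from_t(t: float, n_eff: float, df: float, r: float) -> float:
    """BF10 by quadrature over the Cauchy prior on standardised effect size.

    BF10 = integral T_df(t; delta*sqrt(n_eff)) Cauchy(delta; 0, r) ddelta
           / T_df(t; 0).
    """

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * np.sqrt(n_eff)) * stats.cauchy.pdf(
            delta, scale=r
        )

    centre = t / np.sqrt(n_eff)
    # piecewise around the prior mode and the likelihood peak (quad cannot
    # take break points with infinite limits)
    cuts = sorted({0.0, centre})
    edges = [-np.inf, *cuts, np.inf]
    num = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        part, _ = integrate.quad(
            integrand, a, b, epsabs=1e-12, epsrel=1e-10, limit=400
        )
        num += part
    den = stats.t.pdf(t, df)
    return num / den


def jzs_bf_ttest(
    x: np.ndarray,
    y: np.ndarray | None = None,
    paired: bool = False,
    prior_scale: float = 0.707,
) -> BayesTTestResult:
    """Default-prior (JZS) Bayes factor for a two-tailed t-test.

    One-sample (``y`` None), paired, or independent-samples; the prior on
    the standardised effect size is Cauchy with scale ``prior_scale``.
    """
    x = np.asarray(x, dtype=float)
    if y is not None and paired:
        if len(y) != len(x):
            raise ValueError("paired samples must have equal length")
        x, y = x - np.asarray(y, dtype=float), None
    if y is None:
        n1, n2 = len(x), None
        if n1 < 2:
            raise ValueError("need n >= 2")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ZeroVarianceError("sample has zero variance")
        t = x.mean() / (sd / np.sqrt(n1))
        n_eff, df = float(n1), float(n1 - 1)
    else:
        y = np.asarray(y, dtype=float)
        n1, n2 = len(x), len(y)
        if min(n1, n2) < 2:
            raise ValueError("need n >= 2 per sample")
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ZeroVarianceError("samples have zero pooled variance")
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        n_eff, df = n1 * n2 / (n1 + n2), float(n1 + n2 - 2)
    bf = _jzs_bf_from_t(float(t), n_eff, df, prior_scale)
    return BayesTTestResult(
        bf10=float(bf), t=float(t), n1=n1, n2=n2, df=df, prior_scale=prior_scale
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U with rank-biserial correlation


@dataclass
class NonparamResult:
    U: float
    p: float
    rank_biserial: float
    n1: int
    n2: int


def mann_whitney(x: np.ndarray, y: np.ndarray) -> NonparamResult:
    """Two-sided Mann-Whitney U test with the rank-biserial effect size.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise.  The rank-biserial correlation is
    2U/(n1*n2) - 1, in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (max(n1, n2) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    return NonparamResult(
        U=u,
        p=float(res.pvalue),
        rank_biserial=2.0 * u / (n1 * n2) - 1.0,
        n1=n1,
        n2=n2,
    )


# ---------------------------------------------------------------------------
# BIC-approximated inclusion Bayes factors


def _fit_bic(y: np.ndarray, X: np.ndarray, Z_subject: np.ndarray) -> float:
    """BIC of a random-intercept linear model, exact ML.

    The subject random intercept gives each subject's k observations the
    compound-symmetric marginal covariance sigma^2 (I + theta J).  For
    fixed variance ratio theta the GLS coefficients and sigma^2 have
    closed forms, leaving a one-dimensional profile likelihood in theta
    that is maximised numerically (theta = 0 allowed).
    """
    y = np.asarray(y, dtype=float)
    subjects, inv = np.unique(Z_subject, return_inverse=True)
    counts = np.bincount(inv)
    if counts.min() != counts.max():
        raise ValueError("every subject needs the same number of observations")
    k = int(counts[0])
    n = len(y)
    order = np.argsort(inv, kind="stable")
    yo, Xo, so = y[order], X[order], inv[order]

    def neg2_profile_llf(theta: float) -> float:
        # W = (I + theta J)^{-1} = I - c J with c = theta / (1 + k theta)
        c = theta / (1.0 + k * theta)
        # apply W blockwise via per-subject means
        def w_apply(M):
            M = M if M.ndim == 2 else M[:, None]
            sums = np.add.reduceat(M, np.searchsorted(so, np.arange(len(subjects))), axis=0)
            return M - c * sums[so]
        Wy = w_apply(yo)[:, 0] if yo.ndim == 1 else w_apply(yo)
        WX = w_apply(Xo)
        XtWX = Xo.T @ WX
        XtWy = Xo.T @ Wy
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
        resid = yo - Xo @ beta
        rss_w = float(resid @ (w_apply(resid)[:, 0]))
        sigma2 = max(rss_w / n, 1e-300)
        logdet = len(subjects) * np.log1p(k * theta)
        return n * np.log(2 * np.pi * sigma2) + logdet + n

    res = optimize.minimize_scalar(
        lambda u: neg2_profile_llf(np.expm1(u) if u > 0 else 0.0),
        bounds=(0.0, np.log(1e4)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    best = min(neg2_profile_llf(0.0), res.fun)
    n_params = X.shape[1] + 2  # fixed effects + residual and intercept vars
    return float(best + n_params * np.log(n))


def bf_inclusion_approx(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "electrode",
    between: str = "group",
    subject: str = "subject",
) -> dict[str, float]:
    """Inclusion Bayes factors across matched models, BIC-approximated.

    Candidate models respect marginality: {}, {A}, {B}, {A,B}, {A,B,AxB}
    with A the between and B the within factor, each with a subject random
    intercept.  Per-model marginal likelihoods are approximated by
    exp(-BIC/2) (a unit-information-prior approximation to the default
    ANOVA Bayes factor); the inclusion BF for an effect compares matched
    models with and without it, excluding models containing its
    higher-order interaction.
    """
    y = data[dv].to_numpy(dtype=float)
    subj = data[subject].to_numpy()
    a = pd.get_dummies(data[between], drop_first=True, dtype=float).to_numpy()
    b = pd.get_dummies(data[within], drop_first=True, dtype=float).to_numpy()
    ab = np.column_stack(
        [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    )
    ones = np.ones((len(y), 1))
    designs = {
        frozenset(): ones,
        frozenset({"A"}): np.column_stack([ones, a]),
        frozenset({"B"}): np.column_stack([ones, b]),
        frozenset({"A", "B"}): np.column_stack([ones, a, b]),
        frozenset({"A", "B", "A:B"}): np.column_stack([ones, a, b, ab]),
    }
    bics = {key: _fit_bic(y, X, subj) for key, X in designs.items()}
    bic0 = min(bics.values())
    weights = {key: np.exp(-(v - bic0) / 2.0) for key, v in bics.items()}

    def incl(effect: str, interaction: str | None) -> float:
        with_e = without_e = 0.0
        for key, w in weights.items():
            if interaction is not None and interaction in key:
                continue  # matched models only
            if effect in key:
                with_e += w
            else:
                # the matched counterpart (key - {effect}) must be a model
                if key | {effect} in weights:
                    without_e += w
        if with_e == 0.0:
            raise ValueError(f"effect {effect!r} absent from all models")
        return with_e / without_e

    return {
        between: incl("A", "A:B"),
        within: incl("B", "A:B"),
        f"{between} * {within}": incl("A:B", None),
    }


# ---------------------------------------------------------------------------
# two-sample permutation t (used for source-space group contrasts)


def permutation_t_twosample(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise two-sample permutation t-test (label shuffling).

    ``a``: (n1, P), ``b``: (n2, P).  Returns (t_observed, p) per point,
    two-tailed, p with the add-one convention.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.vstack([a, b])

    def tstat(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        va = xa.var(axis=0, ddof=1)
        vb = xb.var(axis=0, ddof=1)
        sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (xa.mean(axis=0) - xb.mean(axis=0)) / np.sqrt(
                sp2 * (1 / n1 + 1 / n2)
            )
        return np.nan_to_num(t, nan=0.0)

    t_obs = tstat(a, b)
    count = np.zeros_like(t_obs)
    idx = np.arange(n1 + n2)
    for _ in range(n_perm):
        rng.shuffle(idx)
        xa, xb = pooled[idx[:n1]], pooled[idx[n1:]]
        count += np.abs(tstat(xa, xb)) >= np.abs(t_obs) - 1e-12
    p = (1.0 + count) / (1.0 + n_perm)
    return t_obs, p
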