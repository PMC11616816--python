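"""Independent reference computations used to validate the statistics.

Everything here deliberately avoids the code paths it checks: sums of
squares come from nested least-squares fits, permutation p-values from
exhaustive enumeration, and the JZS Bayes factor from the g-prior mixture
integral rather than the noncentral-t quadrature the implementation uses.
"""

import itertools
from math import gamma as gamma_fn

import numpy as np
import pandas as pd
from scipy import integrate

from refback.inference import _orthonormal_contrasts


def brute_force_tmax_p(x: np.ndarray):
    """Exhaustive sign-flip tmax enumeration for a (n, P) matrix."""
    n = x.shape[0]

    def tstat(v):
        return v.mean(0) / (v.std(0, ddof=1) / np.sqrt(n))

    t_obs = tstat(x)
    null = np.array(
        [
            np.abs(tstat(np.array(s)[:, None] * x)).max()
            for s in itertools.product((-1.0, 1.0), repeat=n)
        ]
    )
    p = (null[None, :] >= np.abs(t_obs)[:, None] - 1e-12).sum(1) / 2**n
    return t_obs, p


def rss_mixed_anova(df: pd.DataFrame):
    """Split-plot F statistics as RSS differences between nested fits,
    plus Greenhouse-Geisser epsilon from the pooled covariance."""

    def _rss(y, X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    wide = df.pivot_table(index="subject", columns="electrode", values="value")
    groups = df.groupby("subject")["group"].first().loc[wide.index]
    y = wide.to_numpy().ravel()
    n_subj, k = wide.shape
    subj_idx = np.repeat(np.arange(n_subj), k)
    lev_idx = np.tile(np.arange(k), n_subj)
    grp_codes = pd.factorize(groups)[0]
    grp_idx = np.repeat(grp_codes, k)
    G = len(np.unique(grp_codes))

    S = np.eye(n_subj)[subj_idx]
    B = np.eye(k)[lev_idx]
    GB = np.zeros((len(y), G * k))
    for i, (g, b) in enumerate(zip(grp_idx, lev_idx)):
        GB[i, g * k + b] = 1.0
    rss_s = _rss(y, S)
    rss_sb = _rss(y, np.hstack([S, B]))
    rss_full = _rss(y, np.hstack([S, GB]))
    ss_b, ss_ab, ss_err = rss_s - rss_sb, rss_sb - rss_full, rss_full

    subj_means = wide.to_numpy().mean(axis=1)
    ss_total_between = _rss(subj_means, np.ones((n_subj, 1)))
    ss_within_groups = _rss(subj_means, np.eye(G)[grp_codes])
    ss_a = k * (ss_total_between - ss_within_groups)
    ss_subj = k * ss_within_groups

    df_a, df_subj = G - 1, n_subj - G
    df_b, df_ab, df_err = k - 1, (G - 1) * (k - 1), (n_subj - G) * (k - 1)
    F = {
        "group": (ss_a / df_a) / (ss_subj / df_subj),
        "electrode": (ss_b / df_b) / (ss_err / df_err),
        "interaction": (ss_ab / df_ab) / (ss_err / df_err),
    }
    pooled = np.zeros((k, k))
    for g in np.unique(groups):
        yg = wide.to_numpy()[groups.to_numpy() == g]
        d = yg - yg.mean(axis=0)
        pooled += d.T @ d
    pooled /= n_subj - G
    C = _orthonormal_contrasts(k)
    M = C @ pooled @ C.T
    eps = np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))
    return F, eps


def jzs_bf_one_sample_g_mixture(t: float, n: int, r: float = 0.707) -> float:
    """JZS BF10 via the g-prior mixture integral (inverse-gamma(1/2, r^2/2)
    mixing density), integrated adaptively to high precision."""
    v = n - 1

    def pi_g(g):
        a, b = 0.5, r**2 / 2
        return b**a / gamma_fn(a) * g ** (-a - 1) * np.exp(-b / g)

    def f(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t**2 / ((1 + n * g) * v)) ** (-(v + 1) / 2)
            * pi_g(g)
        )

    num, _ = integrate.quad(f, 0, np.inf, epsabs=1e-12, epsrel=1e-10, limit=500)
    den = (1 + t**2 / v) ** (-(v + 1) / 2)
    return num / den


def sample_with_t(rng: np.random.Generator, t: float, n: int) -> np.ndarray:
    """A sample of size n whose one-sample t statistic is exactly t."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return z + t / np.sqrt(n)
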