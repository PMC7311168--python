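"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's internal code paths: the marginal
likelihood oracle works on full N x N matrices with prior draws of g, the
ANOVA oracle compares nested OLS fits on explicit design matrices, and the
SNR oracle simulates the ratio statistic directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

CANON = ("CS+", "GS1", "GS2", "GS3", "GS4", "CS-")


# ---------------------------------------------------------------------------
# Monte-Carlo marginal likelihood for the JZS mixed model
# ---------------------------------------------------------------------------

def _log_conditional_marginal_batch(y: np.ndarray, parts: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """log p(y | g) up to constants for a batch of draws.

    ``parts`` is a list of (g_draws, X B X^T) pairs; the prior covariance of
    the observations is I + sum_k g_k * (X_k B_k X_k^T).  Works on full N x N
    matrices (batched Cholesky), independent of the package's reduced-form
    evaluation.
    """
    n = len(y)
    n_draws = len(parts[0][0])
    v = np.broadcast_to(np.eye(n), (n_draws, n, n)).copy()
    for g, mat in parts:
        v += g[:, None, None] * mat[None, :, :]
    chol = np.linalg.cholesky(v)
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
    rhs = np.broadcast_to(np.column_stack([y, np.ones(n)]), (n_draws, n, 2))
    a = np.linalg.solve(chol, rhs)
    yvy = np.einsum("ij,ij->i", a[:, :, 0], a[:, :, 0])
    ovo = np.einsum("ij,ij->i", a[:, :, 1], a[:, :, 1])
    ovy = np.einsum("ij,ij->i", a[:, :, 0], a[:, :, 1])
    r = yvy - ovy**2 / ovo
    return -0.5 * logdet - 0.5 * np.log(ovo) - 0.5 * (n - 1) * np.log(r)


def mc_jzs_bf(
    table: pd.DataFrame,
    weights: np.ndarray,
    model: str,
    n_draws: int,
    seed: int,
    rscale_fixed: float = 0.5,
    rscale_random: float = 1.0,
) -> float:
    """Brute-force BF vs the random-intercept null from prior draws of g."""
    y = table["snr"].to_numpy(float)
    subj, _ = pd.factorize(table["subject_id"])
    n = len(y)
    z = np.zeros((n, subj.max() + 1))
    z[np.arange(n), subj] = 1.0
    u = np.asarray(weights, float)
    u = (u - u.mean()) / np.linalg.norm(u - u.mean())
    w_col = u[[CANON.index(c) for c in table["condition"]]]
    x_cov = table["spai"].to_numpy(float)
    x_cov = x_cov - x_cov.mean()
    cols = [w_col]
    if model in ("M2", "M3"):
        cols.append(x_cov)
    if model == "M3":
        cols.append(w_col * x_cov)
    xf = np.column_stack(cols)
    xf = xf - xf.mean(axis=0)
    bf_base = n * np.linalg.inv(xf.T @ xf)

    rng = np.random.default_rng(seed)
    # g ~ IG(1/2, r^2/2)  <=>  1/g ~ Gamma(1/2, rate r^2/2)
    gb = 1.0 / rng.gamma(0.5, 2.0 / rscale_random**2, n_draws)
    gf = 1.0 / rng.gamma(0.5, 2.0 / rscale_fixed**2, n_draws)

    zzt = z @ z.T
    q = xf @ bf_base @ xf.T
    lp_alt = np.empty(n_draws)
    lp_null = np.empty(n_draws)
    chunk = 20_000
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        lp_alt[lo:hi] = _log_conditional_marginal_batch(
            y, [(gb[lo:hi], zzt), (gf[lo:hi], q)])
        lp_null[lo:hi] = _log_conditional_marginal_batch(y, [(gb[lo:hi], zzt)])
    return float(np.exp(logsumexp(lp_alt) - logsumexp(lp_null)))


# ---------------------------------------------------------------------------
# classical repeated-measures ANCOVA by nested OLS fits
# ---------------------------------------------------------------------------

def anova_f_tests(table: pd.DataFrame, response: str = "snr") -> dict:
    """Split-plot F tests via residual sums of squares of explicit OLS fits."""
    wide = table.pivot(index="subject_id", columns="condition", values=response)
    levels = [c for c in CANON if c in wide.columns]
    wide = wide[levels]
    y = wide.to_numpy(float).ravel()  # subject-major
    n, c = wide.shape
    subj = np.repeat(np.arange(n), c)
    cond = np.tile(np.arange(c), n)
    x = table.groupby("subject_id")["spai"].mean().loc[wide.index].to_numpy(float)
    x = x - x.mean()
    xs = np.repeat(x, c)

    subj_d = np.zeros((n * c, n))
    subj_d[np.arange(n * c), subj] = 1.0
    cond_d = np.zeros((n * c, c - 1))
    for j in range(c - 1):
        cond_d[cond == j, j] = 1.0
    inter_d = cond_d * xs[:, None]

    def rss(mat: np.ndarray) -> float:
        resid = y - mat @ np.linalg.lstsq(mat, y, rcond=None)[0]
        return float(resid @ resid)

    full = np.column_stack([subj_d, cond_d, inter_d])
    rss_full = rss(full)
    df_err = n * c - (n + 2 * (c - 1))
    ms_err = rss_full / df_err
    f_cond = ((rss(np.column_stack([subj_d, inter_d])) - rss_full) / (c - 1)) / ms_err
    f_inter = ((rss(np.column_stack([subj_d, cond_d])) - rss_full) / (c - 1)) / ms_err
    return {"f_condition": f_cond, "f_interaction": f_inter,
            "df1": c - 1, "df2": df_err, "ms_error": ms_err}


# ---------------------------------------------------------------------------
# white-noise SNR expectation
# ---------------------------------------------------------------------------

def mc_snr_expectation(n_sims: int, n_noise_bins: int = 6, seed: int = 0) -> tuple[float, float]:
    """Mean and SE of x / mean(y_1..y_k) for iid exponential power bins."""
    rng = np.random.default_rng(seed)
    x = rng.exponential(size=n_sims)
    y = rng.exponential(size=(n_sims, n_noise_bins)).mean(axis=1)
    ratio = x / y
    return float(ratio.mean()), float(ratio.std(ddof=1) / np.sqrt(n_sims))
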