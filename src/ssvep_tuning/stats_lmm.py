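"""Random-intercept mixed models for balanced subject x condition tables.

The analysis model is

    response ~ condition * centered_covariate + (1 | subject)

fitted by REML.  For complete balanced data (one observation per subject and
condition, covariate constant within subject) the REML solution and the
Satterthwaite/Kenward-Roger denominator degrees of freedom have closed
forms via the classical two-stratum (between/within subjects) decomposition:
within-factor tests use (n_subjects - 2) * (n_conditions - 1) denominator
df, the covariate test uses n_subjects - 2.  Incomplete tables are an error
(no imputation), matching the contract of the published analyses.

Effect sizes are semi-partial R^2 computed from the Wald F,
R2 = (df1/df2 * F) / (1 + df1/df2 * F), with confidence intervals from
noncentral-F inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import CONDITIONS


@dataclass(frozen=True)
class FTest:
    f: float
    df1: float
    df2: float
    p: float
    r2: float
    r2_ci: tuple[float, float]


@dataclass(frozen=True)
class CovariateTest:
    beta: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class LMMResult:
    response: str
    conditions: list[str]
    condition_means: np.ndarray
    n_subjects: int
    anova: dict  # {"condition": FTest, "condition:covariate": FTest}
    covariate: CovariateTest
    varcomp: dict  # {"subject": sigma2_b, "residual": sigma2_e}
    ms_error: float
    df_within: float
    reference: str

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


@dataclass(frozen=True)
class ContrastResult:
    condition: str
    estimate: float
    se: float
    t: float
    df: float
    p: float


def _order_conditions(levels: list[str]) -> list[str]:
    known = [c for c in CONDITIONS if c in levels]
    extra = sorted(set(levels) - set(known))
    return known + extra


def partial_r2_from_f(f: float, df1: float, df2: float) -> float:
    q = df1 / df2 * f
    return q / (1.0 + q)


def partial_r2_ci(f: float, df1: float, df2: float, alpha: float = 0.05) -> tuple[float, float]:
    """CI for semi-partial R^2 by inverting the noncentral-F distribution."""

    def to_r2(lam: float) -> float:
        return lam / (lam + df1 + df2 + 1.0)

    def solve(target: float) -> float:
        if stats.ncf.cdf(f, df1, df2, 0.0) < target:
            return 0.0
        hi = 1.0
        while stats.ncf.cdf(f, df1, df2, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return optimize.brentq(lambda lam: stats.ncf.cdf(f, df1, df2, lam) - target, 0.0, hi)

    lam_lo = solve(1.0 - alpha / 2.0)
    lam_hi = solve(alpha / 2.0)
    return (to_r2(lam_lo), to_r2(lam_hi))


def _pivot_balanced(table: pd.DataFrame, response: str, condition: str,
                    subject: str, covariate: str) -> tuple[np.ndarray, np.ndarray, list[str], list]:
    counts = table.groupby([subject, condition], observed=True).size()
    if (counts != 1).any():
        dup = counts[counts != 1]
        raise ValueError(f"table is not one-observation-per-cell: {dup.index.tolist()[:5]}")
    levels = _order_conditions(list(table[condition].unique()))
    wide = table.pivot(index=subject, columns=condition, values=response)
    if wide.isna().any().any():
        missing = [
            (s, c) for s in wide.index for c in levels if pd.isna(wide.loc[s, c])
        ]
        raise ValueError(f"subjects with missing cells (no imputation): {missing[:5]}")
    wide = wide[levels]
    cov = table.groupby(subject, observed=True)[covariate].agg(["min", "max", "mean"])
    if not np.allclose(cov["min"], cov["max"]):
        raise ValueError(f"covariate {covariate!r} must be constant within subject")
    cov = cov.loc[wide.index, "mean"].to_numpy(dtype=float)
    return wide.to_numpy(dtype=float), cov, levels, list(wide.index)


def fit_lmm(
    table: pd.DataFrame,
    response: str = "snr",
    condition: str = "condition",
    subject: str = "subject_id",
    covariate: str = "spai",
    reference: str = "CS-",
) -> LMMResult:
    """Fit the random-intercept ANCOVA on a complete balanced long table."""
    for col in (response, condition, subject, covariate):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    y, x, levels, _ = _pivot_balanced(table, response, condition, subject, covariate)
    n, c = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    x = x - x.mean()  # center the covariate (does not move condition effects)
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("covariate has zero variance")

    # ---- between-subject stratum: subject means ~ covariate ----
    s = y.mean(axis=1)
    beta = float(x @ s) / sxx
    resid_b = s - s.mean() - beta * x
    df_b = n - 2
    ms_b = float(resid_b @ resid_b) / df_b
    se_beta = np.sqrt(ms_b / sxx)
    t_cov = beta / se_beta
    p_cov = 2.0 * stats.t.sf(abs(t_cov), df_b)

    # ---- within-subject stratum: deviations from subject means ----
    d = y - s[:, None]
    col_means = d.mean(axis=0)                     # condition effects
    ss_cond = n * float(col_means @ col_means)
    slopes = (x @ d) / sxx                         # per-condition covariate slopes
    ss_inter = sxx * float(slopes @ slopes)        # slopes sum to zero within stratum
    ss_total = float((d * d).sum())
    df_w = (n - 2) * (c - 1)
    ss_err = max(ss_total - ss_cond - ss_inter, 0.0)
    ms_err = ss_err / df_w
    df1 = c - 1
    f_cond = (ss_cond / df1) / ms_err
    f_inter = (ss_inter / df1) / ms_err

    sigma2_e = ms_err
    sigma2_b = max(0.0, ms_b - sigma2_e / c)

    anova = {}
    for name, f in (("condition", f_cond), ("condition:covariate", f_inter)):
        anova[name] = FTest(
            f=float(f), df1=float(df1), df2=float(df_w),
            p=float(stats.f.sf(f, df1, df_w)),
            r2=partial_r2_from_f(f, df1, df_w),
            r2_ci=partial_r2_ci(f, df1, df_w),
        )

    ref = reference if reference in levels else levels[-1]
    return LMMResult(
        response=response,
        conditions=levels,
        condition_means=y.mean(axis=0),
        n_subjects=n,
        anova=anova,
        covariate=CovariateTest(beta=beta, se=float(se_beta), t=float(t_cov),
                                df=float(df_b), p=float(p_cov)),
        varcomp={"subject": sigma2_b, "residual": sigma2_e},
        ms_error=ms_err,
        df_within=float(df_w),
        reference=ref,
    )


def simple_contrasts(fit: LMMResult, reference: str | None = None) -> list[ContrastResult]:
    """Uncorrected t tests of each condition against the reference level."""
    ref = reference or fit.reference
    if ref not in fit.conditions:
        raise ValueError(f"reference level {ref!r} not among conditions {fit.conditions}")
    ref_idx = fit.conditions.index(ref)
    se = np.sqrt(2.0 * fit.ms_error / fit.n_subjects)
    out = []
    for j, cond in enumerate(fit.conditions):
        if j == ref_idx:
            continue
        est = float(fit.condition_means[j] - fit.condition_means[ref_idx])
        if se == 0:
            t = np.inf if est > 0 else (-np.inf if est < 0 else 0.0)
            p = 0.0 if est != 0 else 1.0
        else:
            t = est / se
            p = float(2.0 * stats.t.sf(abs(t), fit.df_within))
        out.append(ContrastResult(cond, est, float(se), float(t), fit.df_within, p))
    return out


def partial_r2(fit: LMMResult) -> dict:
    """Semi-partial R^2 with CI per fixed effect (covariate via F = t^2)."""
    out = {name: {"r2": ft.r2, "ci": ft.r2_ci} for name, ft in fit.anova.items()}
    f_cov = fit.covariate.t**2
    out["covariate"] = {
        "r2": partial_r2_from_f(f_cov, 1.0, fit.covariate.df),
        "ci": partial_r2_ci(f_cov, 1.0, fit.covariate.df),
    }
    return out


def lmm_table(fits: dict[str, LMMResult]) -> pd.DataFrame:
    """Flatten fits (keyed by outcome name) into a report table."""
    rows = []
    for outcome, fit in fits.items():
        ft = fit.anova["condition"]
        rows.append((outcome, "condition", "F", ft.f, ft.df1, ft.df2, ft.p,
                     ft.r2, ft.r2_ci[0], ft.r2_ci[1]))
        cv = fit.covariate
        rows.append((outcome, "covariate", "t", cv.t, 1.0, cv.df, cv.p,
                     partial_r2_from_f(cv.t**2, 1.0, cv.df), np.nan, np.nan))
        fi = fit.anova["condition:covariate"]
        rows.append((outcome, "condition:covariate", "F", fi.f, fi.df1, fi.df2,
                     fi.p, fi.r2, fi.r2_ci[0], fi.r2_ci[1]))
    return pd.DataFrame(
        rows,
        columns=["outcome", "effect", "stat_type", "statistic", "df1", "df2",
                 "p", "partial_r2", "r2_ci_lo", "r2_ci_hi"],
    )
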