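"""Bayesian model comparison with weighted condition contrasts.

Three hypothesis shapes (lateral inhibition, quadratic, linear) enter a
linear mixed model as a single weighted predictor; nested models add the
subject covariate and its interaction with the weights:

    M1: response ~ w(condition)                        + (1 | subject)
    M2: response ~ w(condition) + covariate            + (1 | subject)
    M3: response ~ w(condition) * covariate            + (1 | subject)
    0:  response ~ 1                                   + (1 | subject)

Priors follow the default Jeffreys-Zellner-Siow setup: a flat prior on the
grand mean, Jeffreys on the error variance, and zero-centered scaled-Cauchy
priors on standardized effects implemented as normal slabs with
inverse-gamma(1/2, r^2/2) mixing on g.  Fixed slopes share one g with a
Zellner g-prior covariance  g * sigma^2 * N * (X'X)^-1  (scale r_fixed,
default 0.5); the random-intercept block has its own g (scale r_random,
default 1).  The grand mean, slopes and error variance are integrated
analytically; the remaining one- or two-dimensional g integral is evaluated
by Gauss-Legendre quadrature on a Cauchy-representation transform of g,
with the numerical error estimated from a half-order rule.  Bayes factors are
invariant to linear transformations of the weight vector (weights are
centered and L2-normalized before entering the design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .contrasts import ContrastWeights, available_contrasts, contrast_weights  # noqa: F401
from .design import CONDITIONS

MODELS = ("M1", "M2", "M3")


# ---------------------------------------------------------------------------
# marginal likelihood machinery
# ---------------------------------------------------------------------------

class _GIntegrand:
    """log p(y | g) up to a g-independent constant, evaluated from m x m
    cross-products (Woodbury / determinant-lemma reduction).

    Columns of ``u`` are grouped; group k receives variance multiplier g_k.
    """

    def __init__(self, y: np.ndarray, u: np.ndarray, groups: np.ndarray):
        y = np.asarray(y, float)
        u = np.asarray(u, float)
        self.n = len(y)
        self.groups = np.asarray(groups)
        self.n_groups = int(self.groups.max()) + 1 if u.shape[1] else 0
        self.m = u.shape[1]
        self.uu = u.T @ u
        self.uy = u.T @ y
        self.u1 = u.T @ np.ones(self.n)
        self.yy = float(y @ y)
        self.y1 = float(y.sum())

    def logp(self, g: np.ndarray) -> np.ndarray:
        """Vectorized over a (k, n_groups) batch of g vectors; returns (k,)."""
        g = np.atleast_2d(np.asarray(g, float))
        d = np.sqrt(g[:, self.groups])  # (k, m)
        k_mat = np.eye(self.m) + d[:, :, None] * self.uu[None, :, :] * d[:, None, :]
        cf = np.linalg.cholesky(k_mat)
        logdet = 2.0 * np.log(np.diagonal(cf, axis1=1, axis2=2)).sum(axis=1)
        rhs = d[:, :, None] * np.column_stack([self.uy, self.u1])[None, :, :]
        a = np.linalg.solve(cf, rhs)
        yvy = self.yy - np.einsum("km,km->k", a[:, :, 0], a[:, :, 0])
        ovo = self.n - np.einsum("km,km->k", a[:, :, 1], a[:, :, 1])
        ovy = self.y1 - np.einsum("km,km->k", a[:, :, 0], a[:, :, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = yvy - ovy**2 / ovo
            out = -0.5 * logdet - 0.5 * np.log(ovo) - 0.5 * (self.n - 1) * np.log(r)
        out[~np.isfinite(out)] = -np.inf
        return out


def _u_to_g(u: np.ndarray, rscales: np.ndarray) -> np.ndarray:
    # g = r^2 / z^2 with z = ndtri(u) standard normal maps the IG(1/2, r^2/2)
    # mixing prior on g to the uniform measure 2 du on u in (1/2, 1); this is
    # the normal-over-normal representation of the Cauchy slab.
    z = special.ndtri(np.asarray(u, float))
    return (rscales / z) ** 2


def _gl_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(order)
    # map from (-1, 1) to (1/2, 1); prior measure on u is 2 du
    return 0.5 + 0.25 * (x + 1.0), 0.5 * w


def _gl_sum(integrand: _GIntegrand, rscales: np.ndarray, order: int,
            shift: float) -> float:
    ndim = len(rscales)
    u, w = _gl_nodes(order)
    if ndim == 1:
        g = _u_to_g(u[:, None], rscales)
        return float(w @ np.exp(integrand.logp(g) - shift))
    if ndim == 2:
        u1, u2 = np.meshgrid(u, u, indexing="ij")
        g = np.column_stack([
            _u_to_g(u1.ravel(), rscales[:1]).ravel(),
            _u_to_g(u2.ravel(), rscales[1:]).ravel(),
        ])
        vals = np.exp(integrand.logp(g) - shift).reshape(order, order)
        return float(w @ vals @ w)
    raise NotImplementedError("quadrature implemented for <= 2 g dimensions")


def _integrate_g(integrand: _GIntegrand, rscales: np.ndarray,
                 order: int = 48) -> tuple[float, float]:
    """log of int p(y|g) prior(g) dg (up to the shared constant) and rel. error.

    Tensor-product Gauss-Legendre in the transformed u coordinates, where the
    integrand is smooth and compactly supported; the numerical error is
    estimated by comparing against the rule with half the nodes.
    """
    ndim = len(rscales)
    grid = np.linspace(0.501, 1.0 - 1e-6, 13)
    if ndim == 1:
        shift = float(integrand.logp(_u_to_g(grid[:, None], rscales)).max())
    else:
        u1, u2 = np.meshgrid(grid, grid, indexing="ij")
        g = np.column_stack([
            _u_to_g(u1.ravel(), rscales[:1]).ravel(),
            _u_to_g(u2.ravel(), rscales[1:]).ravel(),
        ])
        shift = float(integrand.logp(g).max())
    val = _gl_sum(integrand, rscales, order, shift)
    val_half = _gl_sum(integrand, rscales, order // 2, shift)
    if val <= 0 or not np.isfinite(val):
        raise FloatingPointError("non-finite marginal likelihood integral")
    err = abs(val - val_half)
    return float(np.log(val) + shift), float(err / val)


@dataclass(frozen=True)
class BayesFactorResult:
    bf: float
    log_bf: float
    rel_err: float
    model: str
    contrast: str
    settings: dict = field(default_factory=dict, compare=False)

    def __float__(self) -> float:
        return self.bf


def _design_columns(table: pd.DataFrame, weights: ContrastWeights, model: str,
                    response: str, condition: str, subject: str,
                    covariate: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y, Z, Xf): response, subject indicators, centered fixed columns."""
    y = table[response].to_numpy(float)
    subj_codes, _ = pd.factorize(table[subject])
    z = np.zeros((len(y), subj_codes.max() + 1))
    z[np.arange(len(y)), subj_codes] = 1.0
    u = weights.unit()
    cond_idx = [CONDITIONS.index(c) for c in table[condition]]
    w_col = u[cond_idx]
    x = table[covariate].to_numpy(float)
    x = x - x.mean()
    cols = [w_col]
    if model in ("M2", "M3"):
        cols.append(x)
    if model == "M3":
        cols.append(w_col * x)
    xf = np.column_stack(cols)
    xf = xf - xf.mean(axis=0)
    return y, z, xf


def jzs_bf(
    table: pd.DataFrame,
    weights: ContrastWeights,
    model: str = "M1",
    rscale_fixed: float = 0.5,
    rscale_random: float = 1.0,
    response: str = "snr",
    condition: str = "condition",
    subject: str = "subject_id",
    covariate: str = "spai",
    quad_order: int = 48,
) -> BayesFactorResult:
    """Bayes factor of the weighted-contrast model vs the random-intercept null."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if table[[response, condition, subject, covariate]].isna().any().any():
        raise ValueError("table contains missing values")
    y, z, xf = _design_columns(table, weights, model, response, condition,
                               subject, covariate)

    # fixed block: Zellner g-prior covariance g * N * (Xf'Xf)^-1 -> transform
    # columns so the block prior becomes g * I
    xtx = xf.T @ xf
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise ValueError("rank-deficient fixed-effect design (degenerate covariate?)")
    l = np.linalg.cholesky(len(y) * np.linalg.inv(xtx))
    xft = xf @ l

    u_alt = np.column_stack([z, xft])
    groups_alt = np.concatenate([np.zeros(z.shape[1], int), np.ones(xft.shape[1], int)])
    alt = _GIntegrand(y, u_alt, groups_alt)
    null = _GIntegrand(y, z, np.zeros(z.shape[1], int))

    log_num, err_num = _integrate_g(alt, np.array([rscale_random, rscale_fixed]), quad_order)
    log_den, err_den = _integrate_g(null, np.array([rscale_random]), quad_order)
    log_bf = log_num - log_den
    if not np.isfinite(log_bf):
        raise FloatingPointError("non-finite marginal likelihood")
    rel_err = float(np.hypot(err_num, err_den))
    if abs(log_bf) > 0 and rel_err > 0.05 * abs(log_bf):
        warnings.warn(
            f"quadrature error {rel_err:.3g} exceeds 5% of |log BF| {abs(log_bf):.3g}",
            RuntimeWarning, stacklevel=2,
        )
    return BayesFactorResult(
        bf=float(np.exp(log_bf)), log_bf=float(log_bf), rel_err=rel_err,
        model=model, contrast=weights.name,
        settings={"rscale_fixed": rscale_fixed, "rscale_random": rscale_random,
                  "quad_order": quad_order},
    )


def transitive_bf(bf_a_vs_0: float, bf_b_vs_0: float) -> float:
    """Relative evidence of model a over model b sharing a common null."""
    a, b = float(bf_a_vs_0), float(bf_b_vs_0)
    if a <= 0 or b <= 0:
        raise ValueError("Bayes factors must be positive")
    return a / b


def bayes_comparison(
    table: pd.DataFrame,
    contrasts: tuple[str, ...] = ("lateral_inhibition", "quadratic", "linear"),
    models: tuple[str, ...] = MODELS,
    **kwargs,
) -> pd.DataFrame:
    """Model-comparison table: BF vs null per shape and model, plus the
    transitive ratios of the first shape over each alternative."""
    results = {
        (m, name): jzs_bf(table, contrast_weights(name), model=m, **kwargs)
        for m in models for name in contrasts
    }
    rows = []
    lead = contrasts[0]
    for m in models:
        row: dict = {"model": m}
        for name in contrasts:
            res = results[(m, name)]
            row[f"bf_{name}"] = res.bf
            row[f"err_{name}"] = res.rel_err
        for name in contrasts[1:]:
            row[f"{lead}_vs_{name}"] = transitive_bf(
                results[(m, lead)].bf, results[(m, name)].bf
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tuning index and its covariate correlation
# ---------------------------------------------------------------------------

def tuning_index(snr_vector: np.ndarray, weights: ContrastWeights) -> float:
    """Scalar product of the (raw, centered) weights with the six condition SNRs."""
    v = np.asarray(snr_vector, float)
    w = weights.as_array()
    if v.shape != w.shape:
        raise ValueError(f"expected {w.shape[0]} SNR values, got {v.shape}")
    return float(v @ w)


def tuning_index_table(
    snr_table: pd.DataFrame,
    contrasts: tuple[str, ...] = ("lateral_inhibition", "quadratic", "linear"),
    phase: str = "generalization",
) -> pd.DataFrame:
    """Per-subject indices for each contrast shape, with the covariate."""
    sub = snr_table[snr_table["phase"] == phase]
    rows = []
    for subject_id, grp in sub.groupby("subject_id", observed=True, sort=True):
        by_cond = grp.set_index("condition")["snr"]
        if set(by_cond.index) != set(CONDITIONS):
            raise ValueError(f"subject {subject_id}: incomplete condition set")
        vec = by_cond.reindex(list(CONDITIONS)).to_numpy(float)
        spai = float(grp["spai"].iloc[0])
        for name in contrasts:
            rows.append((subject_id, name, tuning_index(vec, contrast_weights(name)), spai))
    return pd.DataFrame(rows, columns=["subject_id", "contrast", "index", "spai"])


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: float
    p: float
    bf_rho: float
    n: int


def pearson_bf(r: float, n: int, kappa: float = 1.0, n_grid: int | None = None) -> float:
    """Two-sided default Bayes factor for a nonzero population correlation.

    The exact sampling density of the observed correlation given rho is
    integrated against a stretched-beta(1/kappa, 1/kappa) prior on (-1, 1)
    (kappa = 1 is uniform).  ``n_grid`` switches to fixed trapezoidal
    integration (used by the refinement oracle); the default is adaptive
    quadrature.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))

    def kernel(rho: np.ndarray) -> np.ndarray:
        # rho-dependent part of p(r | rho, n), Fisher's exact density
        rho = np.asarray(rho, float)
        return (
            (1 - rho**2) ** ((n - 1) / 2.0)
            * (1 - rho * r) ** (1.5 - n)
            * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2.0)
        )

    a = 1.0 / kappa

    def prior(rho: np.ndarray) -> np.ndarray:
        return stats.beta.pdf((np.asarray(rho) + 1) / 2.0, a, a) / 2.0

    if n_grid is not None:
        rho = np.linspace(-1 + 1e-9, 1 - 1e-9, n_grid)
        num = np.trapezoid(kernel(rho) * prior(rho), rho)
    else:
        f = lambda q: float(kernel(q) * prior(q))  # noqa: E731
        with warnings.catch_warnings():
            # near-degenerate |r| ~ 1 concentrates all mass at the endpoint;
            # fall back to a dense fixed grid if the adaptive rule complains
            warnings.simplefilter("error", integrate.IntegrationWarning)
            try:
                lo_part, _ = integrate.quad(f, -1.0, r, limit=200)
                hi_part, _ = integrate.quad(f, r, 1.0, limit=200)
                num = lo_part + hi_part
            except integrate.IntegrationWarning:
                return pearson_bf(r, n, kappa=kappa, n_grid=200_001)
    return float(num / kernel(np.array(0.0)))


def correlate_with_covariate(indices: np.ndarray, spai: np.ndarray,
                             kappa: float = 1.0) -> CorrelationResult:
    """Pearson r with t-based p and the default two-sided correlation BF."""
    x = np.asarray(indices, float)
    s = np.asarray(spai, float)
    if x.shape != s.shape or x.ndim != 1:
        raise ValueError("indices and spai must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or s.std() == 0:
        raise ValueError("zero variance in indices or covariate")
    r = float(np.corrcoef(x, s)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t, p = np.inf, 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, df=float(df), p=p, bf_rho=pearson_bf(r, n, kappa), n=n)


# ---------------------------------------------------------------------------
# bootstrap Bayes factor for cross-phase conditioning effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapBFResult:
    bf: float          # mean over repeats
    se: float          # standard error of the mean over repeats
    se_pct: float      # se as percent of the mean
    bfs: np.ndarray = field(compare=False, default=None)
    b: int = 0
    repeats: int = 0


def bootstrap_bf(
    hab_diffs: np.ndarray,
    acq_diffs: np.ndarray,
    b: int = 100_000,
    repeats: int = 100,
    seed: int = 0,
    smoothing: bool = True,
) -> BootstrapBFResult:
    """Ratio of posterior (acquisition) over prior (habituation) odds that the
    group mean CS+ minus CS- difference is positive, from ``b`` bootstrap
    resamples of subjects, repeated ``repeats`` times for an error estimate.

    With equal-length inputs the same resampling indices are applied to both
    phases (subjects are paired across phases), so identical inputs give
    BF = 1 exactly.  Laplace smoothing (count + 1) / (b - count + 1) keeps
    the odds finite at finite ``b``; it can be disabled.
    """
    hab = np.asarray(hab_diffs, float)
    acq = np.asarray(acq_diffs, float)
    if hab.size == 0 or acq.size == 0:
        raise ValueError("difference vectors must be non-empty")
    if b < 100:
        raise ValueError("b must be >= 100")
    rng = np.random.default_rng(seed)
    paired = hab.size == acq.size
    bfs = np.empty(repeats)
    chunk = max(1, min(b, 20_000))
    for rep in range(repeats):
        pos_h = pos_a = 0
        done = 0
        while done < b:
            nb = min(chunk, b - done)
            idx_h = rng.integers(0, hab.size, size=(nb, hab.size))
            idx_a = idx_h if paired else rng.integers(0, acq.size, size=(nb, acq.size))
            pos_h += int((hab[idx_h].mean(axis=1) > 0).sum())
            pos_a += int((acq[idx_a].mean(axis=1) > 0).sum())
            done += nb
        if smoothing:
            odds_h = (pos_h + 1.0) / (b - pos_h + 1.0)
            odds_a = (pos_a + 1.0) / (b - pos_a + 1.0)
        else:
            if pos_h in (0, b) or pos_a in (0, b):
                raise ZeroDivisionError(
                    "degenerate bootstrap odds; enable smoothing or increase b"
                )
            odds_h = pos_h / (b - pos_h)
            odds_a = pos_a / (b - pos_a)
        bfs[rep] = odds_a / odds_h
    mean = float(bfs.mean())
    se = float(bfs.std(ddof=1) / np.sqrt(repeats)) if repeats > 1 else 0.0
    return BootstrapBFResult(bf=mean, se=se, se_pct=100.0 * se / mean if mean else np.inf,
                             bfs=bfs, b=b, repeats=repeats)


def phase_differences(snr_table: pd.DataFrame, phase: str,
                      plus: str = "CS+", minus: str = "CS-") -> np.ndarray:
    """Per-subject CS+ minus CS- SNR differences for one phase, subject-sorted."""
    sub = snr_table[snr_table["phase"] == phase]
    wide = sub.pivot(index="subject_id", columns="condition", values="snr")
    if plus not in wide.columns or minus not in wide.columns:
        raise ValueError(f"phase {phase!r} lacks {plus}/{minus} rows")
    d = (wide[plus] - wide[minus]).sort_index()
    if d.isna().any():
        raise ValueError("missing cells in phase differences")
    return d.to_numpy(float)
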