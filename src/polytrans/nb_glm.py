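"""Negative-binomial GLM machinery for count matrices.

Implements median-of-ratios size factors, per-gene method-of-moments
dispersion with trend shrinkage, IRLS fitting of NB2 log-link GLMs with
library-size offsets, Wald and likelihood-ratio tests, and
Benjamini-Hochberg adjustment.  The NB2 parameterization is
``Var = mu + alpha * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ALPHA_MIN",
    "GLMFit",
    "estimate_size_factors",
    "estimate_dispersion",
    "fit_nb_glm",
    "nb_loglik",
    "lrt",
    "wald_test",
    "bh_adjust",
    "differential_expression",
]

ALPHA_MIN = 1e-8


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``counts`` is a (genes x samples) array or DataFrame.  Only genes
    with positive counts in every sample contribute; if none exist a
    ``ValueError`` advises a pseudo-reference fallback.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "consider a pseudo-reference (positive-counts-only) fallback"
        )
    logs = np.log(mat[positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return np.exp(log_sf)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _design_hat(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return q @ q.T


def estimate_dispersion(
    counts,
    size_factors: np.ndarray,
    design: np.ndarray,
    shrink: float = 0.25,
    alpha_min: float = ALPHA_MIN,
) -> np.ndarray:
    """Per-gene NB dispersion by method of moments plus trend shrinkage.

    For each gene, normalized counts are projected onto the design by
    OLS; the df-corrected squared residuals are compared per sample
    with the Poisson expectation ``mu_hat_j / s_j`` and the pooled
    excess over ``sum(mu_hat_j**2)`` estimates alpha (this handles
    strongly heterogeneous fitted means, e.g. across fractions).  Raw
    estimates are shrunk (geometric interpolation, weight ``shrink`` on
    the gene-wise value) toward a mean-dispersion trend ``a0 + a1/mu``
    fitted across genes.
    """
    mat = np.asarray(counts, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if mat.shape[1] != n:
        raise ValueError("design rows must match number of samples")
    if n - p < 2:
        raise ValueError(
            f"need >= 2 residual degrees of freedom, have {n - p}"
        )
    y = mat / sf
    hat = _design_hat(X)
    fitted = np.maximum(y @ hat.T, 0.0)
    resid = y - fitted
    # df-corrected residual sum vs per-sample Poisson expectation
    num = (resid**2).sum(axis=1) * n / (n - p) - (fitted / sf).sum(axis=1)
    den = (fitted**2).sum(axis=1)
    mu = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = num / den
    raw = np.where(np.isfinite(raw), raw, alpha_min)
    raw = np.maximum(raw, alpha_min)

    # parametric trend alpha(mu) = a0 + a1/mu on informative genes
    ok = (mu > 0) & (raw > 10 * alpha_min)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        with np.errstate(divide="ignore"):
            trend = a0 + np.where(mu > 0, a1 / mu, 0.0)
        trend = np.maximum(trend, alpha_min)
        alpha = np.exp(shrink * np.log(raw) + (1 - shrink) * np.log(trend))
    else:
        alpha = raw
    return np.maximum(alpha, alpha_min)


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    beta: np.ndarray
    alpha: float
    loglik: float
    converged: bool
    iterations: int
    design: np.ndarray
    mu: np.ndarray
    cov: np.ndarray | None = None
    degenerate: bool = False

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.design))

    def standard_errors(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("covariance unavailable for degenerate fit")
        return np.sqrt(np.diag(self.cov))


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; reduces to Poisson for alpha below ALPHA_MIN."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    if alpha < ALPHA_MIN:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def fit_nb_glm(
    y,
    design,
    size_factors,
    alpha: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMFit:
    """Fit an NB2 GLM with log link and offset ``log(size_factor)`` by IRLS."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    offset = np.log(sf)

    if y.sum() == 0:
        beta = np.full(p, np.nan)
        return GLMFit(beta, alpha, 0.0, True, 0, X, np.zeros(n), None, degenerate=True)

    mu = np.maximum(y, 0.5)
    eta = np.log(mu) - offset  # linear predictor without offset
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta + offset, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtw @ X + 1e-8 * np.eye(p), xtw @ z, rcond=None)[0]
        delta = np.max(np.abs(beta_new - beta)) if it > 1 else np.inf
        beta = beta_new
        eta = X @ beta
        if delta < tol:
            converged = True
            break
    mu = np.exp(np.clip(eta + offset, -30, 30))
    ll = nb_loglik(y, mu, alpha)
    w = mu / (1.0 + alpha * mu)
    xtwx = (X.T * w) @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = None
    return GLMFit(beta, alpha, ll, converged, it, X, mu, cov)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _is_nested(full: np.ndarray, reduced: np.ndarray) -> bool:
    combined = np.hstack([full, reduced])
    return np.linalg.matrix_rank(combined) == np.linalg.matrix_rank(full)


def lrt(full: GLMFit, reduced: GLMFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested NB GLM fits.

    Statistic ``2 * (ll_full - ll_reduced)`` clipped at zero; p-value
    from chi-square with df = rank(full) - rank(reduced).
    """
    if not _is_nested(full.design, reduced.design):
        raise ValueError("reduced design is not nested in the full design")
    df = full.rank - reduced.rank
    if full.degenerate or reduced.degenerate:
        return 0.0, 1.0
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:  # identical column spans: nothing to test
        return stat, 1.0
    return stat, float(stats.chi2.sf(stat, df))


def wald_test(fit: GLMFit, coef_index: int) -> tuple[float, float]:
    """Wald z-test of a single coefficient against zero."""
    if fit.degenerate or fit.cov is None:
        return 0.0, np.nan
    se = fit.standard_errors()[coef_index]
    if not np.isfinite(se) or se == 0:
        return 0.0, np.nan
    z = fit.beta[coef_index] / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are excluded from m."""
    p = np.asarray(pvalues, dtype=float)
    padj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return padj
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    padj[ok] = out
    return padj


# ---------------------------------------------------------------------------
# differential expression driver
# ---------------------------------------------------------------------------

def differential_expression(
    counts: pd.DataFrame,
    condition_labels,
    size_factors: np.ndarray | None = None,
    alphas: np.ndarray | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Two-condition Wald test per gene on the condition coefficient.

    Returns a DataFrame with columns gene, baseMean, log2FoldChange,
    stat, pvalue, padj.  All-zero genes get NA statistics.
    """
    condition_labels = pd.Series(list(condition_labels), index=counts.columns)
    levels = sorted(condition_labels.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {levels}")
    if reference is None:
        reference = levels[0]
    other = [l for l in levels if l != reference][0]
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    X = np.column_stack(
        [np.ones(counts.shape[1]), (condition_labels == other).to_numpy(float)]
    )
    if alphas is None:
        alphas = estimate_dispersion(counts, size_factors, X)
    base_mean = (counts.to_numpy() / size_factors).mean(axis=1)

    rows = []
    for i, gene in enumerate(counts.index):
        y = counts.iloc[i].to_numpy()
        fit = fit_nb_glm(y, X, size_factors, float(alphas[i]))
        if fit.degenerate:
            rows.append((gene, base_mean[i], np.nan, np.nan, np.nan))
            continue
        stat, p = wald_test(fit, 1)
        rows.append((gene, base_mean[i], fit.beta[1] / np.log(2), stat, p))
    out = pd.DataFrame(
        rows, columns=["gene", "baseMean", "log2FoldChange", "stat", "pvalue"]
    ).set_index("gene")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
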