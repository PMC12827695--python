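"""Group statistics, effect sizes, multi-site harmonization.

Implements pooled-variance two-sample t tests (df = nA + nB - 2), Cohen's d
with a normal-approximation 95% CI, Pearson chi-square tests for categorical
demographics, Benjamini-Hochberg FDR, Spearman rank correlations, and
parametric empirical-Bayes location/scale batch harmonization (ComBat) for
features derived across acquisition sites.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    df: int
    p_value: float
    cohens_d: float
    ci95: tuple


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple
    rho: float
    p_value: float
    n: int


@dataclasses.dataclass(frozen=True)
class CombatModel:
    batch_labels: tuple
    site_names: tuple
    feature_grand_mean: np.ndarray
    feature_pooled_sd: np.ndarray
    gamma_star: np.ndarray  # site x feature location
    delta_star: np.ndarray  # site x feature scale (variance)
    parametric: bool


def two_sample_t(values_a, values_b, metric_name: str = "") -> GroupComparison:
    """Pooled-variance (Student) two-sample t test, two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    df = na + nb - 2
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            t = 0.0
            p = 1.0
        else:
            raise ValueError("zero pooled variance with unequal means")
    else:
        t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
        p = float(2 * sps.t.sf(abs(t), df))
    d, ci = cohens_d_ci(a.mean(), a.std(ddof=1), na, b.mean(), b.std(ddof=1), nb)
    return GroupComparison(
        metric_name=metric_name,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=na,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=nb,
        t_statistic=t,
        df=df,
        p_value=p,
        cohens_d=d,
        ci95=ci,
    )


def cohens_d_ci(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, tuple[float, float]]:
    """Pooled-SD Cohen's d and its normal-approximation 95% CI.

    d = (mean_a - mean_b) / sd_pooled with
    sd_pooled = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2)),
    CI = d +/- 1.96 * sqrt((n_a+n_b)/(n_a*n_b) + d^2 / (2 (n_a+n_b))).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 observations per group")
    if sd_a < 0 or sd_b < 0 or (sd_a == 0 and sd_b == 0):
        raise ValueError("standard deviations must be positive")
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    d = float((mean_a - mean_b) / sp)
    n = n_a + n_b
    se = np.sqrt(n / (n_a * n_b) + d**2 / (2 * n))
    return d, (float(d - 1.96 * se), float(d + 1.96 * se))


def chi_square_test(contingency) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction; df = (r-1)(c-1)."""
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    reject = adj <= alpha
    return adj, reject


def spearman(x, y, pair=("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties; t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("cannot rank-correlate a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(variable_pair=tuple(pair), rho=float(rho), p_value=float(p), n=x.size)


# ---------------------------------------------------------------------------
# ComBat harmonization


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_site, g_hat, d_hat, g_bar, tau2, a, b, tol=1e-6, max_iter=500):
    """Iterate conditional posterior updates for one site until convergence."""
    n = z_site.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * g_hat + d_old * g_bar) / (n * tau2 + d_old)
        sum2 = ((z_site - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_fit_apply(
    features: np.ndarray,
    batch,
    covariates: np.ndarray | None = None,
    parametric: bool = True,
) -> tuple[np.ndarray, CombatModel]:
    """Remove site location/scale effects from a subjects x features table.

    Features are standardized against the covariate-adjusted grand mean and
    pooled SD; per-site location (gamma) and scale (delta) estimates are
    shrunk with parametric empirical-Bayes priors (normal / inverse-gamma,
    moment-matched hyperparameters, conditional updates iterated to 1e-6) and
    removed; covariate effects are restored.  With a single site the input is
    returned unchanged.  A site with fewer than 2 subjects is an error.

    With a single feature there is no across-feature information to estimate
    priors from, so the raw site estimates are used (no shrinkage); a warning
    is logged.
    """
    y = np.asarray(features, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if not np.all(np.isfinite(y)):
        raise ValueError("features must be complete (no NaN/inf)")
    batch = np.asarray(batch)
    n_subj, n_feat = y.shape
    if batch.shape[0] != n_subj:
        raise ValueError("batch length does not match subject count")
    sites, site_idx = np.unique(batch, return_inverse=True)
    counts = np.bincount(site_idx)
    for s, c in zip(sites, counts):
        if c < 2:
            raise ValueError(f"site {s!r} has fewer than 2 subjects")
    if len(sites) < 2:
        logger.info("single site; harmonization is the identity")
        model = CombatModel(
            batch_labels=tuple(batch.tolist()),
            site_names=tuple(sites.tolist()),
            feature_grand_mean=y.mean(axis=0),
            feature_pooled_sd=y.std(axis=0, ddof=1),
            gamma_star=np.zeros((1, n_feat)),
            delta_star=np.ones((1, n_feat)),
            parametric=parametric,
        )
        return y.copy(), model

    n_batch = len(sites)
    batch_design = np.eye(n_batch)[site_idx]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.hstack([batch_design, cov])
    else:
        cov = None
        design = batch_design

    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    grand_mean = (counts / n_subj) @ b_hat[:n_batch]
    stand_mean = np.tile(grand_mean, (n_subj, 1))
    if cov is not None:
        stand_mean = stand_mean + cov @ b_hat[n_batch:]
    resid = y - design @ b_hat
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled == 0):
        raise ValueError("a feature has zero residual variance; cannot standardize")
    sd_pooled = np.sqrt(var_pooled)
    z = (y - stand_mean) / sd_pooled

    gamma_star = np.empty((n_batch, n_feat))
    delta_star = np.empty((n_batch, n_feat))
    for k in range(n_batch):
        z_k = z[site_idx == k]
        g_hat = z_k.mean(axis=0)
        d_hat = z_k.var(axis=0, ddof=1)
        if parametric and n_feat >= 2:
            g_bar, tau2 = g_hat.mean(), g_hat.var(ddof=1)
            a_pr, b_pr = _aprior(d_hat), _bprior(d_hat)
            gamma_star[k], delta_star[k] = _it_sol(z_k, g_hat, d_hat, g_bar, tau2, a_pr, b_pr)
        else:
            if parametric and n_feat < 2:
                logger.warning("single feature: empirical-Bayes shrinkage skipped")
            gamma_star[k] = g_hat
            delta_star[k] = d_hat
    delta_star = np.maximum(delta_star, 1e-12)

    z_adj = (z - gamma_star[site_idx]) / np.sqrt(delta_star[site_idx])
    y_adj = z_adj * sd_pooled + stand_mean

    model = CombatModel(
        batch_labels=tuple(batch.tolist()),
        site_names=tuple(sites.tolist()),
        feature_grand_mean=np.asarray(grand_mean, dtype=float).ravel(),
        feature_pooled_sd=sd_pooled,
        gamma_star=gamma_star,
        delta_star=delta_star,
        parametric=parametric,
    )
    return y_adj, model
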