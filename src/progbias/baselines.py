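"""Regression-slope comparator adjustments for collider bias.

Both comparators estimate the global bias slope ``b`` in
``beta*_GY = beta_GY + b * beta_GX`` from incidence-associated variants and
then subtract ``b_hat * beta_GX`` from every progression estimate:

* **Dudbridge (instrument-effect regression)** — OLS of the observed
  progression effects on the observed incidence effects (through the
  origin, as the structural equation has no constant term), optionally
  divided by the Hedges-Olkin reliability ``1 - mean(se_GX^2)/var(bhat_GX)``
  to undo regression dilution from measurement error in bhat_GX.  Valid
  when direct incidence and progression effects are uncorrelated.
* **Slope-Hunter style mixture** — a two-component zero-mean Gaussian
  mixture fitted by EM: a "hunted" component constrained to a line
  through the origin (slope b, i.e. correlation +/-1 up to residual
  noise), and a free-covariance pleiotropic component.  Valid under the
  zero-modal-residual assumption (the modal cluster of
  incidence-associated variants has no direct progression effect).
  Confidence intervals are percentile-bootstrapped over variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sumstats import AnalysisTable

logger = logging.getLogger(__name__)


class BaselineError(ValueError):
    """Estimation failure in a comparator method."""


@dataclass
class SlopeEstimate:
    """A global bias-slope estimate from any method."""

    method: str                       # dudbridge | dudbridge_ho | slopehunter | unadjusted
    b_hat: float
    b_se: float | None = None
    b_ci: tuple | None = None
    n_variants_used: int = 0
    diagnostics: dict = field(default_factory=dict)


@dataclass
class MethodResult:
    """Per-variant adjusted estimates produced by applying a slope.

    ``df`` columns: variant_id, estimate, se, ci_lower, ci_upper, p,
    significant (p < alpha).
    """

    df: pd.DataFrame
    slope: SlopeEstimate
    alpha: float = 0.05


def _selected(table: AnalysisTable, p_threshold: float) -> pd.DataFrame:
    sel = table.df.loc[table.df["p_inc"] < p_threshold]
    return sel


def fit_dudbridge(table: AnalysisTable, p_threshold: float = 1e-3,
                  hedges_olkin: bool = True, intercept: bool = False) -> SlopeEstimate:
    """Instrument-effect regression estimate of the bias slope.

    Regresses bhat*_GY on bhat_GX over variants with p_inc < p_threshold.
    With ``hedges_olkin`` the raw slope is divided by the reliability
    ``1 - mean(se_inc^2) / var(bhat_GX)``; a non-positive reliability
    (measurement error exceeding the observed spread) is an error.
    """
    sel = _selected(table, p_threshold)
    if len(sel) < 3:
        raise BaselineError(
            f"only {len(sel)} variants pass p_inc < {p_threshold}; need >= 3")
    x = sel["beta_inc"].to_numpy()
    y = sel["beta_prog"].to_numpy()
    design = sm.add_constant(x) if intercept else x[:, None]
    fit = sm.OLS(y, design).fit()
    b_raw = float(fit.params[-1])
    se_raw = float(fit.bse[-1])

    diagnostics = {"b_raw": b_raw, "se_raw": se_raw, "intercept": intercept}
    if hedges_olkin:
        reliability = 1.0 - np.mean(sel["se_inc"] ** 2) / np.var(x, ddof=1)
        diagnostics["reliability"] = float(reliability)
        if reliability <= 0:
            raise BaselineError(
                f"Hedges-Olkin reliability {reliability:.3f} <= 0: measurement "
                "error exceeds the observed variance of incidence effects")
        b_hat = b_raw / reliability
        b_se = se_raw / reliability
        method = "dudbridge_ho"
    else:
        b_hat, b_se, method = b_raw, se_raw, "dudbridge"
    ci = (b_hat - 1.96 * b_se, b_hat + 1.96 * b_se)
    return SlopeEstimate(method=method, b_hat=b_hat, b_se=b_se, b_ci=ci,
                         n_variants_used=len(sel), diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Slope-Hunter style constrained mixture


def _mixture_loglik(x, y, params):
    pi1, b, v1, e1, a11, a12, a22 = params
    # hunted: cov [[v1, b v1], [b v1, b^2 v1 + e1]]
    l1 = _bvn_logpdf(x, y, v1, b * v1, b * b * v1 + e1)
    l2 = _bvn_logpdf(x, y, a11, a12, a22)
    return np.logaddexp(np.log(pi1) + l1, np.log1p(-pi1) + l2)


def _bvn_logpdf(x, y, c11, c12, c22):
    det = c11 * c22 - c12 * c12
    if det <= 0 or c11 <= 0:
        return np.full_like(x, -np.inf)
    quad = (c22 * x * x - 2.0 * c12 * x * y + c11 * y * y) / det
    return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def _em_once(x, y, resp_init, max_iter=500, tol=1e-8):
    """Run EM from an initial responsibility vector; returns (params, loglik)."""
    w = np.clip(resp_init, 1e-6, 1 - 1e-6)
    prev_ll = -np.inf
    params = None
    for _ in range(max_iter):
        # M-step
        pi1 = float(np.mean(w))
        if pi1 < 0.01 or pi1 > 0.99:
            raise BaselineError("degenerate mixture weight")
        sw = w.sum()
        sxx = float((w * x * x).sum())
        sxy = float((w * x * y).sum())
        if sxx <= 0:
            raise BaselineError("degenerate hunted component")
        b = sxy / sxx
        v1 = sxx / sw
        e1 = float((w * (y - b * x) ** 2).sum()) / sw
        e1 = max(e1, 1e-12)
        w2 = 1.0 - w
        sw2 = w2.sum()
        a11 = float((w2 * x * x).sum()) / sw2
        a12 = float((w2 * x * y).sum()) / sw2
        a22 = float((w2 * y * y).sum()) / sw2
        # keep the free component non-singular
        det = a11 * a22 - a12 * a12
        if det <= 1e-14 * max(a11 * a22, 1e-30):
            a11 += 1e-8
            a22 += 1e-8
        params = (pi1, b, v1, e1, a11, a12, a22)
        # E-step
        l1 = np.log(pi1) + _bvn_logpdf(x, y, v1, b * v1, b * b * v1 + e1)
        l2 = np.log1p(-pi1) + _bvn_logpdf(x, y, a11, a12, a22)
        ll = float(np.logaddexp(l1, l2).sum())
        w = np.exp(l1 - np.logaddexp(l1, l2))
        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            break
        prev_ll = ll
    return params, ll, w


def _hunted_slope(params):
    """Pick the component representing the hunted (collinear) cluster.

    The EM labeling is arbitrary: the free-covariance component can
    capture the tight line while the line-constrained one absorbs the
    scatter.  The hunted cluster is the more collinear component; return
    its through-origin slope and mixture weight.
    """
    pi1, b, v1, e1, a11, a12, a22 = params
    corr1 = abs(b) * math.sqrt(v1) / math.sqrt(b * b * v1 + e1) if v1 > 0 else 0.0
    corr2 = abs(a12) / math.sqrt(a11 * a22) if a11 > 0 and a22 > 0 else 0.0
    if corr2 > corr1 and a11 > 0:
        return a12 / a11, 1.0 - pi1
    return b, pi1


def _slopehunter_point(x, y, rng, n_restarts=5):
    """Best-of-restarts EM point estimate of the hunted-component slope."""
    from sklearn.cluster import KMeans

    starts = []
    # k-means on the progression/incidence ratio; hunted component gets the
    # cluster with smaller residual spread around its through-origin fit
    ratio = np.clip(y / np.where(np.abs(x) < 1e-12, np.nan, x), -50, 50)
    ratio = np.nan_to_num(ratio, nan=np.nanmedian(ratio) if np.isfinite(np.nanmedian(ratio)) else 0.0)
    km = KMeans(n_clusters=2, n_init=3, random_state=int(rng.integers(2 ** 31)))
    lab = km.fit_predict(ratio[:, None])
    spreads = []
    for k in (0, 1):
        mask = lab == k
        if mask.sum() < 2 or (x[mask] ** 2).sum() <= 0:
            spreads.append(np.inf)
            continue
        bk = (x[mask] * y[mask]).sum() / (x[mask] ** 2).sum()
        spreads.append(np.var(y[mask] - bk * x[mask]))
    hunted = int(np.argmin(spreads))
    starts.append(np.where(lab == hunted, 0.9, 0.1))
    for _ in range(n_restarts):
        starts.append(rng.uniform(0.1, 0.9, size=len(x)))

    best = None
    for resp in starts:
        try:
            params, ll, w = _em_once(x, y, resp)
        except BaselineError:
            continue
        if best is None or ll > best[1]:
            best = (params, ll, w)
    if best is None:
        raise BaselineError("all EM starts degenerate")
    return best


def fit_slopehunter(table: AnalysisTable, p_threshold: float = 1e-3,
                    n_bootstrap: int = 200, n_restarts: int = 5,
                    seed: int = 0) -> SlopeEstimate:
    """Slope-Hunter style mixture estimate of the bias slope.

    Clusters incidence-selected variants into a hunted component (points
    near a common line through the origin) and a free pleiotropic
    component; the bias slope is the hunted line's slope from the best of
    multiple EM starts.  ``n_bootstrap`` percentile-bootstrap resamples of
    the selected variants give the confidence interval.
    """
    sel = _selected(table, p_threshold)
    if len(sel) < 10:
        raise BaselineError(
            f"only {len(sel)} variants pass p_inc < {p_threshold}; need >= 10")
    if n_bootstrap < 1:
        raise BaselineError("n_bootstrap must be >= 1")
    x = sel["beta_inc"].to_numpy()
    y = sel["beta_prog"].to_numpy()
    rng = np.random.default_rng(seed)

    (params, ll, w) = _slopehunter_point(x, y, rng, n_restarts=n_restarts)
    b_hat, pi1 = _hunted_slope(params)

    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(x), size=len(x))
        try:
            (bp, _, _) = _slopehunter_point(x[idx], y[idx], rng, n_restarts=2)
            boots.append(_hunted_slope(bp)[0])
        except BaselineError:
            continue
    boots = np.asarray(boots)
    if len(boots) >= max(10, n_bootstrap // 4):
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
        b_se = float(np.std(boots, ddof=1))
    else:
        ci, b_se = None, None
        logger.warning("slopehunter bootstrap mostly degenerate (%d/%d ok)",
                       len(boots), n_bootstrap)
    return SlopeEstimate(
        method="slopehunter", b_hat=float(b_hat), b_se=b_se, b_ci=ci,
        n_variants_used=len(sel),
        diagnostics={"mixture_weight_hunted": float(pi1), "loglik": float(ll),
                     "responsibilities_mean": float(np.mean(w)),
                     "n_bootstrap_ok": int(len(boots))})


def unadjusted_slope() -> SlopeEstimate:
    """The no-adjustment reference: slope exactly zero."""
    return SlopeEstimate(method="unadjusted", b_hat=0.0, b_se=0.0, b_ci=(0.0, 0.0))


def apply_slope(table: AnalysisTable, slope: SlopeEstimate,
                alpha: float = 0.05) -> MethodResult:
    """De-bias progression estimates with a fitted slope.

    adjusted beta_i = bhat*_GY_i - b_hat * bhat_GX_i
    adjusted se_i   = sqrt(se_prog^2 + b_hat^2 se_inc^2 + bhat_GX^2 se_b^2)

    (the slope-uncertainty term is dropped when ``slope.b_se`` is missing);
    two-sided normal p-values, significance at ``alpha``.
    """
    if not np.isfinite(slope.b_hat):
        raise BaselineError("slope estimate is not finite")
    df = table.df
    b = slope.b_hat
    est = df["beta_prog"] - b * df["beta_inc"]
    var = df["se_prog"] ** 2 + b * b * df["se_inc"] ** 2
    if slope.b_se is not None:
        var = var + df["beta_inc"] ** 2 * slope.b_se ** 2
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "variant_id": df["variant_id"],
        "estimate": est,
        "se": se,
        "ci_lower": est - 1.96 * se,
        "ci_upper": est + 1.96 * se,
        "p": p,
        "significant": (p < alpha).astype(int),
    })
    return MethodResult(df=out.reset_index(drop=True), slope=slope, alpha=alpha)
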