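"""Hierarchical Bayesian bias-reduction model for progression GWAS.

Model (per variant i, all estimates treated with known SEs):

    bhat*_GYi ~ N(beta_GYi + b * beta_GXi, se_prog_i^2)
    bhat_GXi  ~ N(beta_GXi, se_inc_i^2)
    (beta_GXi, beta_GYi) ~ N((mu, 0), [[s_x^2,             rho_i s_x phi_i tau],
                                       [rho_i s_x phi_i tau, phi_i^2 tau^2    ]])

with a horseshoe prior on the direct progression effects (local scales
phi_i ~ Cauchy+(0,1), global scale tau ~ Cauchy+(0,1)), per-variant
correlation rho_i = 2 r_i - 1 with r_i ~ Beta(3,1) (prior mass on strong
positive correlation), b ~ Uniform(-10, 10), mu ~ N(0,1) and
s_x^2 ~ N+(0,1).  ``b`` soaks up the collider-bias path (plus any residual
direct incidence->progression effect), so the posterior for beta_GYi is a
bias-reduced estimate of the direct genetic effect on progression.

Sampling uses a collapsed Metropolis-within-Gibbs scheme: the bivariate
effect pair is integrated out of the likelihood analytically, scale and
correlation parameters are updated by adaptive random-walk Metropolis on
the collapsed posterior (vectorized across variants and chains), and the
progression effects are then drawn exactly from their Gaussian full
conditional.  Collapsing removes the funnel geometry that makes horseshoe
posteriors hard for uncollapsed one-at-a-time samplers.  Because chains
never interact, many replicate datasets can be fitted in one vectorized
run (:func:`fit_mr_horse_many`) by stacking them as extra chain rows.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, ndtri

from .sumstats import AnalysisTable

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)
# transformed-scale bounds; the prior mass excluded is negligible (< 1e-8
# for the half-Cauchy scales) but they keep the collapsed covariance
# numerically positive definite
_U_BOUND = 20.0    # |log phi|, |log tau|, |log s_x|
_V_BOUND = 12.0    # |logit r|, keeps 1 - rho^2 > ~2e-5
_ADAPT_TARGET = 0.44


class HorseModelError(ValueError):
    """Invalid input or configuration for the bias-reduction model."""


@dataclass
class HorseModelConfig:
    """Prior hyperparameters and MCMC settings.

    Defaults follow the published prior choices for kidney-disease traits:
    Beta(3,1) on r (rho = 2r - 1 concentrated on strong positive
    correlation), unit half-Cauchy shrinkage scales, flat b on (-10, 10),
    4 chains of 15,000 iterations with 20% burn-in.
    """

    rho_beta_a: float = 3.0
    rho_beta_b: float = 1.0
    tau_scale: float = 1.0
    phi_scale: float = 1.0
    b_lower: float = -10.0
    b_upper: float = 10.0
    mu_prior_sd: float = 1.0
    sx2_prior_scale: float = 1.0
    prior_family_gy: str = "horseshoe"   # or "normal" (sensitivity mode)
    normal_sd: float = 0.1               # used when prior_family_gy == "normal"
    n_chains: int = 4
    n_iterations: int = 15_000
    burn_in_fraction: float = 0.20
    max_stored_per_chain: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b_lower >= self.b_upper:
            raise HorseModelError("b_lower must be < b_upper")
        for name in ("rho_beta_a", "rho_beta_b", "tau_scale", "phi_scale",
                     "mu_prior_sd", "sx2_prior_scale", "normal_sd"):
            if getattr(self, name) <= 0:
                raise HorseModelError(f"{name} must be positive")
        if not (0.0 < self.burn_in_fraction < 1.0):
            raise HorseModelError("burn_in_fraction must be in (0, 1)")
        if self.n_chains < 2:
            raise HorseModelError("need at least 2 chains for convergence diagnostics")
        if self.prior_family_gy not in ("horseshoe", "normal"):
            raise HorseModelError("prior_family_gy must be 'horseshoe' or 'normal'")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorSummary:
    """Posterior summaries for the progression effects and global parameters.

    ``df`` columns: variant_id, estimate (posterior mean), post_median,
    ci_lower, ci_upper (equal-tailed 95%), post_sd, rhat, ess, significant
    (1 when the credible interval excludes 0).  ``global_summary`` rows:
    b, tau, mu, s_x with mean/median/CI/rhat/ess.  ``b_draws`` keeps the
    pooled post-burn-in draws of b for downstream uncertainty propagation.
    """

    df: pd.DataFrame
    global_summary: pd.DataFrame
    b_draws: np.ndarray
    config: HorseModelConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def b_mean(self) -> float:
        return float(self.global_summary.loc["b", "mean"])

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def select_variants(table: AnalysisTable, p_threshold: float) -> AnalysisTable:
    """Subset to variants associated with incidence at ``p_inc < p_threshold``."""
    if table.df["p_inc"].isna().any():
        raise HorseModelError("p_inc missing for some records")
    keep = table.df["p_inc"] < p_threshold
    if not keep.any():
        raise HorseModelError(
            f"no variants pass p_inc < {p_threshold}; minimum p_inc is "
            f"{table.df['p_inc'].min():.3g} — loosen the threshold")
    return AnalysisTable(df=table.df.loc[keep].reset_index(drop=True),
                         provenance=dict(table.provenance), counts=table.counts)


# ---------------------------------------------------------------------------
# convergence diagnostics: rank-normalized split-Rhat and bulk ESS
# (Vehtari et al. conventions), vectorized over a trailing variant axis


def _basic_rhat(x: np.ndarray) -> np.ndarray:
    """Classic potential-scale-reduction on shape (chains, draws, ...)."""
    c, n = x.shape[0], x.shape[1]
    chain_mean = x.mean(axis=1)
    chain_var = x.var(axis=1, ddof=1)
    w = chain_var.mean(axis=0)
    b = n * chain_mean.var(axis=0, ddof=1)
    degenerate = w <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * w + b / n
        rhat = np.sqrt(var_hat / w)
    return np.where(degenerate, 1.0, rhat)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Normal scores of pooled ranks, applied along (chain, draw) jointly."""
    c, n = x.shape[0], x.shape[1]
    flat = x.reshape(c * n, *x.shape[2:])
    ranks = stats.rankdata(flat, axis=0, method="average")
    return ndtri((ranks - 0.375) / (c * n + 0.25)).reshape(x.shape)


def _split_chains(x: np.ndarray) -> np.ndarray:
    n = x.shape[1] - (x.shape[1] % 2)
    half = n // 2
    return np.concatenate([x[:, :half], x[:, half:n]], axis=0)


def _split_rhat_rank(x: np.ndarray) -> np.ndarray:
    """Rank-normalized split-Rhat for draws of shape (chains, draws, ...)."""
    xs = _split_chains(np.asarray(x, dtype=np.float64))
    # zero-variance chains: rank normalization would inject spurious
    # variation, so report 1.0 by convention (warned in compute_rhat)
    ptp = xs.max(axis=(0, 1)) - xs.min(axis=(0, 1))
    bulk = _basic_rhat(_rank_normalize(xs))
    folded = np.abs(xs - np.median(xs, axis=(0, 1), keepdims=True))
    tail = _basic_rhat(_rank_normalize(folded))
    out = np.maximum(bulk, tail)
    return np.where(ptp <= 0, 1.0, out)


def compute_rhat(chains) -> float:
    """Rank-normalized split-Rhat for one scalar parameter.

    ``chains``: array-like of shape (n_chains, n_draws), post burn-in.
    Chains with zero variance return 1.0 by convention (warned).
    """
    x = np.asarray(chains, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise HorseModelError("compute_rhat needs >= 2 chains of draws")
    if x.shape[1] < 10:
        raise HorseModelError("compute_rhat needs >= 10 draws per chain")
    if np.ptp(x) <= 0:
        warnings.warn("all chains constant; returning Rhat = 1.0 by convention",
                      stacklevel=2)
        return 1.0
    # the finite-sample estimator can dip to sqrt((n-1)/n) below 1;
    # anything <= 1 means "no evidence of non-convergence", reported as 1
    return float(max(_split_rhat_rank(x[:, :, None])[0], 1.0))


def _ess_bulk(x: np.ndarray) -> np.ndarray:
    """Bulk effective sample size on (chains, draws, ...), vectorized.

    Rank-normalized split chains; per-chain autocovariance by FFT; Geyer
    initial-positive-sequence truncation with the monotone correction.
    """
    z = _rank_normalize(_split_chains(np.asarray(x, dtype=np.float64)))
    c, n = z.shape[0], z.shape[1]
    zc = z - z.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(zc, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :n].real / n

    chain_var = acov[:, 0] * n / (n - 1.0)
    w = chain_var.mean(axis=0)
    var_hat = (n - 1.0) / n * w + z.mean(axis=1).var(axis=0, ddof=1)
    mean_acov = acov.mean(axis=0)                     # (draws, ...)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 1.0 - (w - mean_acov) / var_hat         # rho[0] == 1
    t_max = (n // 2) * 2
    # Geyer pairs P_k = rho_{2k} + rho_{2k+1}; truncate at the first
    # non-positive pair, then enforce monotone non-increase
    pair = rho[0:t_max:2] + rho[1:t_max:2]
    positive = np.logical_and.accumulate(pair > 0, axis=0)
    pair = np.minimum.accumulate(pair, axis=0)   # monotone non-increasing
    pair = np.where(positive, pair, 0.0)         # zero beyond the truncation point
    tau = -1.0 + 2.0 * pair.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ess = c * n / np.maximum(tau, 1e-3)
    ess = np.minimum(ess, float(c * n))
    degenerate = ~np.isfinite(var_hat) | (var_hat <= 0)
    return np.where(degenerate, float(c * n), ess)


# ---------------------------------------------------------------------------
# collapsed posterior machinery


def _marginal_loglik(bx, by, sx2o, sy2o, phi, r, tau, sx, b, mu):
    """Per-variant log-likelihood with the effect pair integrated out.

    Marginally (bhat_GX, bhat*_GY) is bivariate normal with mean
    (mu, b*mu) and covariance A Sigma A' + diag(se^2), A = [[1,0],[b,1]].
    Data arrays of shape (rows, m) broadcast against parameter arrays of
    shape (rows, m) (per-variant) or (rows, 1) (global).
    """
    rho = 2.0 * r - 1.0
    sx2 = sx * sx
    c = rho * sx * phi * tau
    t2 = (phi * tau) ** 2
    m11 = sx2 + sx2o
    m12 = b * sx2 + c
    m22 = b * b * sx2 + 2.0 * b * c + t2 + sy2o
    d1 = bx - mu
    d2 = by - b * mu
    det = m11 * m22 - m12 * m12
    quad = m22 * d1 * d1 - 2.0 * m12 * d1 * d2 + m11 * d2 * d2
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad / det


def _lp_log_halfcauchy(u, scale):
    # log prior density of x = exp(u) ~ Cauchy+(0, scale), plus Jacobian u
    x2 = np.exp(2.0 * u)
    out = u - np.log1p(x2 / (scale * scale))
    return np.where(np.abs(u) > _U_BOUND, -np.inf, out)


def _lp_logit_beta(v, a, b):
    # r = expit(v) ~ Beta(a, b); Jacobian r(1-r) folds into the exponents
    out = -(a + b) * np.logaddexp(0.0, -v) - b * v
    return np.where(np.abs(v) > _V_BOUND, -np.inf, out)


def _lp_log_sx(w, scale):
    # s_x^2 = exp(2w) ~ N+(0, scale^2); Jacobian d(s_x^2)/dw = 2 exp(2w)
    s2 = np.exp(2.0 * w)
    out = -0.5 * (s2 / scale) ** 2 + np.log(s2)
    return np.where(np.abs(w) > _U_BOUND, -np.inf, out)


def _draw_beta_gy(bx, by, sx2o, sy2o, phi, r, tau, sx, b, mu, rng):
    """Exact draw of beta_GY from its Gaussian full conditional."""
    rho = 2.0 * r - 1.0
    sx2 = sx * sx
    t2 = (phi * tau) ** 2
    c = rho * sx * phi * tau
    det_s = sx2 * t2 - c * c
    det_s = np.maximum(det_s, 1e-300)
    p11 = t2 / det_s + 1.0 / sx2o + b * b / sy2o
    p12 = -c / det_s + b / sy2o
    p22 = sx2 / det_s + 1.0 / sy2o
    h1 = t2 * mu / det_s + bx / sx2o + b * by / sy2o
    h2 = -c * mu / det_s + by / sy2o
    det_p = p11 * p22 - p12 * p12
    mean = (p11 * h2 - p12 * h1) / det_p
    var = p11 / det_p
    return mean + np.sqrt(var) * rng.standard_normal(mean.shape)


class _AdaptiveScale:
    """Robbins-Monro adaptation of a random-walk proposal scale (frozen
    after burn-in)."""

    def __init__(self, shape, init=0.5):
        self.log_s = np.full(shape, math.log(init))

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted, t):
        gamma = (t + 1.0) ** -0.6
        self.log_s += gamma * (np.asarray(accepted, dtype=float) - _ADAPT_TARGET)
        np.clip(self.log_s, -8.0, 4.0, out=self.log_s)


def _run_sampler(bx_b, sx2o_b, by_b, sy2o_b, config: HorseModelConfig,
                 fixed_globals: dict | None = None):
    """Run the collapsed Gibbs sampler on stacked rows.

    Data arrays have shape (rows, m) where rows = n_datasets * n_chains;
    every row is an independent chain (rows sharing a dataset share data).
    ``fixed_globals`` (b, tau, mu, s_x) switches to the conditional scoring
    pass: global parameters are held fixed and only per-variant parameters
    are sampled.  Returns post-burn-in draws.
    """
    cfg = config
    rows, m = bx_b.shape
    rng = np.random.default_rng(cfg.seed)
    normal_mode = cfg.prior_family_gy == "normal"
    scoring = fixed_globals is not None

    n_iter = cfg.n_iterations
    burn = int(round(cfg.burn_in_fraction * n_iter))
    kept = n_iter - burn
    thin = max(1, math.ceil(kept / cfg.max_stored_per_chain))
    n_stored = (kept + thin - 1) // thin

    # --- initial state (overdispersed across chains) ---
    if scoring:
        b = np.full((rows, 1), fixed_globals["b"])
        mu = np.full((rows, 1), fixed_globals["mu"])
        sx = np.full((rows, 1), fixed_globals["s_x"])
        tau = np.full((rows, 1), fixed_globals["tau"])
    else:
        denom = (bx_b * bx_b).sum(axis=1, keepdims=True)
        slope = np.where(denom > 0, (bx_b * by_b).sum(axis=1, keepdims=True)
                         / np.maximum(denom, 1e-300), 0.0)
        b = slope + (0.5 * np.abs(slope) + 0.1) * rng.standard_normal((rows, 1))
        b = np.clip(b, cfg.b_lower + 1e-6, cfg.b_upper - 1e-6)
        sd_bx = bx_b.std(axis=1, keepdims=True)
        mu = bx_b.mean(axis=1, keepdims=True) \
            + 0.1 * (sd_bx + 1e-6) * rng.standard_normal((rows, 1))
        sx = np.maximum(sd_bx, 1e-3) * np.exp(0.3 * rng.standard_normal((rows, 1)))
        tau = 0.05 * np.exp(0.7 * rng.standard_normal((rows, 1))) + 1e-4
    if normal_mode:
        tau = np.full((rows, 1), cfg.normal_sd)
        phi = np.ones((rows, m))
    else:
        phi = np.exp(0.5 * rng.standard_normal((rows, m)))
    r = np.clip(rng.beta(cfg.rho_beta_a, cfg.rho_beta_b, size=(rows, m)),
                expit(-_V_BOUND), expit(_V_BOUND))

    u = np.log(phi)
    v = logit(r)
    w_tau = np.log(tau)
    w_sx = np.log(sx)

    ll = _marginal_loglik(bx_b, by_b, sx2o_b, sy2o_b, phi, r, tau, sx, b, mu)

    s_phi = _AdaptiveScale((rows, m), 0.8)
    s_r = _AdaptiveScale((rows, m), 1.0)
    s_tau = _AdaptiveScale((rows, 1), 0.3)
    s_sx = _AdaptiveScale((rows, 1), 0.2)
    s_b = _AdaptiveScale((rows, 1), 0.2)
    s_mu = _AdaptiveScale((rows, 1), 0.2)

    draws_gy = np.empty((rows, n_stored, m), dtype=np.float32)
    draws_glob = {k: np.empty((rows, kept)) for k in ("b", "tau", "mu", "s_x")}
    store_idx = 0

    def scalar_update(value, log_prior, adapt, transform):
        """Per-row random-walk update of a global on the collapsed posterior."""
        nonlocal ll
        prop = value + adapt.scale * rng.standard_normal((rows, 1))
        ll_prop = _marginal_loglik(bx_b, by_b, sx2o_b, sy2o_b, *transform(prop))
        log_acc = (ll_prop.sum(axis=1) - ll.sum(axis=1)
                   + log_prior(prop)[:, 0] - log_prior(value)[:, 0])
        acc = np.log(rng.random(rows)) < log_acc
        ll = np.where(acc[:, None], ll_prop, ll)
        return np.where(acc[:, None], prop, value), acc[:, None]

    # out-of-bound proposals carry -inf prior mass; the likelihood may then
    # evaluate to nan, which compares False and is correctly rejected
    old_err = np.seterr(invalid="ignore", over="ignore")
    for it in range(n_iter):
        adapting = it < burn

        if not normal_mode:
            # local shrinkage scales phi_i (vectorized elementwise MH)
            u_prop = u + s_phi.scale * rng.standard_normal((rows, m))
            ll_prop = _marginal_loglik(bx_b, by_b, sx2o_b, sy2o_b,
                                       np.exp(u_prop), r, tau, sx, b, mu)
            log_acc = (ll_prop - ll
                       + _lp_log_halfcauchy(u_prop, cfg.phi_scale)
                       - _lp_log_halfcauchy(u, cfg.phi_scale))
            acc = np.log(rng.random((rows, m))) < log_acc
            u = np.where(acc, u_prop, u)
            ll = np.where(acc, ll_prop, ll)
            phi = np.exp(u)
            if adapting:
                s_phi.update(acc, it)

        # per-variant correlations rho_i = 2 expit(v_i) - 1
        v_prop = v + s_r.scale * rng.standard_normal((rows, m))
        ll_prop = _marginal_loglik(bx_b, by_b, sx2o_b, sy2o_b,
                                   phi, expit(v_prop), tau, sx, b, mu)
        log_acc = (ll_prop - ll
                   + _lp_logit_beta(v_prop, cfg.rho_beta_a, cfg.rho_beta_b)
                   - _lp_logit_beta(v, cfg.rho_beta_a, cfg.rho_beta_b))
        acc = np.log(rng.random((rows, m))) < log_acc
        v = np.where(acc, v_prop, v)
        ll = np.where(acc, ll_prop, ll)
        r = expit(v)
        if adapting:
            s_r.update(acc, it)

        if not scoring:
            if not normal_mode:
                w_tau, acc = scalar_update(
                    w_tau, lambda x: _lp_log_halfcauchy(x, cfg.tau_scale), s_tau,
                    transform=lambda x: (phi, r, np.exp(x), sx, b, mu))
                tau = np.exp(w_tau)
                if adapting:
                    s_tau.update(acc, it)

            w_sx, acc = scalar_update(
                w_sx, lambda x: _lp_log_sx(x, cfg.sx2_prior_scale), s_sx,
                transform=lambda x: (phi, r, tau, np.exp(x), b, mu))
            sx = np.exp(w_sx)
            if adapting:
                s_sx.update(acc, it)

            b, acc = scalar_update(
                b, lambda x: np.where((x > cfg.b_lower) & (x < cfg.b_upper), 0.0, -np.inf),
                s_b, transform=lambda x: (phi, r, tau, sx, x, mu))
            if adapting:
                s_b.update(acc, it)

            mu, acc = scalar_update(
                mu, lambda x: -0.5 * (x / cfg.mu_prior_sd) ** 2, s_mu,
                transform=lambda x: (phi, r, tau, sx, b, x))
            if adapting:
                s_mu.update(acc, it)

        if it >= burn:
            k = it - burn
            draws_glob["b"][:, k] = b[:, 0]
            draws_glob["tau"][:, k] = tau[:, 0]
            draws_glob["mu"][:, k] = mu[:, 0]
            draws_glob["s_x"][:, k] = sx[:, 0]
            if k % thin == 0:
                draws_gy[:, store_idx, :] = _draw_beta_gy(
                    bx_b, by_b, sx2o_b, sy2o_b, phi, r, tau, sx, b, mu, rng)
                store_idx += 1

    np.seterr(**old_err)
    return {"beta_gy": draws_gy[:, :store_idx, :],
            "globals": draws_glob, "thin": thin}


def _validate_table(df: pd.DataFrame):
    if len(df) < 3:
        raise HorseModelError("model needs at least 3 variants")
    vals = df[["beta_inc", "se_inc", "beta_prog", "se_prog"]].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise HorseModelError("non-finite beta/SE in input table")
    if np.any(vals[:, 1] <= 0) or np.any(vals[:, 3] <= 0):
        raise HorseModelError("all SEs must be positive")
    return (vals[:, 0], vals[:, 1] ** 2, vals[:, 2], vals[:, 3] ** 2)


def _summarize(gy: np.ndarray, glob: dict, variant_ids, config: HorseModelConfig,
               thin: int, fixed_globals: dict | None) -> PosteriorSummary:
    """Build a PosteriorSummary from draws of one dataset.

    ``gy``: (chains, stored, m) progression-effect draws;
    ``glob``: name -> (chains, kept) global-parameter draws.
    """
    cc, s, m = gy.shape
    gy64 = gy.astype(np.float64)
    pooled = gy64.reshape(cc * s, m)
    ci_lo, med, ci_hi = np.quantile(pooled, [0.025, 0.5, 0.975], axis=0)
    summary_df = pd.DataFrame({
        "variant_id": np.asarray(variant_ids),
        "estimate": pooled.mean(axis=0),
        "post_median": med,
        "ci_lower": ci_lo,
        "ci_upper": ci_hi,
        "post_sd": pooled.std(axis=0, ddof=1),
        "rhat": np.maximum(_split_rhat_rank(gy64), 1.0),
        "ess": _ess_bulk(gy64),
        "significant": ((ci_lo > 0) | (ci_hi < 0)).astype(int),
    })

    rows = {}
    for name, d in glob.items():
        flat = d.reshape(-1)
        if fixed_globals is not None:
            rows[name] = {"mean": flat[0], "median": flat[0], "ci_lower": flat[0],
                          "ci_upper": flat[0], "sd": 0.0, "rhat": np.nan, "ess": np.nan}
            continue
        gq = np.quantile(flat, [0.025, 0.5, 0.975])
        rows[name] = {
            "mean": float(flat.mean()),
            "median": float(gq[1]),
            "ci_lower": float(gq[0]),
            "ci_upper": float(gq[2]),
            "sd": float(flat.std(ddof=1)),
            "rhat": float(max(_split_rhat_rank(d[:, :, None])[0], 1.0)),
            "ess": float(_ess_bulk(d[:, :, None])[0]),
        }
    return PosteriorSummary(
        df=summary_df,
        global_summary=pd.DataFrame(rows).T,
        b_draws=glob["b"].reshape(-1).copy(),
        config=config,
        diagnostics={"thin": thin, "n_stored_per_chain": s,
                     "fixed_globals": fixed_globals})


def fit_mr_horse(table: AnalysisTable, config: HorseModelConfig | None = None,
                 fixed_globals: dict | None = None) -> PosteriorSummary:
    """Fit the bias-reduction model and summarize the posterior.

    Parameters
    ----------
    table
        Harmonized incidence/progression summary statistics.
    config
        Priors and MCMC settings (defaults: :class:`HorseModelConfig`).
    fixed_globals
        Optional dict with keys ``b, tau, mu, s_x``: hold the global
        parameters fixed and sample only per-variant parameters (the
        conditional scoring pass used to estimate effects for variants
        outside the incidence-selected fitting set).

    Returns a :class:`PosteriorSummary`; a variant is flagged significant
    when its equal-tailed 95% credible interval excludes zero.
    """
    return fit_mr_horse_many([table], config, fixed_globals=fixed_globals)[0]


def fit_mr_horse_many(tables, config: HorseModelConfig | None = None,
                      fixed_globals: dict | None = None) -> list:
    """Fit the model independently to several same-size tables in one
    vectorized sampler run.

    Replicate datasets are stacked as extra chain rows (chains never
    interact), which amortizes per-iteration overhead when scoring many
    simulation replicates.  Returns one :class:`PosteriorSummary` per
    table, in order.
    """
    config = config or HorseModelConfig()
    if not tables:
        raise HorseModelError("no tables given")
    data = [_validate_table(t.df) for t in tables]
    m = len(data[0][0])
    if any(len(d[0]) != m for d in data):
        raise HorseModelError("all tables must have the same number of variants")
    cc = config.n_chains
    nrep = len(tables)

    def stack(j):
        arr = np.stack([d[j] for d in data])          # (nrep, m)
        return np.repeat(arr, cc, axis=0)             # (nrep*chains, m)

    out = _run_sampler(stack(0), stack(1), stack(2), stack(3), config,
                       fixed_globals=fixed_globals)
    gy = out["beta_gy"]
    kept = out["globals"]["b"].shape[1]
    summaries = []
    for i, t in enumerate(tables):
        sl = slice(i * cc, (i + 1) * cc)
        glob = {k: v[sl] for k, v in out["globals"].items()}
        summaries.append(_summarize(gy[sl], glob, t.df["variant_id"].to_numpy(),
                                    config, out["thin"], fixed_globals))
    return summaries


def fit_and_score(table: AnalysisTable, config: HorseModelConfig | None = None,
                  p_threshold: float = 1e-3) -> PosteriorSummary:
    """Two-pass fit: estimate globals on incidence-selected variants, then
    score every remaining variant conditionally.

    Genome-scale joint fitting is impractical, so the model is fitted on
    the subset with ``p_inc < p_threshold``; variants outside the subset
    get posterior summaries with b, tau, mu, s_x fixed at their posterior
    means.  Rows are returned in the original table order.
    """
    config = config or HorseModelConfig()
    selected = select_variants(table, p_threshold)
    first = fit_mr_horse(selected, config)
    rest_mask = ~table.df["variant_id"].isin(selected.df["variant_id"])
    if not rest_mask.any():
        return first
    rest = AnalysisTable(df=table.df.loc[rest_mask].reset_index(drop=True),
                         provenance=dict(table.provenance))
    fixed = {k: float(first.global_summary.loc[k, "mean"])
             for k in ("b", "tau", "mu", "s_x")}
    second = fit_mr_horse(rest, config, fixed_globals=fixed)
    merged = pd.concat([first.df, second.df], ignore_index=True)
    order = pd.Index(table.df["variant_id"])
    merged = merged.set_index("variant_id").loc[order].reset_index()
    return PosteriorSummary(df=merged, global_summary=first.global_summary,
                            b_draws=first.b_draws, config=config,
                            diagnostics={"two_pass": True,
                                         "n_selected": len(selected),
                                         "p_threshold": p_threshold})
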