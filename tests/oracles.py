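"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own posterior machinery: the
importance-sampling integrator evaluates the model's marginal likelihood
through generic linear algebra (matrix products and `numpy.linalg`
inverses) rather than the hand-expanded scalar formulas used by the
sampler, and draws every parameter from its prior (with a wide normal
proposal for the bias coefficient, weight-corrected).
"""

import numpy as np
from scipy import stats


def is_posterior_b(bx, sx, by, sy, n_samples=1_000_000, seed=7,
                   b_prop=(0.0, 1.5), batch=200_000,
                   rho_beta=(3.0, 1.0)):
    """Importance-sampling posterior mean/SD of the bias coefficient b.

    Effect pairs are integrated out exactly: given the scale parameters,
    the observed (bhat_GX, bhat*_GY) pair is bivariate normal with
    covariance A Sigma A' + diag(se^2).  Returns
    (mean, sd, ess, se_mean, se_sd).
    """
    rng = np.random.default_rng(seed)
    bx = np.asarray(bx, float)
    m = len(bx)
    data = np.stack([bx, by], axis=1)
    logws, bs = [], []
    for start in range(0, n_samples, batch):
        k = min(batch, n_samples - start)
        b = rng.normal(b_prop[0], b_prop[1], size=k)
        mu = rng.standard_normal(k)
        sx2p = np.abs(rng.standard_normal(k))        # s_x^2 ~ N+(0,1)
        tau = np.abs(stats.cauchy.rvs(size=k, random_state=rng))
        phi = np.abs(stats.cauchy.rvs(size=(k, m), random_state=rng))
        r = rng.beta(*rho_beta, size=(k, m))
        rho = 2.0 * r - 1.0
        sxp = np.sqrt(sx2p)
        pt = phi * tau[:, None]
        sig = np.empty((k, m, 2, 2))
        sig[..., 0, 0] = sx2p[:, None]
        sig[..., 0, 1] = sig[..., 1, 0] = rho * sxp[:, None] * pt
        sig[..., 1, 1] = pt ** 2
        amat = np.zeros((k, 2, 2))
        amat[:, 0, 0] = 1.0
        amat[:, 1, 0] = b
        amat[:, 1, 1] = 1.0
        cov = np.einsum("kab,kmbc,kdc->kmad", amat, sig, amat)
        cov[..., 0, 0] += np.asarray(sx) ** 2
        cov[..., 1, 1] += np.asarray(sy) ** 2
        mean = np.stack([np.broadcast_to(mu[:, None], (k, m)),
                         (b * mu)[:, None] * np.ones((k, m))], axis=-1)
        diff = data[None] - mean
        cov_inv = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
        quad = np.einsum("kmi,kmij,kmj->km", diff, cov_inv, diff)
        logw = (-np.log(2 * np.pi) - 0.5 * logdet - 0.5 * quad).sum(axis=1)
        logw += (np.where(np.abs(b) < 10, -np.log(20.0), -np.inf)
                 - stats.norm.logpdf(b, *b_prop))
        logws.append(logw)
        bs.append(b)
    logw = np.concatenate(logws)
    b = np.concatenate(bs)
    logw -= logw.max()
    w = np.exp(logw)
    sw = w.sum()
    ess = sw * sw / (w @ w)
    mean_b = (w @ b) / sw
    var_b = (w @ (b * b)) / sw - mean_b ** 2
    sd_b = np.sqrt(var_b)
    return mean_b, sd_b, ess, np.sqrt(var_b / ess), sd_b / np.sqrt(2 * ess)


def empirical_bias_slope(table, truth, on_observed=True):
    """Generative collider-bias slope on the observed (log-odds) scale.

    Regresses the observed cases-only progression estimates of
    incidence-only (GI) variants — whose direct progression effect is zero,
    so everything they show is bias — on the true liability-scale incidence
    effects, then rescales by the regression of observed incidence
    estimates on the same true effects.  Both regressors are error-free,
    so no measurement-error correction is needed.
    """
    m = table.df.merge(truth.df, on="variant_id")
    gi = m[m["cluster"] == "GI"]
    x_true = gi["beta_gx_true"].to_numpy()
    denom = float(x_true @ x_true)
    slope_liab = float(x_true @ gi["beta_prog"].to_numpy()) / denom
    if not on_observed:
        return slope_liab
    scale = float(x_true @ gi["beta_inc"].to_numpy()) / denom
    return slope_liab / scale
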