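"""Individual-level simulator of collider bias in progression GWAS.

The generative model: independent HWE genotypes; a continuous incidence
liability

    Inc_j = sum_i beta_GX_i G_ij + U_j + eps_I_j

with a standard-normal confounder ``U`` and noise variance chosen so the
genetic score explains ``h2_liability`` of the liability variance; a binary
disease indicator thresholding the liability at the empirical
(1 - prevalence) quantile; and a progression phenotype

    Prog_j = sum_i beta_GY_i G_ij + lambda * Inc_j + gamma * U_j + eps_P_j

whose genetic and noise components are rescaled so that, in the full
population, SNP heritability and the fraction of variance attributable to
``U`` both hit the midpoints of their configured ranges.  GWAS of the
binary incidence trait is run in the whole population (per-SNP logistic
regression) and GWAS of progression in cases only (per-SNP linear
regression): conditioning on case status opens the collider path through
``U`` and biases the progression estimates of incidence-associated SNPs.

Variants fall into four clusters: null (G0), incidence-only (GI),
progression-only (GP) and pleiotropic (GIP); pleiotropic effect pairs are
rank-correlated with coefficient ``rho`` via a Gaussian copula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .sumstats import AnalysisTable

CLUSTERS = ("G0", "GI", "GP", "GIP")


class SimulationError(ValueError):
    """Invalid simulation configuration or degenerate generative state."""


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the main simulated scenario.

    Cluster variance targets (``r2_*``) are absolute variance contributions
    on the phenotype scale before rescaling; for progression only their
    relative sizes matter because the genetic score is rescaled to the
    heritability target.  The pleiotropic cluster is given the larger
    progression target so that it explains more progression variance than
    the non-pleiotropic cluster.
    """

    n_individuals: int = 10_000
    n_snps: int = 2000
    frac_null: float = 0.95
    frac_inc_only: float = 0.01
    frac_prog_only: float = 0.01
    frac_pleio: float = 0.03
    rho: float = 0.7
    r2_inc_only: float = 0.5          # liability variance from the GI cluster
    r2_inc_pleio: float = 0.5         # liability variance from the GIP cluster
    r2_prog_nonpleio: float = 0.5     # relative progression target, GP cluster
    r2_prog_pleio: float = 2.0        # relative progression target, GIP cluster
    h2_liability: float = 0.40
    h2_prog_range: tuple = (0.30, 0.40)
    confounder_var_range: tuple = (0.30, 0.40)
    lambda_: float = 0.1
    gamma: float = 1.5
    prevalence: float = 0.40
    maf_range: tuple = (0.01, 0.49)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_null, self.frac_inc_only, self.frac_prog_only, self.frac_pleio)
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise SimulationError(f"cluster fractions must sum to 1, got {sum(fracs)!r}")
        if any(f < 0 for f in fracs):
            raise SimulationError("cluster fractions must be non-negative")
        if not (0.0 < self.prevalence < 1.0):
            raise SimulationError("prevalence must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5)")
        if not (-1.0 <= self.rho <= 1.0):
            raise SimulationError("rho must be in [-1, 1]")
        if not (0.0 < self.h2_liability < 1.0):
            raise SimulationError("h2_liability must be in (0, 1)")

    def cluster_counts(self) -> dict:
        """Integer variant counts per cluster (remainder goes to G0)."""
        m = self.n_snps
        n_gi = round(self.frac_inc_only * m)
        n_gp = round(self.frac_prog_only * m)
        n_gip = round(self.frac_pleio * m)
        n_g0 = m - n_gi - n_gp - n_gip
        if n_g0 < 0:
            raise SimulationError("cluster counts exceed n_snps")
        return {"G0": n_g0, "GI": n_gi, "GP": n_gp, "GIP": n_gip}

    def as_dict(self) -> dict:
        d = asdict(self)
        d["h2_prog_range"] = list(self.h2_prog_range)
        d["confounder_var_range"] = list(self.confounder_var_range)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class TrueEffects:
    """Per-variant ground truth plus the realized scaling constants.

    ``df`` columns: variant_id, maf, beta_gx_true (per-allele liability
    effect), beta_gy_true (per-allele direct progression effect), cluster.
    ``params`` records realized variances (liability, progression, noise
    terms, heritabilities) for downstream variance-explained computations.
    """

    df: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)
        # realized variance components ride along in a JSON side-car so
        # variance-explained fractions survive a round trip
        import json
        from pathlib import Path

        Path(str(path) + ".params.json").write_text(
            json.dumps(self.params, indent=2, default=float))

    @classmethod
    def read(cls, path) -> "TrueEffects":
        import json
        from pathlib import Path

        side = Path(str(path) + ".params.json")
        params = json.loads(side.read_text()) if side.exists() else {}
        return cls(df=pd.read_csv(path, sep="\t"), params=params)


def _halfnormal_r2_scale(cluster_r2: float, n_variants: int) -> float:
    # scale such that E[r2_i] = cluster_r2 / n: half-normal mean = scale*sqrt(2/pi)
    return cluster_r2 * math.sqrt(math.pi) / (n_variants * math.sqrt(2.0))


def draw_effect_sizes(n_variants: int, cluster_r2: float, mafs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Signed per-allele effects for one cluster.

    Per-variant variance contributions r2_i are half-normal with scale
    ``cluster_r2 * sqrt(pi) / (n * sqrt(2))`` (so the cluster sums to
    ``cluster_r2`` in expectation); the per-allele effect magnitude is
    ``sqrt(r2_i / (2 maf (1 - maf)))`` with a uniform random sign.
    """
    if cluster_r2 < 0:
        raise SimulationError("cluster_r2 must be non-negative")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (n_variants,):
        raise SimulationError("mafs must have length n_variants")
    if n_variants == 0 or cluster_r2 == 0.0:
        return np.zeros(n_variants)
    scale = _halfnormal_r2_scale(cluster_r2, n_variants)
    r2 = np.abs(rng.normal(0.0, scale, size=n_variants))
    signs = rng.choice([-1.0, 1.0], size=n_variants)
    return signs * np.sqrt(r2 / (2.0 * mafs * (1.0 - mafs)))


def draw_correlated_effect_sizes(n_variants: int, r2_x: float, r2_y: float,
                                 rho: float, mafs: np.ndarray,
                                 rng: np.random.Generator) -> tuple:
    """Rank-correlated (incidence, progression) effect pairs via a Gaussian copula.

    A bivariate standard normal with correlation ``rho`` is mapped through
    each margin's signed effect-size quantile function (random sign x
    half-normal r2), preserving rank correlation ~ rho between the signed
    effects.  Returns ``(beta_x, beta_y, realized_pearson)``.
    """
    if n_variants == 0:
        return np.zeros(0), np.zeros(0), np.nan
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n_variants, method="cholesky")
    u = stats.norm.cdf(z)  # in (0,1), rank-correlated

    def signed_quantile(u_col: np.ndarray, cluster_r2: float) -> np.ndarray:
        # symmetric signed margin: sign from u>0.5, magnitude from the
        # half-normal r2 quantile at |2u-1|
        scale = _halfnormal_r2_scale(cluster_r2, n_variants)
        mag_u = np.abs(2.0 * u_col - 1.0)
        r2 = stats.halfnorm.ppf(mag_u, scale=scale)
        return np.sign(u_col - 0.5) * np.sqrt(r2 / (2.0 * mafs * (1.0 - mafs)))

    bx = signed_quantile(u[:, 0], r2_x)
    by = signed_quantile(u[:, 1], r2_y)
    if n_variants > 2 and np.std(bx) > 0 and np.std(by) > 0:
        realized = float(np.corrcoef(bx, by)[0, 1])
    else:
        realized = np.nan
    return bx, by, realized


def simulate_genotypes(n_individuals: int, mafs: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Independent HWE genotypes: column i ~ i.i.d. Binomial(2, maf_i)."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise SimulationError("mafs must lie in (0, 0.5]")
    return rng.binomial(2, mafs, size=(n_individuals, len(mafs))).astype(np.float64)


def draw_true_effects(config: SimulationConfig, rng: np.random.Generator) -> TrueEffects:
    """Cluster assignment and raw (pre-rescaling) effect draws."""
    counts = config.cluster_counts()
    m = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    cluster = np.repeat(list(counts.keys()), list(counts.values()))
    perm = rng.permutation(m)
    cluster = cluster[perm]

    beta_gx = np.zeros(m)
    beta_gy = np.zeros(m)
    gi = cluster == "GI"
    gp = cluster == "GP"
    gip = cluster == "GIP"
    def normalize(beta, maf, target):
        # rescale the cluster so its variance contribution hits the target
        # exactly: half-normal draws keep their relative sizes but the
        # realized sum would otherwise fluctuate wildly in small clusters,
        # occasionally making the liability heritability budget infeasible
        realized = float((2.0 * maf * (1.0 - maf)) @ (beta ** 2))
        if realized <= 0 or target <= 0:
            return beta
        return beta * math.sqrt(target / realized)

    beta_gx[gi] = normalize(
        draw_effect_sizes(int(gi.sum()), config.r2_inc_only, mafs[gi], rng),
        mafs[gi], config.r2_inc_only)
    beta_gy[gp] = normalize(
        draw_effect_sizes(int(gp.sum()), config.r2_prog_nonpleio, mafs[gp], rng),
        mafs[gp], config.r2_prog_nonpleio)
    bx, by, realized_rho = draw_correlated_effect_sizes(
        int(gip.sum()), config.r2_inc_pleio, config.r2_prog_pleio,
        config.rho, mafs[gip], rng)
    beta_gx[gip] = normalize(bx, mafs[gip], config.r2_inc_pleio)
    beta_gy[gip] = normalize(by, mafs[gip], config.r2_prog_pleio)

    df = pd.DataFrame({
        "variant_id": [f"snp{i + 1:05d}" for i in range(m)],
        "maf": mafs,
        "beta_gx_true": beta_gx,
        "beta_gy_true": beta_gy,
        "cluster": cluster,
    })
    return TrueEffects(df=df, params={"realized_pleio_correlation": realized_rho})


def simulate_phenotypes(genotypes: np.ndarray, true_effects: TrueEffects,
                        config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Liability, binary incidence, progression and confounder values.

    Rescales the direct progression effects in-place in ``true_effects``
    (and records all realized variance components in ``params``) so that
    progression SNP heritability and the confounder variance fraction hit
    the midpoints of their configured ranges in the full population.
    """
    n, m = genotypes.shape
    te = true_effects.df
    beta_gx = te["beta_gx_true"].to_numpy()
    beta_gy_raw = te["beta_gy_true"].to_numpy()
    geno_var = genotypes.var(axis=0)

    g_inc = genotypes @ beta_gx
    var_g_inc = float(geno_var @ (beta_gx ** 2))
    if var_g_inc <= 0 and config.h2_liability > 0:
        raise SimulationError("no genetic variance on liability but h2_liability > 0")
    h2 = config.h2_liability
    # U ~ N(0,1) enters the liability with coefficient 1; solve the noise
    # variance so the genetic score explains exactly h2 of liability variance
    var_eps_i = var_g_inc * (1.0 - h2) / h2 - 1.0
    if var_eps_i < 0:
        raise SimulationError(
            f"liability genetic variance {var_g_inc:.3f} too small for "
            f"h2_liability={h2}: needs >= {h2 / (1 - h2):.3f}; raise r2_inc_* targets")
    u = rng.normal(0.0, 1.0, size=n)
    eps_i = rng.normal(0.0, math.sqrt(var_eps_i), size=n)
    liability = g_inc + u + eps_i

    # empirical threshold guarantees the target prevalence in every replicate
    n_cases = math.ceil(config.prevalence * n)
    threshold = np.partition(liability, n - n_cases)[n - n_cases]
    incident = (liability >= threshold).astype(np.int8)

    lam, gam = config.lambda_, config.gamma
    h2_prog = 0.5 * (config.h2_prog_range[0] + config.h2_prog_range[1])
    cu = 0.5 * (config.confounder_var_range[0] + config.confounder_var_range[1])
    var_u_total = (lam + gam) ** 2            # U reaches Prog via gamma and via lambda*Inc
    qa = float(geno_var @ (beta_gy_raw ** 2))
    if var_u_total > 0:
        var_total = var_u_total / cu
        var_g_target = h2_prog * var_total
        # marginal genetic effect of SNP i on Prog is a*beta_gy_i + lambda*beta_gx_i;
        # solve the quadratic in the rescaling factor a
        qb = 2.0 * lam * float(geno_var @ (beta_gy_raw * beta_gx))
        qc = lam ** 2 * var_g_inc - var_g_target
        if qa <= 0:
            raise SimulationError("no raw progression effects to rescale; set r2_prog_* > 0")
        a = (-qb + math.sqrt(qb ** 2 - 4.0 * qa * qc)) / (2.0 * qa)
    else:
        # no confounder pathway at all (lambda = gamma = 0): the confounder
        # fraction is vacuous, keep the raw effects and scale noise only
        a = 1.0
        var_g_target = qa
        var_total = var_g_target / h2_prog if var_g_target > 0 else 1.0
    beta_gy = a * beta_gy_raw

    var_eps_p = var_total - var_g_target - var_u_total - lam ** 2 * var_eps_i
    if var_eps_p < 0:
        raise SimulationError("infeasible progression variance budget; widen ranges")
    eps_p = rng.normal(0.0, math.sqrt(var_eps_p), size=n)
    progression = genotypes @ beta_gy + lam * liability + gam * u + eps_p

    te["beta_gy_true"] = beta_gy
    true_effects.params.update({
        "var_g_liability": var_g_inc,
        "var_eps_liability": var_eps_i,
        "var_liability": var_g_inc + 1.0 + var_eps_i,
        "h2_liability_realized": var_g_inc / (var_g_inc + 1.0 + var_eps_i),
        "progression_rescale": a,
        "var_g_progression": var_g_target,
        "var_progression": var_total,
        "h2_progression": h2_prog,
        "confounder_fraction": cu,
        "var_eps_progression": var_eps_p,
        "n_cases": int(incident.sum()),
    })
    return {"liability": liability, "incident": incident,
            "progression": progression, "confounder": u}


def run_gwas(genotypes: np.ndarray, phenotype: np.ndarray,
             subset_mask: np.ndarray | None = None, model: str = "linear",
             max_iter: int = 25, tol: float = 1e-8,
             chunk_size: int = 512) -> pd.DataFrame:
    """Marginal single-variant GWAS across all SNPs.

    ``model='logistic'`` fits per-SNP intercept+genotype logistic
    regressions by Newton-Raphson, vectorized across SNPs in chunks;
    ``model='linear'`` uses closed-form simple regression with t-based
    two-sided p-values.  SNPs monomorphic in the analysis subset, and
    non-converged logistic fits, return missing estimates with
    ``converged=False``.
    """
    if subset_mask is not None:
        genotypes = genotypes[subset_mask]
        phenotype = phenotype[subset_mask]
    n, m = genotypes.shape
    if n < 3:
        raise SimulationError("GWAS subset too small")
    y = np.asarray(phenotype, dtype=np.float64)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    converged = np.zeros(m, dtype=bool)

    if model == "linear":
        gm = genotypes.mean(axis=0)
        gc = genotypes - gm
        sxx = (gc ** 2).sum(axis=0)
        poly = sxx <= 0
        yc = y - y.mean()
        sxy = gc.T @ yc
        syy = float(yc @ yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            rss = np.maximum(syy - b * sxy, 0.0)
            sigma2 = rss / (n - 2)
            s = np.sqrt(sigma2 / sxx)
        beta[~poly] = b[~poly]
        se[~poly] = s[~poly]
        converged = ~poly
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    elif model == "logistic":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise SimulationError("logistic model requires a 0/1 phenotype")
        # genotypes take only the values 0/1/2, so the per-SNP likelihood
        # depends on the data solely through six counts; Newton-Raphson on
        # those sufficient statistics is exact and orders of magnitude
        # cheaper than iterating over individuals
        gi = genotypes.astype(np.int8)
        ybool = y.astype(bool)
        n_g = np.empty((3, m))
        k_g = np.empty((3, m))
        for gval in (0, 1, 2):
            mask = gi == gval
            n_g[gval] = mask.sum(axis=0)
            k_g[gval] = (mask & ybool[:, None]).sum(axis=0)
        poly = (n_g > 0).sum(axis=0) <= 1
        gvals = np.array([0.0, 1.0, 2.0])[:, None]
        b0 = np.full(m, float(np.log(y.mean() / (1.0 - y.mean()))))
        b1 = np.zeros(m)
        d0 = d1 = np.zeros(m)
        for _ in range(max_iter):
            p_g = expit(b0 + gvals * b1)            # (3, m)
            w_g = n_g * p_g * (1.0 - p_g)
            r_g = k_g - n_g * p_g
            s0 = r_g.sum(axis=0)
            s1 = (gvals * r_g).sum(axis=0)
            h00 = w_g.sum(axis=0)
            h01 = (gvals * w_g).sum(axis=0)
            h11 = (gvals * gvals * w_g).sum(axis=0)
            det = h00 * h11 - h01 ** 2
            ok = (~poly) & (det > 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                d0 = np.where(ok, (h11 * s0 - h01 * s1) / det, 0.0)
                d1 = np.where(ok, (h00 * s1 - h01 * s0) / det, 0.0)
            # dampen huge first steps (quasi-separation guard)
            np.clip(d0, -4, 4, out=d0)
            np.clip(d1, -4, 4, out=d1)
            b0 += d0
            b1 += d1
            if np.max(np.maximum(np.abs(d0), np.abs(d1))) < tol:
                break
        p_g = expit(b0 + gvals * b1)
        w_g = n_g * p_g * (1.0 - p_g)
        h00 = w_g.sum(axis=0)
        h01 = (gvals * w_g).sum(axis=0)
        h11 = (gvals * gvals * w_g).sum(axis=0)
        det = h00 * h11 - h01 ** 2
        final_ok = ((~poly) & (det > 1e-12)
                    & (np.maximum(np.abs(d0), np.abs(d1)) < math.sqrt(tol)))
        with np.errstate(divide="ignore", invalid="ignore"):
            var_b1 = h00 / det
        beta = np.where(final_ok, b1, np.nan)
        se = np.where(final_ok, np.sqrt(np.abs(var_b1)), np.nan)
        converged = final_ok
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise SimulationError(f"unknown GWAS model {model!r}")

    return pd.DataFrame({"beta": beta, "se": se, "p": p,
                         "n": n, "converged": converged})


def simulate_study(config: SimulationConfig) -> tuple:
    """End-to-end generation of one replicate.

    Returns ``(AnalysisTable, TrueEffects)``: incidence statistics from a
    whole-population logistic GWAS and progression statistics from a
    cases-only linear GWAS, already aligned on a common effect allele (the
    simulator codes the trait-increasing strand directly, so no flipping is
    needed).
    """
    master = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(3)]

    truth = draw_true_effects(config, rngs[0])
    genotypes = simulate_genotypes(config.n_individuals, truth.df["maf"].to_numpy(), rngs[1])
    pheno = simulate_phenotypes(genotypes, truth, config, rngs[2])

    inc_gwas = run_gwas(genotypes, pheno["incident"], model="logistic")
    cases = pheno["incident"].astype(bool)
    prog_gwas = run_gwas(genotypes, pheno["progression"], subset_mask=cases, model="linear")

    eaf = genotypes.mean(axis=0) / 2.0
    df = pd.DataFrame({
        "variant_id": truth.df["variant_id"],
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf,
        "beta_inc": inc_gwas["beta"],
        "se_inc": inc_gwas["se"],
        "p_inc": inc_gwas["p"],
        "n_inc": inc_gwas["n"],
        "beta_prog": prog_gwas["beta"],
        "se_prog": prog_gwas["se"],
        "p_prog": prog_gwas["p"],
        "n_prog": prog_gwas["n"],
    })
    dropped = ~(inc_gwas["converged"].to_numpy() & prog_gwas["converged"].to_numpy())
    if dropped.any():
        df = df.loc[~dropped].reset_index(drop=True)
        truth = TrueEffects(df=truth.df.loc[~dropped].reset_index(drop=True),
                            params=truth.params)
    table = AnalysisTable(df=df, provenance={
        "incidence": "simulated logistic GWAS, full population",
        "progression": "simulated linear GWAS, cases only",
        "seed": config.seed,
    })
    return table, truth
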