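"""Replicate-level simulation harness used by the evaluation scripts.

Runs batches of simulated replicates through the Bayesian adjustment and
computes the headline operating characteristics: pooled type-1 error over
truly-null variants, detection power by variance-explained bin, per-method
bias over incidence-affected variants and convergence rates.
"""

from __future__ import annotations

import logging

import numpy as np

from .evaluate import compute_bias, compute_type1_error, variance_explained
from .horse import HorseModelConfig, fit_mr_horse_many
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

#: variance-explained bin centred on 0.5% of the progression variance
HALF_PERCENT_BIN = (0.004, 0.006)


def replicate_seed(master_seed: int, scenario: int, replicate: int) -> int:
    """Deterministic child seed below 2**31 for one scenario/replicate."""
    ss = np.random.SeedSequence([int(master_seed), int(scenario), int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_replicates(rho: float, n_replicates: int, master_seed: int,
                   scenario_index: int = 0,
                   sim_overrides: dict | None = None,
                   horse_config: HorseModelConfig | None = None):
    """Simulate ``n_replicates`` studies at one correlation and fit the
    Bayesian model to each (batched into one vectorized sampler run).

    Returns (tables, truths, summaries).
    """
    sim_overrides = dict(sim_overrides or {})
    tables, truths = [], []
    for rep in range(n_replicates):
        cfg = SimulationConfig(rho=rho,
                               seed=replicate_seed(master_seed, scenario_index, rep),
                               **sim_overrides)
        t, tr = simulate_study(cfg)
        tables.append(t)
        truths.append(tr)
    hc = horse_config or HorseModelConfig(
        n_iterations=2000, max_stored_per_chain=400,
        seed=replicate_seed(master_seed, scenario_index, 10_000))
    summaries = fit_mr_horse_many(tables, hc)
    logger.info("rho=%+.1f: %d replicates fitted", rho, n_replicates)
    return tables, truths, summaries


def pooled_type1_error(summaries, truths) -> tuple:
    """Pooled fraction of null (G0 u GI) variants flagged significant."""
    hits = total = 0
    for s, tr in zip(summaries, truths):
        m = s.df.merge(tr.df, on="variant_id")
        nulls = m["beta_gy_true"] == 0.0
        hits += int(m.loc[nulls, "significant"].sum())
        total += int(nulls.sum())
    return hits / total, total


def pooled_bin_power(summaries, truths, bin_edges=HALF_PERCENT_BIN) -> tuple:
    """Pooled detection fraction for non-null variants in one VE bin."""
    hits = total = 0
    lo, hi = bin_edges
    for s, tr in zip(summaries, truths):
        m = s.df.merge(tr.df, on="variant_id")
        nn = m[m["beta_gy_true"] != 0.0]
        ve = variance_explained(nn["beta_gy_true"].to_numpy(),
                                nn["maf"].to_numpy(),
                                tr.params["var_progression"])
        mask = (ve > lo) & (ve <= hi)
        hits += int(nn.loc[mask, "significant"].sum())
        total += int(mask.sum())
    return (hits / total if total else float("nan")), total


def rhat_convergence_fraction(summaries, threshold: float = 1.1) -> tuple:
    """Fraction of variants whose split-Rhat is below ``threshold``."""
    ok = total = 0
    for s in summaries:
        ok += int((s.df["rhat"] < threshold).sum())
        total += len(s.df)
    return ok / total, total


def per_replicate_biases(tables, truths, summaries) -> dict:
    """Per-replicate mean |error| over GI u GIP for each method.

    Returns arrays keyed by method: mr_horse, unadjusted, dudbridge,
    slopehunter (NaN where a comparator fails on a replicate).
    """
    from .baselines import (BaselineError, apply_slope, fit_dudbridge,
                            fit_slopehunter, unadjusted_slope)

    out = {k: [] for k in ("mr_horse", "unadjusted", "dudbridge", "slopehunter")}
    for t, tr, s in zip(tables, truths, summaries):
        out["mr_horse"].append(compute_bias(s, tr))
        out["unadjusted"].append(compute_bias(apply_slope(t, unadjusted_slope()), tr))
        try:
            dud = apply_slope(t, fit_dudbridge(t))
            out["dudbridge"].append(compute_bias(dud, tr))
        except BaselineError:
            out["dudbridge"].append(np.nan)
        try:
            sh = apply_slope(t, fit_slopehunter(t, n_bootstrap=1, seed=1))
            out["slopehunter"].append(compute_bias(sh, tr))
        except BaselineError:
            out["slopehunter"].append(np.nan)
    return {k: np.asarray(v) for k, v in out.items()}
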