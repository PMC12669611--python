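import numpy as np
import pandas as pd
import pytest

from progbias.simulate import SimulationConfig, simulate_study
from progbias.sumstats import AnalysisTable


def make_study_df(variant_ids, beta, se, p=None, eaf=0.3, n=1000,
                  effect_allele="A", other_allele="G"):
    """Canonical per-study frame for harmonization tests."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if p is None:
        from scipy import stats
        p = 2 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame({
        "variant_id": variant_ids,
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "p": p,
        "n": n,
    })


def make_table(beta_inc, se_inc, beta_prog, se_prog, p_inc=None):
    """Minimal harmonized AnalysisTable from raw arrays."""
    from scipy import stats

    beta_inc = np.asarray(beta_inc, dtype=float)
    se_inc = np.asarray(se_inc, dtype=float)
    beta_prog = np.asarray(beta_prog, dtype=float)
    se_prog = np.asarray(se_prog, dtype=float)
    if p_inc is None:
        p_inc = 2 * stats.norm.sf(np.abs(beta_inc / se_inc))
    df = pd.DataFrame({
        "variant_id": [f"v{i:04d}" for i in range(len(beta_inc))],
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta_inc": beta_inc,
        "se_inc": se_inc,
        "p_inc": p_inc,
        "n_inc": 10000,
        "beta_prog": beta_prog,
        "se_prog": se_prog,
        "p_prog": 2 * stats.norm.sf(np.abs(beta_prog / se_prog)),
        "n_prog": 4000,
    })
    return AnalysisTable(df=df)


SMALL_CONFIG = dict(n_individuals=4000, n_snps=400, seed=7, rho=0.7)


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated replicate shared across tests (read-only)."""
    table, truth = simulate_study(SimulationConfig(**SMALL_CONFIG))
    return table, truth


@pytest.fixture(scope="session")
def toy_table():
    """5-variant instance with a known bias-slope structure."""
    bx = np.array([0.30, -0.25, 0.20, 0.15, -0.20])
    by = 0.4 * bx + np.array([0.02, -0.01, 0.015, -0.02, 0.01])
    return make_table(bx, np.full(5, 0.05), by, np.full(5, 0.10),
                      p_inc=np.full(5, 1e-6))
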