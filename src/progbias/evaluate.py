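"""Scoring adjustment methods against simulation ground truth.

Definitions follow the simulation study conventions: type-1 error is the
fraction of truly-null progression variants (clusters G0 and GI) flagged
significant; power is the per-effect-size-bin detection fraction among
truly non-null variants, binning by the fraction of progression variance
explained, 2 beta^2 maf (1 - maf) / var(progression); bias is the mean
absolute error over variants with incidence effects (GI and GIP), where
the collider distortion concentrates.  The instrument-strength heuristic
is the mean of (beta_prog / se_prog)^2 over incidence-selected variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import AnalysisTable
from .simulate import TrueEffects


class EvaluationError(ValueError):
    """Misaligned inputs or undefined metric."""


@dataclass
class EvaluationMetrics:
    """Metrics for one method on one (or pooled) replicate(s)."""

    method: str
    type1_error: float
    power_curve: pd.DataFrame
    bias: float
    unadjusted_bias: float | None = None
    mean_f_statistic: float | None = None
    n_replicates: int = 1
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "type1_error": self.type1_error,
            "power_curve": self.power_curve.to_dict(orient="list"),
            "bias": self.bias,
            "unadjusted_bias": self.unadjusted_bias,
            "mean_f_statistic": self.mean_f_statistic,
            "n_replicates": self.n_replicates,
            **self.extra,
        }


def _aligned(results, truth: TrueEffects) -> pd.DataFrame:
    """Inner-join result df (variant_id, estimate, significant) with truth."""
    rdf = results.df if hasattr(results, "df") else results
    need = {"variant_id", "estimate", "significant"}
    if not need.issubset(rdf.columns):
        raise EvaluationError(f"results table must have columns {sorted(need)}")
    merged = rdf.merge(truth.df, on="variant_id", how="inner", validate="1:1")
    if len(merged) == 0:
        raise EvaluationError("no shared variants between results and truth")
    return merged


def compute_type1_error(results, truth: TrueEffects) -> float:
    """Fraction of truly-null (beta_GY = 0) variants flagged significant."""
    merged = _aligned(results, truth)
    nulls = merged["beta_gy_true"] == 0.0
    if not nulls.any():
        raise EvaluationError("no null variants; type-1 error undefined")
    return float(merged.loc[nulls, "significant"].mean())


def variance_explained(beta: np.ndarray, maf: np.ndarray,
                       var_phenotype: float = 1.0) -> np.ndarray:
    """Per-variant fraction of phenotype variance: 2 beta^2 maf (1-maf) / var."""
    return 2.0 * beta ** 2 * maf * (1.0 - maf) / var_phenotype


def compute_power(results, truth: TrueEffects, bins=None,
                  var_phenotype: float | None = None) -> pd.DataFrame:
    """Detection fraction of truly non-null variants by variance explained.

    ``bins``: bin edges on the variance-explained axis (fractions); default
    is deciles of the realized non-null distribution.  Empty bins are
    omitted.  Returns columns bin_left, bin_right, ve_mid, n, power, sem.
    """
    merged = _aligned(results, truth)
    nn = merged.loc[merged["beta_gy_true"] != 0.0]
    if len(nn) == 0:
        raise EvaluationError("no non-null variants; power undefined")
    if var_phenotype is None:
        var_phenotype = float(truth.params.get("var_progression", 1.0))
    ve = variance_explained(nn["beta_gy_true"].to_numpy(), nn["maf"].to_numpy(),
                            var_phenotype)
    if bins is None:
        bins = np.unique(np.quantile(ve, np.linspace(0, 1, 11)))
    bins = np.asarray(bins, dtype=float)
    idx = np.clip(np.digitize(ve, bins) - 1, 0, len(bins) - 2)
    rows = []
    sig = nn["significant"].to_numpy()
    for k in range(len(bins) - 1):
        mask = idx == k
        n = int(mask.sum())
        if n == 0:
            continue
        p = float(sig[mask].mean())
        rows.append({"bin_left": bins[k], "bin_right": bins[k + 1],
                     "ve_mid": float(ve[mask].mean()), "n": n, "power": p,
                     "sem": float(np.sqrt(p * (1 - p) / n))})
    return pd.DataFrame(rows)


def compute_bias(results, truth: TrueEffects,
                 clusters=("GI", "GIP")) -> float:
    """Mean |estimate - beta_GY_true| over the given clusters."""
    merged = _aligned(results, truth)
    sel = merged["cluster"].isin(clusters)
    if not sel.any():
        return float("nan")
    err = merged.loc[sel, "estimate"] - merged.loc[sel, "beta_gy_true"]
    return float(err.abs().mean())


def compute_mean_f_statistic(table: AnalysisTable, p_threshold: float = 1e-3) -> float:
    """Mean (beta_prog / se_prog)^2 over variants with p_inc < p_threshold.

    A mean F above ~15 indicates the selected instruments carry enough
    progression signal for the Bayesian adjustment to be well powered.
    """
    sel = table.df.loc[table.df["p_inc"] < p_threshold]
    if len(sel) == 0:
        raise EvaluationError(f"no variants pass p_inc < {p_threshold}")
    return float(np.mean((sel["beta_prog"] / sel["se_prog"]) ** 2))


def unadjusted_results(table: AnalysisTable, alpha: float = 0.05) -> "pd.DataFrame":
    """Raw progression estimates in the results-table layout (no adjustment)."""
    from .baselines import apply_slope, unadjusted_slope

    return apply_slope(table, unadjusted_slope(), alpha=alpha)


def evaluate_method(results, truth: TrueEffects, table: AnalysisTable | None = None,
                    method: str = "", bins=None) -> EvaluationMetrics:
    """All metrics for one method on one replicate."""
    t1e = compute_type1_error(results, truth)
    power = compute_power(results, truth, bins=bins)
    bias = compute_bias(results, truth)
    unadj_bias = None
    fstat = None
    if table is not None:
        unadj_bias = compute_bias(unadjusted_results(table), truth)
        try:
            fstat = compute_mean_f_statistic(table)
        except EvaluationError:
            fstat = None
    return EvaluationMetrics(method=method, type1_error=t1e, power_curve=power,
                             bias=bias, unadjusted_bias=unadj_bias,
                             mean_f_statistic=fstat)


def pool_metrics(metrics: list[EvaluationMetrics]) -> EvaluationMetrics:
    """Average per-replicate metrics; SEM across replicates in ``extra``.

    Power curves are pooled by re-averaging per-bin with weights n (bins
    must share edges across replicates, as with fixed-edge binning).
    """
    if not metrics:
        raise EvaluationError("nothing to pool")
    t1e = np.array([m.type1_error for m in metrics])
    bias = np.array([m.bias for m in metrics])
    pc = pd.concat([m.power_curve for m in metrics], ignore_index=True)
    pooled_pc = (pc.assign(hits=pc["power"] * pc["n"],
                           ve_w=pc["ve_mid"] * pc["n"])
                 .groupby(["bin_left", "bin_right"], as_index=False)
                 .agg(n=("n", "sum"), hits=("hits", "sum"), ve_w=("ve_w", "sum")))
    pooled_pc["power"] = pooled_pc["hits"] / pooled_pc["n"]
    pooled_pc["ve_mid"] = pooled_pc["ve_w"] / pooled_pc["n"]
    pooled_pc["sem"] = np.sqrt(pooled_pc["power"] * (1 - pooled_pc["power"]) / pooled_pc["n"])
    pooled_pc = pooled_pc.drop(columns=["hits", "ve_w"])
    k = len(metrics)
    unadj = [m.unadjusted_bias for m in metrics if m.unadjusted_bias is not None]
    fstats = [m.mean_f_statistic for m in metrics if m.mean_f_statistic is not None]
    return EvaluationMetrics(
        method=metrics[0].method,
        type1_error=float(t1e.mean()),
        power_curve=pooled_pc,
        bias=float(bias.mean()),
        unadjusted_bias=float(np.mean(unadj)) if unadj else None,
        mean_f_statistic=float(np.mean(fstats)) if fstats else None,
        n_replicates=k,
        extra={"type1_error_sem": float(t1e.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
               "bias_sem": float(bias.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0})


def plot_power_curve(power_df: pd.DataFrame, ax=None, label: str = ""):
    """Minimal power-vs-variance-explained line plot (percent scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(100 * power_df["ve_mid"], 100 * power_df["power"],
                yerr=196 * power_df["sem"], marker="o", capsize=2, label=label)
    ax.set_xlabel("variance explained per variant (%)")
    ax.set_ylabel("power (%)")
    ax.set_ylim(0, 100)
    if label:
        ax.legend()
    return ax
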