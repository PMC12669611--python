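"""End-to-end applied analysis on a pair of real (or simulated) GWAS.

Mirrors the kidney-function case study design: harmonize a cross-sectional
(incidence-proxy) GWAS with a progression GWAS, restrict to an externally
clumped independent-variant list, add back progression lead variants that
clumping on the incidence p-value removed, run the Bayesian adjustment and
both slope comparators, and report per-variant before/after estimates with
user-supplied locus labels and negative-control flags.

LD clumping itself is out of scope; produce the ID list with e.g.

    plink --bfile REF --clump incidence.tsv --clump-p1 1 \\
          --clump-kb 100 --clump-r2 0.001 --clump-snp-field variant_id

and pass the resulting variant IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import BaselineError, apply_slope, fit_dudbridge, fit_slopehunter, unadjusted_slope
from .horse import HorseModelConfig, fit_mr_horse
from .sumstats import AnalysisTable, add_lead_variants, harmonize, read_sumstats

logger = logging.getLogger(__name__)


@dataclass
class AppliedReport:
    """Per-variant before/after table plus negative-control attenuation.

    ``df`` columns: variant_id, locus_label, control_flag, beta_unadj,
    ci_unadj_l, ci_unadj_u, sig_unadj, then per method ``<m>_estimate,
    <m>_ci_l, <m>_ci_u, <m>_significant``.  ``attenuation`` maps method ->
    mean |adjusted| / |unadjusted| over flagged negative-control variants.
    """

    df: pd.DataFrame
    attenuation: dict = field(default_factory=dict)
    slopes: dict = field(default_factory=dict)
    missing_lead_ids: list = field(default_factory=list)
    harmonize_counts: dict = field(default_factory=dict)


def run_applied_analysis(
    incidence_path,
    progression_path,
    clumped_ids,
    lead_ids=(),
    annotations: pd.DataFrame | None = None,
    horse_config: HorseModelConfig | None = None,
    p_threshold: float = 1e-3,
    n_bootstrap: int = 200,
    incidence_column_map: dict | None = None,
    progression_column_map: dict | None = None,
    keep_ambiguous: bool = False,
    alpha: float = 0.05,
) -> AppliedReport:
    """Harmonize, select, adjust with all three methods, and report.

    Parameters
    ----------
    clumped_ids, lead_ids
        Variant-ID iterables: the externally clumped independent set, and
        progression lead variants to re-add if clumping dropped them.
    annotations
        Optional DataFrame with columns variant_id, locus_label,
        control_flag (truthy marks a negative-control variant).
    """
    inc = read_sumstats(incidence_path, column_map=incidence_column_map)
    pro = read_sumstats(progression_path, column_map=progression_column_map)
    full = harmonize(inc, pro, keep_ambiguous=keep_ambiguous,
                     provenance={"incidence": str(incidence_path),
                                 "progression": str(progression_path)})

    clumped_ids = list(dict.fromkeys(str(v) for v in clumped_ids))
    if not clumped_ids:
        raise ValueError("clumped_ids must be nonempty")
    lead_ids = [str(v) for v in lead_ids]

    base = full.df.loc[full.df["variant_id"].isin(clumped_ids)]
    table = AnalysisTable(df=base.reset_index(drop=True),
                          provenance=full.provenance, counts=full.counts)
    lead_rows = full.df.loc[full.df["variant_id"].isin(lead_ids)]
    missing_leads = sorted(set(lead_ids) - set(lead_rows["variant_id"]))
    if missing_leads:
        logger.warning("lead variants absent from harmonized data: %s", missing_leads)
    table = add_lead_variants(table, lead_rows)
    logger.info("applied analysis on %d variants (%d clumped + leads)",
                len(table), len(base))

    results = {"unadjusted": apply_slope(table, unadjusted_slope(), alpha=alpha)}
    slopes = {}
    try:
        dud = fit_dudbridge(table, p_threshold=p_threshold, hedges_olkin=True)
        slopes["dudbridge"] = dud
        results["dudbridge"] = apply_slope(table, dud, alpha=alpha)
    except BaselineError as exc:
        logger.warning("dudbridge failed: %s", exc)
    try:
        sh = fit_slopehunter(table, p_threshold=p_threshold, n_bootstrap=n_bootstrap)
        slopes["slopehunter"] = sh
        results["slopehunter"] = apply_slope(table, sh, alpha=alpha)
    except BaselineError as exc:
        logger.warning("slopehunter failed: %s", exc)
    horse = fit_mr_horse(table, horse_config or HorseModelConfig())
    slopes["mr_horse"] = horse.global_summary.loc["b"].to_dict()

    unadj = results["unadjusted"].df.set_index("variant_id")
    report = pd.DataFrame({
        "variant_id": unadj.index,
        "beta_unadj": unadj["estimate"].to_numpy(),
        "ci_unadj_l": unadj["ci_lower"].to_numpy(),
        "ci_unadj_u": unadj["ci_upper"].to_numpy(),
        "sig_unadj": unadj["significant"].to_numpy(),
    })
    for name, res in [("dudbridge", results.get("dudbridge")),
                      ("slopehunter", results.get("slopehunter"))]:
        if res is None:
            continue
        r = res.df.set_index("variant_id").loc[report["variant_id"]]
        report[f"{name}_estimate"] = r["estimate"].to_numpy()
        report[f"{name}_ci_l"] = r["ci_lower"].to_numpy()
        report[f"{name}_ci_u"] = r["ci_upper"].to_numpy()
        report[f"{name}_significant"] = r["significant"].to_numpy()
    h = horse.df.set_index("variant_id").loc[report["variant_id"]]
    report["mr_horse_estimate"] = h["estimate"].to_numpy()
    report["mr_horse_ci_l"] = h["ci_lower"].to_numpy()
    report["mr_horse_ci_u"] = h["ci_upper"].to_numpy()
    report["mr_horse_significant"] = h["significant"].to_numpy()

    if annotations is not None:
        ann = annotations[["variant_id", "locus_label", "control_flag"]].copy()
        ann["variant_id"] = ann["variant_id"].astype(str)
        report = report.merge(ann, on="variant_id", how="left")
    else:
        report["locus_label"] = ""
        report["control_flag"] = False
    report["control_flag"] = report["control_flag"].map(
        lambda v: bool(v) if pd.notna(v) else False)

    attenuation = {}
    controls = report["control_flag"].to_numpy()
    if controls.any():
        denom = np.abs(report.loc[controls, "beta_unadj"])
        denom = np.where(denom < 1e-12, np.nan, denom)
        for name in ("dudbridge", "slopehunter", "mr_horse"):
            col = f"{name}_estimate"
            if col in report:
                attenuation[name] = float(np.nanmean(
                    np.abs(report.loc[controls, col]) / denom))

    front = ["variant_id", "locus_label", "control_flag"]
    report = report[front + [c for c in report.columns if c not in front]]
    return AppliedReport(df=report.reset_index(drop=True),
                         attenuation=attenuation, slopes=slopes,
                         missing_lead_ids=missing_leads,
                         harmonize_counts=full.counts.as_dict() if full.counts else {})
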