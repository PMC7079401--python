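"""End-to-end orchestration: score -> describe -> screen -> parcel -> fit.

One configured run reproduces the survey's result artifacts from any
conforming cohort table (or from the calibrated synthetic generator):
scored cohort, descriptive cross-tabs with the Fisher/chi-square rule,
the prevalence block, the screening selection, the SEM fit with robust
fit statistics and a threshold verdict, and the effect-decomposition
table.  Every artifact is stamped with the config hash and seed;
re-running with the same config and seed reproduces the outputs
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import descriptives, scales, screening
from .descriptives import ContingencyTable, crude_association, prevalence
from .io import load_model_yaml, read_cohort
from .model import OUTCOME, default_sem_spec
from .sem import decompose_effects, fit_indices, fit_ml, independence_spec, satorra_bentler
from .synth import analysis_frame, default_config, generate

__all__ = ["RunConfig", "run_all", "score_cohort"]

log = logging.getLogger("stressproc")

#: variables cross-tabulated against the depression flag, Table-1/2/3 style
TABLE_VARIABLES = (
    "income_category",
    "education",
    "occupation",
    "religion",
    "marital_status",
    "marital_agreement",
    "food_access_difficulty",
    "pregnancy_intention",
    "trimester",
    "fear_of_birth",
    "history_cmd",
    "partner_support",
    "social_support_category",
)

SCREENING_CANDIDATES = (
    "food_adequate",
    "unplanned",
    "fear_birth",
    "history_cmd",
    "marital_agreement",
    "partner_support",
    "social_support",
    "age_years",
    "income",
    "parity",
    "muac_cm",
    "pci_total",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``input`` is a cohort CSV; when omitted a synthetic cohort of size
    ``n`` is generated from the packaged calibrated condition with
    ``seed``.  Cutoffs default to the published rules (EPDS 12/13/17,
    OSSS-3 poor < 9, printed MUAC rule set).
    """

    output_dir: str | Path
    input: str | Path | None = None
    column_map: Mapping[str, str] | None = None
    epds_coding: str = "coded"
    n: int = 916
    seed: int = 7
    model_file: str | Path | None = None
    muac_ruleset: str = "printed"
    screening_alpha: float = 0.05
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in dataclasses.asdict(self).items() if k != "output_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def score_cohort(cohort: pd.DataFrame, muac_ruleset: str = "printed") -> pd.DataFrame:
    """Add instrument totals, categories and flags to a cohort table."""
    out = cohort.copy()
    epds = [
        scales.score_epds(row)
        for row in cohort[[f"epds_{i}" for i in range(1, 11)]].to_numpy()
    ]
    out["epds_total"] = [s.total for s in epds]
    out["epds_category"] = [s.category for s in epds]
    out["self_harm_flag"] = [int(s.has_flag("self_harm_flag")) for s in epds]
    out["referral_flag"] = [int(s.has_flag("referral_flag")) for s in epds]
    osss = [
        scales.score_osss3(row)
        for row in cohort[["osss_1", "osss_2", "osss_3"]].to_numpy()
    ]
    out["social_support"] = [s.total for s in osss]
    out["social_support_category"] = [s.category for s in osss]
    if {"pci_1", "pci_2", "pci_3", "pci_4"} <= set(cohort.columns):
        out["pci_total"] = [
            scales.score_pci4(row).total
            for row in cohort[["pci_1", "pci_2", "pci_3", "pci_4"]].to_numpy()
        ]
    if "muac_cm" in cohort.columns:
        out["muac_class"] = [
            scales.classify_muac(v, muac_ruleset) for v in cohort["muac_cm"]
        ]
    if "gestational_weeks" in cohort.columns:
        out["trimester"] = np.where(cohort["gestational_weeks"] <= 27, "second", "third")
    return out


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _crosstabs(analysis: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    flag = analysis["epds_category"] == "possible_depression"
    rows = []
    outdir.mkdir(parents=True, exist_ok=True)
    for var in TABLE_VARIABLES:
        if var not in analysis.columns:
            continue
        counts = pd.crosstab(analysis[var], flag)
        if counts.shape[1] < 2 or counts.shape[0] < 2:
            log.warning("table %s degenerate; skipped", var)
            continue
        table = ContingencyTable(
            counts.to_numpy(),
            row_labels=tuple(map(str, counts.index)),
            col_labels=tuple(map(str, counts.columns)),
        )
        result = crude_association(table)
        counts.to_csv(outdir / f"crosstab_{var}.csv")
        rows.append(
            {
                "variable": var,
                "method": result.method,
                "statistic": result.statistic,
                "df": result.df,
                "p_value": result.p_value,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "association_tests.csv", index=False, float_format="%.10g")
    return summary


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict with the in-memory artifacts (scored cohort, test
    summary, prevalence block, screening result, fitted model, effect
    table, verdict).  Stage failures raise with a stage-labeled message;
    artifacts written before the failure are left in place.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    # -- stage: input -------------------------------------------------
    if config.input is None:
        cohort = generate(default_config(n=config.n), seed=config.seed)
        log.info("generated synthetic cohort n=%d (seed %d)", len(cohort), config.seed)
    else:
        cohort = read_cohort(config.input, config.column_map, config.epds_coding)
        log.info("read cohort n=%d from %s", len(cohort), config.input)

    # -- stage: scoring ----------------------------------------------
    try:
        scored = score_cohort(cohort, config.muac_ruleset)
    except Exception as exc:
        raise RuntimeError(f"stage scoring failed: {exc}") from exc
    scored.to_csv(outdir / "scored.csv", index=False, float_format="%.10g")

    excluded = scored[scored["epds_total"] >= scales.EPDS_EXCLUSION]
    analysis = scored[scored["epds_total"] <= scales.EPDS_EXCLUSION - 1]
    n_referral = int(scored["referral_flag"].sum())
    log.info(
        "eligibility: %d analyzed, %d excluded (EPDS >= 17), %d referred",
        len(analysis), len(excluded), n_referral,
    )

    # -- stage: descriptives ------------------------------------------
    try:
        tests = _crosstabs(analysis, outdir / "tables")
        n_dep = int((analysis["epds_category"] == "possible_depression").sum())
        prev = prevalence(n_dep, len(analysis))
        prev_by_trim = {}
        if "trimester" in analysis.columns:
            for trim, grp in analysis.groupby("trimester"):
                k = int((grp["epds_category"] == "possible_depression").sum())
                prev_by_trim[str(trim)] = dataclasses.asdict(prevalence(k, len(grp)))
        prev_block = {
            "overall": dataclasses.asdict(prev),
            "by_trimester": prev_by_trim,
            "percent": dict(
                zip(("proportion", "ci_low", "ci_high"), prev.as_percent())
            ),
        }
    except Exception as exc:
        raise RuntimeError(f"stage descriptives failed: {exc}") from exc
    _write_json(outdir / "prevalence.json", {**prev_block, **stamp})
    if prev.numerator == 0:
        log.warning("no participant screened positive; prevalence block is 0%%")

    # -- stage: screening ---------------------------------------------
    try:
        frame = analysis_frame(analysis).join(
            analysis[["age_years", "income", "parity", "muac_cm", "pci_total"]]
        )
        candidates = [c for c in SCREENING_CANDIDATES if c in frame.columns]
        screen = screening.screen_variables(
            frame, "epds_total", candidates, "cluster_id", alpha=config.screening_alpha
        )
        if not screen["selected"]:
            log.warning("screening selected no variables at p < %.2f", config.screening_alpha)
    except Exception as exc:
        raise RuntimeError(f"stage screening failed: {exc}") from exc
    _write_json(outdir / "selected.json", {**screen, **stamp})

    # -- stage: SEM ----------------------------------------------------
    try:
        spec = (
            load_model_yaml(config.model_file)
            if config.model_file
            else default_sem_spec()
        )
        fit = fit_ml(spec, frame)
        satorra_bentler(fit)
        baseline = fit_ml(independence_spec(spec.observed), frame)
        satorra_bentler(baseline)
        indices = fit_indices(fit, baseline)
        effects = decompose_effects(fit, OUTCOME if OUTCOME in spec.latents else spec.latents[0])
    except Exception as exc:
        raise RuntimeError(f"stage sem failed: {exc}") from exc

    verdict = {
        "chi2_sb_p_gt_05": bool(fit.p_value_sb is not None and fit.p_value_sb > 0.05),
        "cfi_ge_090": bool(indices["cfi_sb"] >= 0.90),
        "tli_ge_090": bool(indices["tli_sb"] >= 0.90),
        "rmsea_le_008": bool(indices["rmsea_sb"] <= 0.08),
        "srmr": indices["srmr"],
        "heywood": list(fit.heywood),
        "converged": fit.converged,
    }
    fit_payload = {
        "n": fit.n,
        "df": fit.df,
        "chi2_ml": fit.chi2_ml,
        "chi2_sb": fit.chi2_sb,
        "scaling_c": fit.scaling_c,
        "p_value_sb": fit.p_value_sb,
        "indices": indices,
        "estimates": fit.estimates().round(10).to_dict(orient="index"),
        "standardized": fit.standardized().round(10).to_dict(),
        "r2": fit.r2().round(10).to_dict(),
        "effects": effects.table.round(10).to_dict(orient="index"),
        "verdict": verdict,
        **stamp,
    }
    _write_json(outdir / "fit.json", fit_payload)
    effects.table.round(2).to_csv(outdir / "effects.csv", float_format="%.2f")

    manifest = {
        **stamp,
        "n_input": len(scored),
        "n_analysis": len(analysis),
        "n_excluded": len(excluded),
        "n_referral": n_referral,
        "stages": ["scoring", "descriptives", "screening", "sem"],
    }
    _write_json(outdir / "manifest.json", manifest)
    return {
        "scored": scored,
        "analysis": analysis,
        "excluded": excluded,
        "tests": tests,
        "prevalence": prev_block,
        "screening": screen,
        "fit": fit,
        "indices": indices,
        "effects": effects,
        "verdict": verdict,
        "manifest": manifest,
    }
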