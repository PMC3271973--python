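"""End-to-end orchestration of the screening and serum-validation workflow.

Stages run in the study's order — candidate screen, serum group
statistics, ROC, surveillance, ELISA plate reduction — each driven by the
corresponding library module; a stage whose inputs are not configured is
skipped with a notice.  The report carries full-precision numbers in JSON
(rounded integer percentages are derived at the reporting layer only) plus
provenance: the config, its hash, the seed, and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .cohorts import CA125_CUTOFF_U_ML
from .roc import roc_curve, threshold_at_specificity
from .screen import ScreenParams, run_screen
from .stats import anova_bonferroni, fold_change, ttest_raw
from .surveillance import SurveillanceParams, compare_outcomes, composite_average, fraction_above

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "round_half_up_pct"]


def round_half_up_pct(numerator: float, denominator: float) -> int:
    """Integer percentage with round-half-up (58% from 19/33, 23% from 8/35)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; unset paths skip their stage."""

    matrix: str | None = None
    samples: str | None = None
    annotation: str | None = None
    cohort: str | None = None
    surveillance: str | None = None
    plate: str | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"
    screen_params: ScreenParams = field(default_factory=ScreenParams)
    surveillance_params: SurveillanceParams = field(default_factory=SurveillanceParams)
    control_groups: tuple[str, ...] = ("Control", "Benign")
    case_groups: tuple[str, ...] = ("EarlyEOC", "LateEOC", "RecurrentEOC")
    roc_specificities: tuple[float, ...] = (0.90, 0.95)
    ca125_cutoff: float = CA125_CUTOFF_U_ML

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        screen = ScreenParams(**raw.pop("screen_params", {}))
        surveil = SurveillanceParams(**raw.pop("surveillance_params", {}))
        for key in ("control_groups", "case_groups", "roc_specificities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(screen_params=screen, surveillance_params=surveil, **raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _screen_stage(config: PipelineConfig, out: Path) -> dict:
    matrix = sio.read_expression_matrix(config.matrix, config.samples)
    annotation = sio.read_annotation(config.annotation)
    result = run_screen(matrix, annotation, config.screen_params)
    result.per_gene.to_csv(out / "screen_per_gene.tsv", sep="\t", index_label="gene_id")
    n_ret = result.stage_counts["n_candidates"]
    n_dis = result.stage_counts["n_disqualified"]
    section = {
        "stage_counts": result.stage_counts,
        "retained_pct": round_half_up_pct(n_ret, n_ret + n_dis) if n_ret + n_dis else None,
        "disqualified_pct": round_half_up_pct(n_dis, n_ret + n_dis) if n_ret + n_dis else None,
        "candidates_top20": result.candidates[:20],
        "n_candidates": n_ret,
    }
    return section


def _serum_stage(config: PipelineConfig, out: Path) -> dict:
    cohort = sio.read_serum_cohort(config.cohort)
    summaries = (
        cohort.groupby("group")["igfbp4"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1), min="min", max="max")
        .reset_index()
    )
    summaries.to_csv(out / "serum_group_summaries.tsv", sep="\t", index=False)

    groups = {g: v["igfbp4"].to_numpy() for g, v in cohort.groupby("group")}
    eligible = {g: v for g, v in groups.items() if len(v) >= 2}
    overall, pairwise = anova_bonferroni(eligible)
    ctrl = cohort[cohort["group"].isin(config.control_groups)]["igfbp4"].to_numpy()
    case = cohort[cohort["group"].isin(config.case_groups)]["igfbp4"].to_numpy()
    headline = ttest_raw(ctrl, case, variant="welch")

    section = {
        "group_summaries": summaries.to_dict(orient="records"),
        "anova": {"F": overall.statistic, "df": overall.df, "p": overall.p},
        "pairwise": [
            {"comparison": t.comparison, "t": t.statistic, "p": t.p, "adjusted_p": t.adjusted_p}
            for t in pairwise
        ],
        "controls_vs_cases": {"t": headline.statistic, "df": headline.df, "p": headline.p},
        "fold_change_case_vs_control": fold_change(case.mean(), ctrl.mean()),
    }
    benign = groups.get("Benign")
    if benign is not None and len(benign):
        section["fold_change_case_vs_benign"] = fold_change(case.mean(), benign.mean())
    if "ca125" in cohort.columns and cohort["ca125"].notna().any():
        sub = cohort.dropna(subset=["ca125"])
        hi_marker = sub["igfbp4"] > sub["igfbp4"].median()
        hi_ca125 = sub["ca125"] > config.ca125_cutoff
        section["ca125_concordance"] = {
            "cutoff_u_ml": config.ca125_cutoff,
            "counts": pd.crosstab(hi_marker, hi_ca125).to_dict(),
        }
    return section


def _roc_stage(config: PipelineConfig, out: Path) -> dict:
    cohort = sio.read_serum_cohort(config.cohort)
    section: dict = {}
    for name, controls in (
        ("healthy_and_benign_vs_eoc", config.control_groups),
        ("benign_vs_eoc", ("Benign",)),
    ):
        sub = cohort[cohort["group"].isin(tuple(controls) + tuple(config.case_groups))]
        labels = sub["group"].isin(config.case_groups).to_numpy()
        if labels.all() or not labels.any():
            log.info("ROC definition %s skipped: single class", name)
            continue
        result = roc_curve(sub["igfbp4"].to_numpy(), labels)
        result.points.to_csv(out / f"roc_{name}.tsv", sep="\t", index=False)
        queries = []
        for target in config.roc_specificities:
            thr, sens, attained = threshold_at_specificity(result, target)
            queries.append(
                {
                    "target_specificity": target,
                    "threshold_ng_ml": thr,
                    "sensitivity": sens,
                    "attained_specificity": attained,
                }
            )
        section[name] = {"auc": result.auc, "queries": queries}
    return section


def _surveillance_stage(config: PipelineConfig, out: Path) -> dict:
    sset = sio.read_surveillance(config.surveillance)
    params = config.surveillance_params
    composites = composite_average(sset)
    composites.rename("composite_ng_ml").to_csv(out / "surveillance_composites.tsv", sep="\t")
    section: dict = {"threshold_ng_ml": params.threshold, "fractions": {}}
    for outcome in ("NED", "AWD"):
        if sset.readings["outcome"].eq(outcome).any():
            above, total, pct = fraction_above(sset, params, outcome)
            section["fractions"][outcome] = {"above": above, "total": total, "pct": pct}
    for mode in ("composite", "serial"):
        try:
            t = compare_outcomes(sset, mode=mode)
            section[f"{mode}_test"] = {"t": t.statistic, "df": t.df, "p": t.p, "note": t.note}
        except ValueError as exc:
            section[f"{mode}_test"] = {"skipped": str(exc)}
    return section


def _elisa_stage(config: PipelineConfig, out: Path) -> dict:
    from .elisa import reduce_plate

    plate = sio.read_plate(config.plate)
    concs, curve = reduce_plate(plate)
    concs.to_csv(out / "elisa_concentrations.csv", index=False)
    calibration = {
        "a": curve.a,
        "b": curve.b,
        "c": curve.c,
        "d": curve.d,
        "residual_rms": curve.residual_rms,
        "conc_range": list(curve.conc_range),
    }
    (out / "elisa_calibration.json").write_text(json.dumps(calibration, indent=2))
    return {"calibration": calibration, "n_reduced": int(len(concs))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the JSON report.

    Returns the report dict; also written to ``<out_dir>/report.json``
    alongside per-stage TSV/CSV artifacts.  Deterministic for fixed
    inputs and seed (no timestamps in the report).
    """
    logging.basicConfig(level=config.log_level)
    out = sio.ensure_dir(config.out_dir)
    report: dict = {
        "provenance": {
            "config": asdict(config),
            "config_sha256_16": config.digest(),
            "seed": config.seed,
            "package": "seroscreen 0.1.0",
        }
    }
    stages = [
        ("screen", (config.matrix, config.samples, config.annotation), _screen_stage),
        ("serum_stats", (config.cohort,), _serum_stage),
        ("roc", (config.cohort,), _roc_stage),
        ("surveillance", (config.surveillance,), _surveillance_stage),
        ("elisa", (config.plate,), _elisa_stage),
    ]
    for name, inputs, fn in stages:
        if any(p is None for p in inputs):
            log.info("stage %s skipped: inputs not configured", name)
            report[name] = {"skipped": "inputs not configured"}
            continue
        report[name] = fn(config, out)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
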