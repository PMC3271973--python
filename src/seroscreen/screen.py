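"""Secreted-biomarker candidate screen.

Three-stage cascade over a coverage matrix:

1. expression floor — keep genes whose mean coverage across all samples is
   strictly greater than a floor (default 1 RPKM);
2. secretome intersection — keep genes annotated as encoding secreted
   proteins (the secretome list is supplied, not bundled);
3. variability disqualification — drop genes whose across-sample standard
   deviation exceeds a fraction of their mean (default 75%), i.e. a
   coefficient-of-variation filter selecting markers expressed consistently
   across tumors.

Survivors are "top candidate genes", ranked by mean coverage descending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "ScreenParams",
    "ScreenResult",
    "filter_expressed",
    "intersect_secretome",
    "variability_filter",
    "run_screen",
    "retained_percentages",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the screening cascade.

    min_mean_coverage : float
        Expression floor in coverage (RPKM) units; genes pass with mean
        strictly greater than this (a gene at exactly the floor is
        excluded).
    cv_threshold : float
        Disqualify a gene when sd > cv_threshold * mean (strict).
    rank_report_fraction : float
        Top-fraction used when reporting how highly a candidate ranks
        among expressed genes.
    """

    min_mean_coverage: float = 1.0
    cv_threshold: float = 0.75
    rank_report_fraction: float = 0.075

    def __post_init__(self) -> None:
        if self.min_mean_coverage < 0:
            raise ValueError("min_mean_coverage must be >= 0")
        if not self.cv_threshold > 0:
            raise ValueError("cv_threshold must be > 0")
        if not 0 < self.rank_report_fraction <= 1:
            raise ValueError("rank_report_fraction must be in (0, 1]")


@dataclass
class ScreenResult:
    """Per-gene verdicts and stage-by-stage accounting of the cascade."""

    per_gene: pd.DataFrame = field(repr=False)
    stage_counts: dict[str, int]
    candidates: list[str]

    def __post_init__(self) -> None:
        c = self.stage_counts
        assert c["n_candidates"] == c["n_secreted"] - c["n_disqualified"]


def _require_nonempty(matrix: ExpressionMatrix) -> None:
    if matrix.values.empty:
        raise ValueError("empty expression matrix")


def filter_expressed(matrix: ExpressionMatrix, params: ScreenParams) -> set[str]:
    """Genes whose mean coverage over all samples strictly exceeds the floor."""
    _require_nonempty(matrix)
    means = matrix.values.mean(axis=1)
    return set(means.index[means > params.min_mean_coverage])


def intersect_secretome(genes: set[str], annotation: pd.DataFrame) -> set[str]:
    """Subset of ``genes`` flagged as secreted in the annotation.

    Gene ids are matched exactly (case-sensitive).  Genes absent from the
    annotation are treated as non-secreted and logged.
    """
    uncovered = [g for g in genes if g not in annotation.index]
    if uncovered:
        log.warning(
            "%d gene(s) missing from annotation, treated as non-secreted", len(uncovered)
        )
    secreted = set(annotation.index[annotation["secreted"].astype(bool)])
    return genes & secreted


def variability_filter(
    matrix: ExpressionMatrix, genes: set[str], params: ScreenParams
) -> tuple[set[str], set[str]]:
    """Split genes into (retained, disqualified) by the CV criterion.

    A gene is disqualified iff its across-sample sd (n-1 denominator)
    strictly exceeds ``cv_threshold`` times its mean.  Mean-zero genes
    have an undefined ratio and are disqualified by convention.
    """
    unknown = genes - set(matrix.values.index)
    if unknown:
        raise KeyError(f"genes not in matrix: {sorted(unknown)[:5]}")
    retained: set[str] = set()
    disqualified: set[str] = set()
    sub = matrix.values.loc[sorted(genes)]
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    for g in sub.index:
        if means[g] == 0:
            log.info("gene %s has zero mean; disqualified by convention", g)
            disqualified.add(g)
        elif sds[g] > params.cv_threshold * means[g]:
            disqualified.add(g)
        else:
            retained.add(g)
    return retained, disqualified


def run_screen(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    params: ScreenParams | None = None,
) -> ScreenResult:
    """Run the full cascade and account for every stage.

    Returns per-gene flags (passed_expression, passed_secretome,
    passed_variability, final_candidate) with mean, sd and sd/mean ratio,
    the stage counts, and the candidate list ordered by mean coverage
    descending (ties broken by gene id).
    """
    params = params or ScreenParams()
    _require_nonempty(matrix)

    expressed = filter_expressed(matrix, params)
    secreted = intersect_secretome(expressed, annotation)
    retained, disqualified = variability_filter(matrix, secreted, params)

    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(means > 0, sds / means, np.inf)
    per_gene = pd.DataFrame(
        {
            "mean": means,
            "sd": sds,
            "cv": ratio,
            "secreted": [
                bool(annotation["secreted"].get(g, False)) for g in matrix.values.index
            ],
            "passed_expression": matrix.values.index.isin(sorted(expressed)),
            "passed_secretome": matrix.values.index.isin(sorted(secreted)),
            "passed_variability": matrix.values.index.isin(sorted(retained)),
        },
        index=matrix.values.index,
    )
    per_gene["final_candidate"] = (
        per_gene["passed_expression"]
        & per_gene["passed_secretome"]
        & per_gene["passed_variability"]
    )

    candidates = sorted(retained, key=lambda g: (-means[g], g))
    stage_counts = {
        "n_input": int(len(matrix.values.index)),
        "n_expressed": len(expressed),
        "n_secreted": len(secreted),
        "n_disqualified": len(disqualified),
        "n_candidates": len(retained),
    }
    return ScreenResult(per_gene=per_gene, stage_counts=stage_counts, candidates=candidates)


def retained_percentages(n_retained: int, n_disqualified: int) -> tuple[int, int]:
    """Round-half-up percentages of retained and disqualified candidates."""
    total = n_retained + n_disqualified
    if total == 0:
        raise ValueError("no candidates to account for")
    pct = lambda k: int(math.floor(100.0 * k / total + 0.5))
    return pct(n_retained), pct(n_disqualified)
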