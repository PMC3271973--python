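"""Serial post-surgical marker surveillance.

Patients monitored through chemotherapy contribute an ordered series of
serum readings and an outcome label: NED (no evidence of disease) or AWD
(alive with disease).  Analyses are run in two modes: *composite*, where
each patient's readings are first averaged over the whole post-surgical
period, and *serial*, where all readings are pooled as individual
observations.  A concentration threshold (default 1000 ng/ml, the
ROC-derived working cutoff) splits readings into high/low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .stats import TestResult, ttest_raw

__all__ = [
    "SurveillanceSet",
    "SurveillanceParams",
    "composite_average",
    "fraction_above",
    "compare_outcomes",
]

OUTCOME_LABELS = ("NED", "AWD")


@dataclass
class SurveillanceSet:
    """Long-format serial readings: one row per patient visit.

    ``readings`` columns: patient_id, outcome ('NED'|'AWD'), visit
    (index or date, ordered within patient), level (ng/ml, >= 0).
    """

    readings: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"patient_id", "outcome", "visit", "level"}
        missing = required - set(self.readings.columns)
        if missing:
            raise ValueError(f"surveillance table missing columns: {sorted(missing)}")
        bad = set(self.readings["outcome"]) - set(OUTCOME_LABELS)
        if bad:
            raise ValueError(f"unknown outcome labels: {sorted(bad)}")
        if (self.readings["level"] < 0).any():
            raise ValueError("levels must be >= 0")
        if self.readings.empty:
            raise ValueError("surveillance set has no readings")

    def patients(self, outcome: str | None = None) -> list[str]:
        df = self.readings
        if outcome is not None:
            df = df[df["outcome"] == outcome]
        return list(pd.unique(df["patient_id"]))


@dataclass(frozen=True)
class SurveillanceParams:
    """threshold: ng/ml cutoff separating high from low readings (> is high)."""

    threshold: float = 1000.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")


def composite_average(sset: SurveillanceSet) -> pd.Series:
    """Per-patient composite value: mean of all that patient's readings."""
    return sset.readings.groupby("patient_id", sort=False)["level"].mean()


def fraction_above(
    sset: SurveillanceSet,
    params: SurveillanceParams | None = None,
    outcome: str | None = None,
) -> tuple[int, int, int]:
    """Pooled count of readings strictly above the threshold.

    Pools every serial reading of every patient with the given outcome
    (or all patients when ``outcome`` is None) and returns (count above,
    total, percentage rounded half-up to an integer).
    """
    params = params or SurveillanceParams()
    df = sset.readings
    if outcome is not None:
        df = df[df["outcome"] == outcome]
    if df.empty:
        raise ValueError(f"no readings for outcome {outcome!r}")
    above = int((df["level"] > params.threshold).sum())
    total = int(len(df))
    pct = int(math.floor(100.0 * above / total + 0.5))
    return above, total, pct


def compare_outcomes(
    sset: SurveillanceSet, mode: str = "composite", variant: str = "welch"
) -> TestResult:
    """Two-sided t test of NED vs AWD levels.

    mode 'composite' compares per-patient composite averages (needs >= 2
    patients per outcome); mode 'serial' pools all readings as independent
    observations (needs >= 2 readings per outcome) — the serial convention
    ignores within-patient correlation and is flagged in the result note.
    """
    if mode not in ("composite", "serial"):
        raise ValueError(f"unknown mode: {mode}")
    df = sset.readings
    if mode == "composite":
        comp = composite_average(sset)
        outcome_of = df.drop_duplicates("patient_id").set_index("patient_id")["outcome"]
        ned = comp[outcome_of[comp.index] == "NED"]
        awd = comp[outcome_of[comp.index] == "AWD"]
        note = None
    else:
        ned = df.loc[df["outcome"] == "NED", "level"]
        awd = df.loc[df["outcome"] == "AWD", "level"]
        note = "serial readings treated as independent observations"
    if len(ned) < 2 or len(awd) < 2:
        raise ValueError(f"mode {mode!r} needs >= 2 observations per outcome group")
    res = ttest_raw(ned.to_numpy(), awd.to_numpy(), variant=variant)
    return TestResult(
        res.statistic, res.df, res.p, comparison=f"NED vs AWD ({mode})", note=note or res.note
    )
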