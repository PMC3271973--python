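"""Synthetic data with the statistical structure the analyses assume.

The study's tumor expression matrix and serum cohorts are not publicly
deposited; only group-level summaries are published.  This module
generates stand-ins that match those summaries so every downstream stage
(screen, statistics, ROC, surveillance, ELISA reduction) can be exercised
and tested end-to-end:

* **Expression matrices** — zero-inflated lognormal coverage across a
  22-sample-style cohort, with a designated secreted subset and optional
  "spike" genes constructed to be highly expressed (inside a target
  top-fraction) with low coefficient of variation, i.e. genes the
  candidate screen must find.
* **Serum cohorts** — per-group lognormal concentrations with parameters
  solved by analytic moment matching, so requested means and SDs are the
  distributional truth (sigma^2 = ln(1 + s^2/m^2), mu = ln m - sigma^2/2).
  Group SDs of the order of the means rule out a normal model on positive
  support; lognormal is the natural choice.
* **Surveillance series** — per-patient serial readings with NED/AWD
  outcome structure.
* **ELISA plates** — standards plus samples generated from a known 4PL
  response with Gaussian absorbance noise.

Every simulator is a pure function of its spec, whose integer seed fully
determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohorts
from .expression import ExpressionMatrix
from .surveillance import SurveillanceSet

__all__ = [
    "SpikeGene",
    "ExpressionSimSpec",
    "SerumSimSpec",
    "SurveillanceSimSpec",
    "simulate_expression",
    "simulate_serum_cohort",
    "simulate_surveillance",
    "simulate_plate",
    "lognormal_params",
]

_DEFAULT_TUMOR_GROUPS = {g: m.n for g, m in cohorts.TUMOR_COVERAGE_GROUPS.items()}


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and sd."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class SpikeGene:
    """A planted screen-positive gene.

    The gene is drawn so that, in every sample, it sits within the top
    ``top_fraction`` of expressed genes, and its across-sample coefficient
    of variation stays below ``max_cv``.
    """

    gene_id: str
    top_fraction: float = 0.075
    max_cv: float = 0.5


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Spec for the tumor coverage matrix.

    Defaults emulate the sequenced tumor panel: 22 samples across five
    disease groups, ~20k annotated genes of which roughly half are
    expressed above 1 RPKM, a 17% secreted fraction mirroring the
    working-set/expressed ratio, and moderate per-sample noise.
    """

    n_genes: int = 20000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_TUMOR_GROUPS)
    )
    log_mean: float = 0.0
    log_sd: float = 2.0
    sample_log_sd: float = 0.25
    secretome_fraction: float = 0.17
    spike_genes: tuple[SpikeGene, ...] = ()
    zero_inflation: float = 0.25
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        if self.n_genes < len(self.spike_genes):
            raise ValueError("n_genes: fewer genes than spike genes")
        if not self.group_sizes or any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group_sizes: every group needs n >= 1")
        if not 0 <= self.secretome_fraction <= 1:
            raise ValueError("secretome_fraction: must be in [0, 1]")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation: must be in [0, 1]")
        for sg in self.spike_genes:
            if not 0 < sg.top_fraction <= 1:
                raise ValueError("spike_genes: top_fraction must be in (0, 1]")
            if not sg.max_cv > 0:
                raise ValueError("spike_genes: max_cv must be > 0")
        if self.sample_log_sd < 0 or self.log_sd <= 0:
            raise ValueError("log_sd: dispersion parameters must be positive")


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a coverage matrix and matching gene annotation.

    Returns the matrix and an annotation DataFrame indexed by gene id with
    columns ``length_bp`` and ``secreted``.  Spike genes are always
    flagged secreted (they are planted to survive the secretome stage).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_g, n_s = spec.n_genes, spec.n_samples

    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    spike_ids = [sg.gene_id for sg in spec.spike_genes]
    if len(set(spike_ids)) != len(spike_ids):
        raise ValueError("spike_genes: duplicate gene ids")
    # spike genes replace the last baseline ids
    for k, sid in enumerate(spike_ids):
        gene_ids[n_g - len(spike_ids) + k] = sid

    sample_ids, groups = [], {}
    for g, n in spec.group_sizes.items():
        for i in range(n):
            sid = f"{g}_{i + 1}"
            sample_ids.append(sid)
            groups[sid] = g

    base_mean = rng.lognormal(spec.log_mean, spec.log_sd, size=n_g)
    noise = rng.lognormal(0.0, spec.sample_log_sd, size=(n_g, n_s))
    values = base_mean[:, None] * noise
    if spec.zero_inflation > 0:
        values[rng.random((n_g, n_s)) < spec.zero_inflation] = 0.0

    # plant spikes: mean placed high enough that the expected fraction of
    # gene-sample values above it is one third of the requested top
    # fraction, CV well under the cap
    from scipy.stats import norm

    total_sd = math.hypot(spec.log_sd, spec.sample_log_sd)
    for sg in spec.spike_genes:
        row = gene_ids.index(sg.gene_id)
        z = norm.ppf(1.0 - sg.top_fraction / 3.0)
        level = math.exp(spec.log_mean + z * total_sd)
        sigma = min(0.2, sg.max_cv / 2.5)
        values[row, :] = level * rng.lognormal(0.0, sigma, size=n_s)

    secreted = np.zeros(n_g, dtype=bool)
    n_secreted = int(math.floor(spec.secretome_fraction * n_g))
    spike_rows = [gene_ids.index(s) for s in spike_ids]
    secreted[spike_rows] = True
    remaining = max(0, n_secreted - len(spike_rows))
    pool = np.setdiff1d(np.arange(n_g), spike_rows)
    if remaining:
        secreted[rng.choice(pool, size=remaining, replace=False)] = True

    lengths = np.exp(rng.normal(7.5, 0.6, size=n_g)).astype(int) + 200
    annotation = pd.DataFrame(
        {"length_bp": lengths, "secreted": secreted}, index=pd.Index(gene_ids, name="gene_id")
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=annotation.index, columns=sample_ids),
        sample_groups=pd.Series(groups),
    )
    return matrix, annotation


@dataclass(frozen=True)
class SerumSimSpec:
    """Spec for a serum cohort: per-group (n, mean ng/ml, sd ng/ml).

    Defaults are the published validation-cohort summaries (82 healthy
    controls, 6 benign, 16 early, 40 late, 16 recurrent).
    """

    group_specs: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: {
            g: (m.n, m.mean, m.sd) for g, m in cohorts.SERUM_GROUPS.items()
        }
    )
    distribution: str = "lognormal"
    seed: int = 0

    def validate(self) -> None:
        if self.distribution != "lognormal":
            raise ValueError("distribution: only 'lognormal' is supported")
        if not self.group_specs:
            raise ValueError("group_specs: at least one group required")
        for g, (n, mean, sd) in self.group_specs.items():
            if n < 1:
                raise ValueError(f"group_specs[{g}]: n must be >= 1")
            if mean <= 0:
                raise ValueError(f"group_specs[{g}]: mean must be > 0")
            if sd < 0:
                raise ValueError(f"group_specs[{g}]: sd must be >= 0")


def simulate_serum_cohort(spec: SerumSimSpec) -> pd.DataFrame:
    """Draw a serum cohort table (subject_id, group, igfbp4 ng/ml).

    Concentrations are lognormal with analytically moment-matched
    parameters, so each group's distributional mean and sd equal the
    requested values; sample sizes are exactly as requested and all
    draws are strictly positive.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g, (n, mean, sd) in spec.group_specs.items():
        if sd == 0:
            vals = np.full(n, mean)
        else:
            mu, sigma = lognormal_params(mean, sd)
            vals = rng.lognormal(mu, sigma, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{g}_{i + 1}" for i in range(n)],
                    "group": g,
                    "igfbp4": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SurveillanceSimSpec:
    """Spec for serial surveillance series.

    Defaults: five NED and five AWD patients with 5-9 visits each, levels
    lognormal around the published pooled group means with dispersion
    comparable to the serum case groups (sd = 60% of mean).
    """

    n_patients: dict[str, int] = field(default_factory=lambda: {"NED": 5, "AWD": 5})
    visits_per_patient: tuple[int, int] = (5, 9)
    level_specs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            g: (m, 0.6 * m) for g, m in cohorts.SURVEILLANCE_GROUP_MEANS.items()
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.n_patients or any(n < 1 for n in self.n_patients.values()):
            raise ValueError("n_patients: every outcome needs >= 1 patient")
        lo, hi = self.visits_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_patient: need 1 <= min <= max")
        for g, (mean, sd) in self.level_specs.items():
            if mean <= 0 or sd < 0:
                raise ValueError(f"level_specs[{g}]: mean > 0 and sd >= 0 required")
        missing = set(self.n_patients) - set(self.level_specs)
        if missing:
            raise ValueError(f"level_specs: missing outcomes {sorted(missing)}")


def simulate_surveillance(spec: SurveillanceSimSpec) -> SurveillanceSet:
    """Draw per-patient serial reading series with outcome labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.visits_per_patient
    rows = []
    for outcome, n_pat in spec.n_patients.items():
        mean, sd = spec.level_specs[outcome]
        for p in range(n_pat):
            n_visits = int(rng.integers(lo, hi + 1))
            if sd == 0:
                levels = np.full(n_visits, mean)
            else:
                mu, sigma = lognormal_params(mean, sd)
                levels = rng.lognormal(mu, sigma, size=n_visits)
            for v, lvl in enumerate(levels):
                rows.append(
                    {
                        "patient_id": f"{outcome}_{p + 1}",
                        "outcome": outcome,
                        "visit": v + 1,
                        "level": lvl,
                    }
                )
    return SurveillanceSet(readings=pd.DataFrame(rows))


def simulate_plate(
    curve_params: tuple[float, float, float, float] = (0.05, 1.2, 300.0, 2.4),
    standard_concs: tuple[float, ...] = (0.0, 25.0, 75.0, 225.0, 675.0, 2025.0),
    sample_concs: tuple[float, ...] | None = None,
    n_samples: int = 40,
    noise_sd: float = 0.0,
    background: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthesize one ELISA plate table from a known 4PL response.

    ``curve_params`` are (a, b, c, d) of the 4PL in the plate-reduction
    parameterization (a = zero-concentration asymptote).  Standards and
    samples are laid out in duplicate; Gaussian noise of ``noise_sd`` is
    added to each raw absorbance.  Returns the plate table and the true
    sample concentrations keyed by replicate group.
    """
    from .elisa import four_param_logistic

    a, b, c, d = curve_params
    rng = np.random.default_rng(seed)
    if sample_concs is None:
        lo, hi = min(x for x in standard_concs if x > 0), max(standard_concs)
        sample_concs = tuple(
            np.exp(rng.uniform(np.log(lo * 1.5), np.log(hi / 1.5), size=n_samples))
        )
    rows = []
    well = iter(f"{r}{c_:02d}" for r in "ABCDEFGH" for c_ in range(1, 13))
    for i, conc in enumerate(standard_concs):
        for _ in range(2):
            y = four_param_logistic(conc, a, b, c, d) + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "well_id": next(well),
                    "role": "standard",
                    "known_conc": conc,
                    "a450": y + background,
                    "a620": background,
                    "replicate_group": f"STD{i}",
                }
            )
    truths = {}
    for i, conc in enumerate(sample_concs):
        group = f"S{i + 1}"
        truths[group] = float(conc)
        for _ in range(2):
            y = four_param_logistic(conc, a, b, c, d) + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "well_id": next(well),
                    "role": "sample",
                    "known_conc": np.nan,
                    "a450": y + background,
                    "a620": background,
                    "replicate_group": group,
                }
            )
    return pd.DataFrame(rows), pd.Series(truths, name="true_conc")
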