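"""Sandwich-ELISA plate reduction.

Absorbance is read at 450 nm with a 620 nm background correction.  Each
plate carries its own standard series; a four-parameter logistic (4PL)

    y = d + (a - d) / (1 + (x / c)^b)

is fit to the background-corrected standards by least squares and inverted
analytically to map sample absorbances to concentrations (ng/ml).  In this
parameterization ``a`` is the zero-concentration asymptote, ``d`` the
saturation asymptote, ``c`` the inflection concentration and ``b > 0`` the
slope; an ascending (sandwich) plate simply has a < d.  Duplicate wells
are averaged on the concentration scale.  Calibration is strictly
per-plate: a curve must never be applied to wells from another plate.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import geometric_mean

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationCurve",
    "background_correct",
    "four_param_logistic",
    "fit_standard_curve",
    "interpolate_concentration",
    "reduce_plate",
]


def background_correct(a450, a620):
    """Background-corrected absorbance: A450 - A620 (elementwise)."""
    a450 = np.asarray(a450, dtype=float)
    a620 = np.asarray(a620, dtype=float)
    if not (np.isfinite(a450).all() and np.isfinite(a620).all()):
        raise ValueError("absorbances must be finite")
    out = a450 - a620
    return float(out) if out.ndim == 0 else out


def four_param_logistic(x, a, b, c, d):
    """4PL response y = d + (a - d) / (1 + (x/c)^b); defined for x >= 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted per-plate 4PL standard curve.

    ``conc_range`` is the concentration span of the standards; interpolated
    samples outside it are extrapolations and flagged by the caller.
    """

    a: float
    b: float
    c: float
    d: float
    residual_rms: float
    conc_range: tuple[float, float]

    def forward(self, x):
        return four_param_logistic(x, self.a, self.b, self.c, self.d)

    def inverse(self, y: float) -> float:
        return interpolate_concentration(self, y)


def fit_standard_curve(
    concentrations, absorbances, replicate_groups=None
) -> CalibrationCurve:
    """Least-squares 4PL fit to (known concentration, corrected absorbance).

    Requires at least 5 distinct standard concentrations.  Duplicate
    standards sharing a ``replicate_groups`` key (or, absent that, the
    same concentration) are averaged before fitting.  Degenerate standards
    (flat response) raise.
    """
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.shape != absb.shape:
        raise ValueError("concentrations and absorbances must align")
    key = conc if replicate_groups is None else np.asarray(replicate_groups)
    df = pd.DataFrame({"key": key, "conc": conc, "absb": absb})
    agg = df.groupby("key", sort=False).mean()
    x = agg["conc"].to_numpy()
    y = agg["absb"].to_numpy()
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct standard concentrations")
    if np.ptp(y) == 0:
        raise ValueError("degenerate standards: identical absorbance at all levels")

    order = np.argsort(x)
    x, y = x[order], y[order]
    nonzero = x[x > 0]
    # a anchored at the low-concentration end, d at the high end; the fit
    # then converges for both ascending and descending plates with b > 0
    p0 = [y[0], 1.0, geometric_mean(nonzero), y[-1]]
    lo = [-np.inf, 1e-6, 1e-12, -np.inf]
    hi = [np.inf, np.inf, np.inf, np.inf]
    popt, _ = curve_fit(
        four_param_logistic, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    a, b, c, d = (float(v) for v in popt)
    resid = y - four_param_logistic(x, a, b, c, d)
    rms = float(np.sqrt(np.mean(resid**2)))
    if not all(np.isfinite([a, b, c, d, rms])):
        raise RuntimeError("standard-curve fit did not converge to finite parameters")
    return CalibrationCurve(a, b, c, d, rms, (float(x.min()), float(x.max())))


def interpolate_concentration(curve: CalibrationCurve, absorbance: float) -> float:
    """Invert the 4PL analytically: x = c * ((a-d)/(y-d) - 1)^(1/b).

    The absorbance must lie strictly between the two asymptotes; values at
    or beyond either asymptote have no finite concentration and raise.
    """
    y = float(absorbance)
    lo, hi = sorted((curve.a, curve.d))
    if not lo < y < hi:
        raise ValueError(
            f"absorbance {y:.4f} outside the open asymptote interval ({lo:.4f}, {hi:.4f})"
        )
    ratio = (curve.a - curve.d) / (y - curve.d) - 1.0
    return float(curve.c * ratio ** (1.0 / curve.b))


def reduce_plate(plate: pd.DataFrame) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Full reduction of one plate table to per-replicate concentrations.

    ``plate`` columns: well_id, role ('standard'|'control'|'sample'),
    known_conc (standards), a450, a620, replicate_group.  Returns a table
    of (replicate_group, role, concentration ng/ml, n_wells, out_of_range)
    and the plate's calibration curve.  Duplicates are averaged on the
    concentration scale; wells whose absorbance falls outside the curve's
    asymptotes are reported with NaN and flagged rather than dropped.
    """
    required = {"well_id", "role", "a450", "a620", "replicate_group"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    corrected = background_correct(plate["a450"], plate["a620"])
    plate = plate.assign(corrected=corrected)

    std = plate[plate["role"] == "standard"]
    if std.empty:
        raise ValueError("plate has no standard wells")
    curve = fit_standard_curve(
        std["known_conc"], std["corrected"], replicate_groups=std["replicate_group"]
    )

    rows = []
    unknowns = plate[plate["role"].isin(["control", "sample"])]
    for (group, role), wells in unknowns.groupby(["replicate_group", "role"], sort=False):
        concs, flagged = [], False
        for y in wells["corrected"]:
            try:
                concs.append(interpolate_concentration(curve, y))
            except ValueError:
                flagged = True
        rows.append(
            {
                "replicate_group": group,
                "role": role,
                "concentration": float(np.mean(concs)) if concs else float("nan"),
                "n_wells": len(wells),
                "out_of_range": flagged,
            }
        )
    return pd.DataFrame(rows), curve
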