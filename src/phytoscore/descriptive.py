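"""Summary statistics, derived quality ratios and calibration-line quantitation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import MeasurementTable
from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class DescriptiveSummary:
    """Per-variable summary. ``cv_percent`` is NaN (flagged) when the mean is 0."""

    variable: str
    n: int
    min: float
    max: float
    mean: float
    median: float
    sd: float
    se: float
    cv_percent: float
    cv_defined: bool = True


def summarize(values: Sequence[float], variable: str = "") -> DescriptiveSummary:
    """Summary statistics with sample (n-1) SD, SE = sd/sqrt(n) and CV = 100*sd/mean.

    The median of an even-length series is the midpoint of the two central
    values. ``n == 1`` yields sd = se = cv = 0 by convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("summarize: empty input")
    if np.isnan(arr).any():
        raise ValidationError(f"summarize: variable {variable!r} has missing values")
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n >= 2 else 0.0
    se = sd / math.sqrt(n)
    if sd == 0.0:
        cv, cv_defined = 0.0, True
    elif mean == 0.0:
        cv, cv_defined = float("nan"), False
    else:
        cv, cv_defined = 100.0 * sd / mean, True
    return DescriptiveSummary(
        variable=variable,
        n=n,
        min=float(arr.min()),
        max=float(arr.max()),
        mean=mean,
        median=float(np.median(arr)),
        sd=sd,
        se=se,
        cv_percent=cv,
        cv_defined=cv_defined,
    )


def describe_table(table: MeasurementTable, by: str = "overall") -> pd.DataFrame:
    """One summary row per (variable[, region])."""
    if by not in ("overall", "region"):
        raise ValueError(f"describe_table: unknown grouping {by!r}")
    rows = []
    for var in table.variables:
        table.require_complete([var], stage="describe")
        if by == "overall":
            s = summarize(table.data[var], var)
            rows.append({"grouping": "overall", **s.__dict__})
        else:
            for region in table.regions:
                vals = table.data.loc[table.data["region"] == region, var]
                s = summarize(vals, var)
                rows.append({"grouping": region, **s.__dict__})
    return pd.DataFrame(rows)


def sugar_acid_ratio(total_polysaccharide, total_acid):
    """Elementwise polysaccharide/acid quotient, computed per replicate.

    Note a mean of per-replicate ratios differs from the ratio of means;
    this function is applied before any averaging.
    """
    poly = np.asarray(total_polysaccharide, dtype=float)
    acid = np.asarray(total_acid, dtype=float)
    if np.any(acid <= 0):
        raise DomainError("sugar_acid_ratio: total_acid must be > 0")
    out = poly / acid
    return float(out) if out.ndim == 0 else out


def add_sugar_acid_ratio(
    table: MeasurementTable,
    polysaccharide: str = "total_polysaccharide",
    acid: str = "total_acid",
    name: str = "sugar_acid_ratio",
) -> MeasurementTable:
    """Return a copy of *table* with the per-replicate ratio column appended."""
    df = table.data.copy()
    df[name] = sugar_acid_ratio(df[polysaccharide], df[acid])
    units = dict(table.units)
    units[name] = ""
    return MeasurementTable(df, units=units)


@dataclass(frozen=True)
class CalibrationLine:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValidationError("calibration valid_range must have low < high")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError("r_squared must lie in [0, 1]")

    def response_at(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class Quantified:
    concentration: float
    extrapolated: bool


def fit_calibration(
    concentrations: Sequence[float],
    responses: Sequence[float],
    analyte: str = "",
) -> CalibrationLine:
    """Ordinary least squares line response = slope*conc + intercept."""
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if x.size < 3 or x.size != y.size:
        raise DomainError("fit_calibration: need >= 3 paired points")
    if np.ptp(x) == 0 or x.std() == 0:
        raise DomainError("fit_calibration: zero concentration variance")
    fit = stats.linregress(x, y)
    return CalibrationLine(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(float(fit.rvalue) ** 2, 1.0),
        valid_range=(float(x.min()), float(x.max())),
    )


def quantify(line: CalibrationLine, response: float) -> Quantified:
    """Inverse prediction (response - intercept)/slope, flagged when outside range."""
    if line.slope == 0:
        raise DomainError("quantify: zero slope")
    conc = (response - line.intercept) / line.slope
    lo, hi = line.valid_range
    return Quantified(concentration=conc, extrapolated=not (lo <= conc <= hi))
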