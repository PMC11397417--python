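"""Synthetic replicate-level study generator.

The raw measurements behind the published study design (12 regions x 4
replicate trees, 8 mineral elements + 6 quality indicators) are not public.
This module generates tables with the same design and a configurable
statistical structure — per-variable region-mean ranges, within-region
coefficients of variation and a target replicate-level correlation matrix —
so every downstream stage can be exercised and power-tested.

The noise model is multiplicative Gaussian: a replicate value is
``mean * (1 + cv/100 * z)`` with ``z`` drawn from a correlated standard
normal (via a factor of the repaired target correlation matrix), floored at
a small positive epsilon.  A lognormal variant with matched CV is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    DEFAULT_UNITS,
    MeasurementTable,
    QUALITY_VARIABLES,
    VariablePanel,
    default_panels,
)
from .errors import ValidationError

_EPS_FLOOR = 1e-9

#: per-variable (low, high) for uniformly drawn region means
DEFAULT_MEAN_RANGES: dict[str, tuple[float, float]] = {
    "K": (3.89, 5.44),
    "Ca": (0.89, 2.32),
    "Zn": (31.11, 102.15),
    "Mg": (4.27, 10.23),
    "Cu": (4.22, 13.52),
    "Fe": (0.53, 2.03),
    "Se": (0.63, 2.16),
    "Mn": (0.24, 0.73),
    "total_polysaccharide": (16.35, 38.50),
    "total_acid": (0.81, 3.34),
    "sugar_acid_ratio": (7.21, 31.69),
    "total_polyphenols": (1.27, 3.81),
    "l_malic_acid": (0.65, 2.13),
    "aa2bg": (1.56, 4.55),
}

#: per-variable within-region CV in percent
DEFAULT_CV_PERCENT: dict[str, float] = {
    "K": 5.82,
    "Ca": 18.43,
    "Zn": 32.95,
    "Mg": 20.22,
    "Cu": 27.03,
    "Fe": 31.55,
    "Se": 31.88,
    "Mn": 22.05,
    "total_polysaccharide": 17.37,
    "total_acid": 32.50,
    "sugar_acid_ratio": 49.50,
    "total_polyphenols": 23.14,
    "l_malic_acid": 28.06,
    "aa2bg": 23.03,
}

#: seed pairwise correlations (unlisted pairs default to 0)
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("K", "Mg"): -0.48,
    ("K", "Mn"): 0.29,
    ("Ca", "Zn"): 0.42,
    ("Ca", "Mg"): 0.51,
    ("Ca", "Fe"): -0.56,
    ("Ca", "Mn"): -0.37,
    ("Zn", "Se"): 0.72,
    ("Mg", "Cu"): -0.33,
    ("Mg", "Mn"): -0.46,
    ("Cu", "Fe"): -0.59,
    ("Fe", "Mn"): 0.43,
    ("Se", "Mn"): -0.55,
    ("total_polysaccharide", "sugar_acid_ratio"): 0.32,
    ("total_acid", "sugar_acid_ratio"): -0.86,
    ("total_acid", "total_polyphenols"): 0.70,
    ("total_acid", "l_malic_acid"): 0.31,
    ("total_acid", "aa2bg"): 0.83,
    ("sugar_acid_ratio", "total_polyphenols"): -0.48,
    ("sugar_acid_ratio", "l_malic_acid"): -0.30,
    ("sugar_acid_ratio", "aa2bg"): -0.71,
    ("total_polyphenols", "l_malic_acid"): 0.59,
    ("total_polyphenols", "aa2bg"): 0.47,
}


def default_correlation_matrix(variables: Sequence[str]) -> pd.DataFrame:
    """Correlation matrix seeded from the default pairwise values, PSD-repaired."""
    p = len(variables)
    mat = np.eye(p)
    index = {v: i for i, v in enumerate(variables)}
    for (a, b), r in DEFAULT_CORRELATIONS.items():
        if a in index and b in index:
            mat[index[a], index[b]] = mat[index[b], index[a]] = r
    mat = nearest_psd_correlation(mat)
    return pd.DataFrame(mat, index=list(variables), columns=list(variables))


def nearest_psd_correlation(mat: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues to ``min_eig`` and restore the unit diagonal."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValidationError("correlation matrix must be symmetric")
    if np.any(np.abs(mat) > 1 + 1e-12):
        raise ValidationError("correlation entries must lie in [-1, 1]")
    w, v = np.linalg.eigh(mat)
    if w.min() >= 0:
        out = mat.copy()
    else:
        w = np.clip(w, min_eig, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    w2 = np.linalg.eigvalsh(out)
    if w2.min() < -1e-10:
        raise ValidationError("correlation matrix is not PSD after repair")
    return out


@dataclass
class SimulationConfig:
    """Configuration for a synthetic study."""

    n_regions: int = 12
    n_replicates: int = 4
    panels: list[VariablePanel] = field(default_factory=default_panels)
    region_mean_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_RANGES)
    )
    within_region_cv: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CV_PERCENT)
    )
    target_correlation: pd.DataFrame | None = None
    correlate_region_means: bool = False
    noise: str = "normal"  # or "lognormal"
    seed: int = 0

    @property
    def variables(self) -> list[str]:
        out: list[str] = []
        for panel in self.panels:
            out.extend(panel.members)
        return out

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_replicates < 1:
            raise ValidationError("n_regions and n_replicates must be >= 1")
        if self.noise not in ("normal", "lognormal"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        for var in self.variables:
            if var not in self.region_mean_ranges:
                raise ValidationError(f"no mean range for variable {var!r}")
            lo, hi = self.region_mean_ranges[var]
            if not 0 <= lo < hi:
                raise ValidationError(f"bad mean range for {var!r}: ({lo}, {hi})")
            if self.within_region_cv.get(var, 0.0) < 0:
                raise ValidationError(f"negative CV for {var!r}")
        if self.target_correlation is None:
            self.target_correlation = default_correlation_matrix(self.variables)
        else:
            tc = self.target_correlation
            if isinstance(tc, pd.DataFrame):
                tc = tc.loc[self.variables, self.variables]
                mat = nearest_psd_correlation(tc.to_numpy())
            else:
                mat = nearest_psd_correlation(np.asarray(tc, dtype=float))
            self.target_correlation = pd.DataFrame(
                mat, index=self.variables, columns=self.variables
            )

    def region_codes(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_regions)]


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a synthetic table."""

    region_means: pd.DataFrame  # regions x variables
    true_order: list[str] | None  # best region first; None when undefined
    order_defined: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "region_means": {
                r: {v: float(self.region_means.loc[r, v]) for v in self.region_means.columns}
                for r in self.region_means.index
            },
            "true_order": self.true_order,
            "order_defined": self.order_defined,
            "seed": self.seed,
        }


def _correlation_factor(corr: pd.DataFrame) -> np.ndarray:
    """Triangular-like factor L with L @ L.T == corr (eigh-based; works for PSD)."""
    w, v = np.linalg.eigh(corr.to_numpy())
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _composite_order(region_means: pd.DataFrame, quality_vars: Sequence[str]) -> list[str]:
    """Rank regions by the mean of z-scored quality variables (best first).

    This is the declared composite criterion recorded in PlantedTruth; the
    pipeline's PCA-based score is expected to recover it when the planted
    signal dominates.
    """
    sub = region_means.loc[:, list(quality_vars)]
    sd = sub.std(ddof=1)
    sd = sd.replace(0.0, 1.0)
    z = (sub - sub.mean()) / sd
    score = z.mean(axis=1)
    order = score.sort_values(ascending=False, kind="stable")
    return list(order.index)


def _quality_members(config: SimulationConfig) -> list[str]:
    out: list[str] = []
    for panel in config.panels:
        if panel.role == "quality":
            out.extend(panel.members)
    if not out:
        out = [v for v in config.variables if v in QUALITY_VARIABLES]
    return out


def _assemble_table(
    config: SimulationConfig, region_means: pd.DataFrame, rng: np.random.Generator
) -> MeasurementTable:
    variables = config.variables
    cvs = np.array([config.within_region_cv.get(v, 0.0) for v in variables]) / 100.0
    L = _correlation_factor(config.target_correlation)
    rows = []
    for region in config.region_codes():
        mu = region_means.loc[region].to_numpy()
        z = rng.standard_normal((config.n_replicates, len(variables))) @ L.T
        if config.noise == "normal":
            vals = mu * (1.0 + cvs * z)
        else:
            sigma = np.sqrt(np.log1p(cvs**2))
            vals = mu * np.exp(sigma * z - sigma**2 / 2.0)
        vals = np.maximum(vals, _EPS_FLOOR)
        for j in range(config.n_replicates):
            row: dict[str, object] = {
                "sample_id": f"{region}-{j + 1}",
                "region": region,
                "species": region_means.loc[region, "__species__"]
                if "__species__" in region_means.columns
                else "sp1",
                **{v: vals[j, i] for i, v in enumerate(variables)},
            }
            rows.append(row)
    df = pd.DataFrame(rows, columns=["sample_id", "region", "species", *variables])
    units = {v: DEFAULT_UNITS.get(v, "") for v in variables}
    # percent columns may exceed 100 under extreme noise draws; cap to keep
    # tables valid without disturbing typical draws
    for v in variables:
        if units[v] == "%":
            df[v] = df[v].clip(upper=100.0)
    return MeasurementTable(df, units=units)


def generate_study(config: SimulationConfig) -> tuple[MeasurementTable, PlantedTruth]:
    """Draw a full synthetic study; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    variables = config.variables
    regions = config.region_codes()
    lo = np.array([config.region_mean_ranges[v][0] for v in variables])
    hi = np.array([config.region_mean_ranges[v][1] for v in variables])
    if config.correlate_region_means:
        # Gaussian copula: correlated normals -> uniforms -> range
        from scipy.stats import norm

        L = _correlation_factor(config.target_correlation)
        z = rng.standard_normal((config.n_regions, len(variables))) @ L.T
        u = norm.cdf(z)
    else:
        u = rng.uniform(size=(config.n_regions, len(variables)))
    means = lo + u * (hi - lo)
    region_means = pd.DataFrame(means, index=regions, columns=variables)
    table = _assemble_table(config, region_means, rng)
    truth = PlantedTruth(
        region_means=region_means,
        true_order=_composite_order(region_means, _quality_members(config)),
        order_defined=True,
        seed=config.seed,
    )
    return table, truth


def plant_ordering(
    config: SimulationConfig, effect_size: float
) -> tuple[MeasurementTable, PlantedTruth]:
    """Generate a study whose quality composite increases monotonically.

    Region means of every quality variable follow a geometric ramp whose
    adjacent-rank separation equals ``effect_size`` standard deviations of
    the regional mean estimator (within-region SD / sqrt(n_replicates)), so
    the planted ordering becomes recoverable once the effect dominates the
    noise.  The multiplicative ramp keeps all means strictly positive and
    strictly monotone for any effect size.  ``effect_size`` 0 leaves the
    ordering undefined.
    """
    if effect_size < 0:
        raise ValidationError("effect_size must be >= 0")
    rng = np.random.default_rng(config.seed)
    variables = config.variables
    regions = config.region_codes()
    quality_vars = set(_quality_members(config))
    n = config.n_regions

    perm = rng.permutation(n)  # perm[i] = rank position of region i (0 = best)
    means = np.empty((n, len(variables)))
    for j, var in enumerate(variables):
        lo, hi = config.region_mean_ranges[var]
        base = 0.5 * (lo + hi)
        if var in quality_vars and effect_size > 0:
            cv = config.within_region_cv.get(var, 0.0) / 100.0
            factor = 1.0 + effect_size * cv / np.sqrt(config.n_replicates)
            means[:, j] = base * factor ** ((n - 1) / 2.0 - perm)
        else:
            means[:, j] = lo + rng.uniform(size=n) * (hi - lo)
    region_means = pd.DataFrame(means, index=regions, columns=variables)
    table = _assemble_table(config, region_means, rng)
    if effect_size == 0:
        truth = PlantedTruth(region_means, None, False, config.seed)
    else:
        order = [regions[i] for i in np.argsort(perm, kind="stable")]
        truth = PlantedTruth(region_means, order, True, config.seed)
    return table, truth


def zero_noise(config: SimulationConfig) -> SimulationConfig:
    """Copy of *config* with all within-region CVs set to 0."""
    return replace(
        config, within_region_cv={v: 0.0 for v in config.variables}
    )
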