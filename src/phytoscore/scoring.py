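"""Comprehensive quality evaluation: component scores, weights, H0 and ranking.

Pipeline: aggregate replicates to region means, standardize the quality
panel, run correlation-matrix PCA, compute per-region component scores
``H_rk = sum_j Z_rj * w_jk``, weight the retained components by their
(unrounded) variance contributions normalized to 1, and rank regions by the
weighted sum ``H0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import MeasurementTable, VariablePanel, aggregate_regions, quality_panel
from .errors import AlignmentError, DomainError
from .multivariate import (
    PCAModel,
    ZTable,
    pca_correlation,
    retain_components,
    standardize,
    variance_contributions,
)


@dataclass
class CompositeScores:
    regions: list[str]
    h: pd.DataFrame  # regions x H1..Hk
    weights: np.ndarray  # normalized variance contributions, sum 1
    h0: pd.Series
    ranking: pd.DataFrame  # columns rank, region, h0
    tied: bool = False
    report: dict = field(default_factory=dict)


def component_scores(z: ZTable, model: PCAModel, k: int) -> pd.DataFrame:
    """Scores ``H_rk = sum_j Z_rj * w_jk`` for the first *k* components."""
    if list(z.variables) != list(model.variables):
        raise AlignmentError(
            "component_scores: variable order of ZTable and PCAModel differ"
        )
    if not 1 <= k <= model.n_variables:
        raise DomainError(f"component_scores: k must be in [1, {model.n_variables}]")
    w = model.csc.to_numpy()[:, :k]
    h = z.z.to_numpy() @ w
    return pd.DataFrame(h, index=z.regions, columns=[f"H{i + 1}" for i in range(k)])


def composite_weights(
    model: PCAModel | Sequence[float], k: int, p: int | None = None
) -> np.ndarray:
    """Weights ``v_i / sum_{j<=k} v_j`` from unrounded variance contributions.

    Accepts a fitted model, or a sequence of variance-contribution
    percentages (as printed, e.g. ``(58.880, 25.628, 9.147)``) directly.
    """
    if k < 1:
        raise DomainError("composite_weights: k must be >= 1")
    if isinstance(model, PCAModel):
        v, _ = variance_contributions(model)
    else:
        v = np.asarray(list(model), dtype=float)
    if k > v.size:
        raise DomainError(f"composite_weights: k={k} exceeds {v.size} components")
    v = v[:k]
    total = v.sum()
    if total <= 0:
        raise DomainError("composite_weights: non-positive variance total")
    return v / total


def composite_score(h: pd.DataFrame | np.ndarray, weights: Sequence[float]) -> pd.Series:
    """Weighted sum ``h0_r = sum_k weight_k * H_rk``."""
    weights = np.asarray(list(weights), dtype=float)
    if isinstance(h, pd.DataFrame):
        mat, index = h.to_numpy(dtype=float), h.index
    else:
        mat, index = np.asarray(h, dtype=float), None
    if mat.ndim != 2 or mat.shape[1] != weights.size:
        raise DomainError(
            f"composite_score: {mat.shape[1] if mat.ndim == 2 else '?'} columns "
            f"vs {weights.size} weights"
        )
    h0 = mat @ weights
    return pd.Series(h0, index=index, name="h0")


def rank_regions(h0: pd.Series | Sequence[float], regions: Sequence[str] | None = None
                 ) -> tuple[pd.DataFrame, bool]:
    """Descending ranking table with deterministic region-code tie-breaking."""
    if isinstance(h0, pd.Series) and regions is None:
        regions = list(h0.index)
    scores = np.asarray(list(h0), dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DomainError("rank_regions: non-finite score")
    regions = list(regions)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], regions[i]))
    tied = len(set(scores.tolist())) < len(scores)
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(scores) + 1),
            "region": [regions[i] for i in order],
            "h0": [scores[i] for i in order],
        }
    )
    return table, tied


def evaluate(
    table: MeasurementTable,
    panel: VariablePanel | None = None,
    rule: str = "fixed_k",
    k: int | None = 3,
    threshold: float | None = None,
    aggregate: bool = True,
    rounded_weights: bool = False,
) -> CompositeScores:
    """End-to-end comprehensive evaluation of a measurement table.

    By default the analysis runs on region means.  ``rounded_weights``
    reproduces the 2-decimal weight convention instead of the unrounded
    variance-contribution weights.
    """
    if panel is None:
        panel = quality_panel()
    panel.check_against(table)
    table.require_complete(panel.members, stage="score")
    regional = aggregate_regions(table) if aggregate else table
    z = standardize(regional, panel)
    model = pca_correlation(z)
    n_keep = retain_components(model, rule=rule, k=k, threshold=threshold)
    n_keep = max(1, n_keep)
    h = component_scores(z, model, n_keep)
    weights = composite_weights(model, n_keep)
    if rounded_weights:
        weights = np.round(weights, 2)
    h0 = composite_score(h, weights)
    ranking, tied = rank_regions(h0)
    v, cum = variance_contributions(model)
    lam = model.eigenvalues
    score_var = h.var(ddof=0 if len(h) < 2 else 1, axis=0).to_numpy()
    report = {
        "n_regions": len(z.regions),
        "n_retained": int(n_keep),
        "retention_rule": rule,
        "eigenvalues": [float(x) for x in lam],
        "variability_percent": [float(x) for x in v],
        "cumulative_percent": [float(x) for x in cum],
        "weights": [float(x) for x in weights],
        "rounded_weights": bool(rounded_weights),
        "consistency": {
            "eigenvalue_sum_minus_p": float(lam.sum() - model.n_variables),
            "max_abs_score_mean": float(np.abs(h.mean(axis=0)).max()),
            "max_abs_score_var_minus_eigenvalue": float(
                np.abs(score_var - lam[:n_keep]).max()
            ),
        },
        "tied": bool(tied),
    }
    return CompositeScores(
        regions=list(z.regions),
        h=h,
        weights=weights,
        h0=h0,
        ranking=ranking,
        tied=tied,
        report=report,
    )
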