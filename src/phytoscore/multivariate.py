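"""Standardization, correlation-matrix PCA and hierarchical clustering.

PCA is always performed on the sample correlation matrix (the panel mixes
units, and the eigenvalue sum then equals the number of variables).  The
model exposes the three coupled quantities used for composite scoring:

* loadings ``a_jk = eigvec_jk * sqrt(lambda_k)``
* component-score coefficients ``w_jk = a_jk / sqrt(lambda_k)`` (the
  eigenvector entries), applied to standardized variables
* variance contributions ``v_k = 100 * lambda_k / p``
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_data import MeasurementTable, VariablePanel
from .errors import DomainError, ValidationError

_EIG_CLAMP = 1e-12


@dataclass
class ZTable:
    """Column-standardized (mean 0, sample SD 1) region-level matrix."""

    z: pd.DataFrame  # regions x variables
    center: pd.Series
    scale: pd.Series

    @property
    def regions(self) -> list[str]:
        return list(self.z.index)

    @property
    def variables(self) -> list[str]:
        return list(self.z.columns)

    def validate(self, atol: float = 1e-10) -> None:
        means = self.z.mean(axis=0).to_numpy()
        sds = self.z.std(axis=0, ddof=1).to_numpy()
        if np.any(np.abs(means) > atol):
            raise ValidationError("ZTable column means are not 0")
        if np.any(np.abs(sds - 1.0) > atol):
            raise ValidationError("ZTable column SDs are not 1")


def standardize(
    table: MeasurementTable | pd.DataFrame,
    panel: VariablePanel | Sequence[str] | None = None,
) -> ZTable:
    """Column z-scores with sample (n-1) SD; center/scale retained."""
    if isinstance(table, MeasurementTable):
        if panel is None:
            panel = table.variables
        data = table.values(panel)
        data = data.set_axis(list(table.data["region"]), axis=0)
    else:
        cols = (
            list(panel.members)
            if isinstance(panel, VariablePanel)
            else (list(panel) if panel is not None else list(table.columns))
        )
        data = table.loc[:, cols]
    if len(data) < 2:
        raise DomainError("standardize: need >= 2 rows")
    if data.isna().any().any():
        raise ValidationError("standardize: missing values")
    center = data.mean(axis=0)
    scale = data.std(axis=0, ddof=1)
    zero = [v for v, s in scale.items() if s == 0]
    if zero:
        raise DomainError(f"standardize: zero-variance variable(s) {zero}")
    z = (data - center) / scale
    return ZTable(z=z, center=center, scale=scale)


@dataclass
class PCAModel:
    variables: list[str]
    eigenvalues: np.ndarray  # descending, >= 0
    eigenvectors: np.ndarray  # orthonormal columns (p x p)
    loadings: pd.DataFrame  # a_jk
    csc: pd.DataFrame  # w_jk = a_jk / sqrt(lambda_k)
    variability_percent: np.ndarray  # 100 * lambda_k / p
    cumulative_percent: np.ndarray

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def pca_correlation(z: ZTable) -> PCAModel:
    """Eigendecomposition of the sample correlation matrix of a ZTable.

    Components are ordered by descending eigenvalue; eigenvalues below 1e-12
    are clamped to 0.  Sign convention: each eigenvector is oriented so that
    its largest-|loading| entry is positive.
    """
    zm = z.z.to_numpy(dtype=float)
    if not np.all(np.isfinite(zm)):
        raise DomainError("pca_correlation: non-finite input")
    n = zm.shape[0]
    corr = zm.T @ zm / (n - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    w = np.where(w < _EIG_CLAMP, 0.0, w)
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    p = len(z.variables)
    loadings = v * np.sqrt(w)
    vperc = 100.0 * w / p
    comps = [f"PC{k + 1}" for k in range(p)]
    return PCAModel(
        variables=list(z.variables),
        eigenvalues=w,
        eigenvectors=v,
        loadings=pd.DataFrame(loadings, index=z.variables, columns=comps),
        csc=pd.DataFrame(v, index=z.variables, columns=comps),
        variability_percent=vperc,
        cumulative_percent=np.cumsum(vperc),
    )


def variance_contributions(
    model: PCAModel | Sequence[float], p: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component percentages ``100 * lambda_k / p`` and their running sum.

    Accepts a fitted model, or a bare eigenvalue sequence together with the
    number of variables ``p`` (defaulting to the sequence length).
    """
    if isinstance(model, PCAModel):
        lam = model.eigenvalues
        p = model.n_variables
    else:
        lam = np.asarray(list(model), dtype=float)
        if p is None:
            p = lam.size
    v = 100.0 * lam / p
    return v, np.cumsum(v)


def retain_components(
    model: PCAModel | Sequence[float],
    rule: str = "kaiser",
    k: int | None = None,
    threshold: float | None = None,
    p: int | None = None,
) -> int:
    """Number of components to keep under ``fixed_k`` / ``cumulative_threshold`` / ``kaiser``."""
    if isinstance(model, PCAModel):
        lam = model.eigenvalues
        p = model.n_variables
    else:
        lam = np.asarray(list(model), dtype=float)
        if p is None:
            p = lam.size
    if rule == "fixed_k":
        if k is None or not 1 <= k <= p:
            raise DomainError(f"retain_components: fixed_k needs 1 <= k <= {p}")
        return int(k)
    if rule == "kaiser":
        return int(np.sum(lam > 1.0))
    if rule == "cumulative_threshold":
        if threshold is None:
            raise DomainError("retain_components: cumulative_threshold needs a threshold")
        thr = threshold * 100.0 if threshold <= 1.0 else threshold
        _, cum = variance_contributions(lam, p=p)
        hits = np.nonzero(cum >= thr - 1e-12)[0]
        if hits.size == 0:
            return int(lam.size)
        return int(hits[0]) + 1
    raise ValueError(f"unknown retention rule {rule!r}")


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Complete-linkage merge history in scipy linkage format."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]
    metric: str
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.labels[i] for i in order]


def hcluster(
    rows,
    labels: Sequence[str] | None = None,
    metric: str = "euclidean",
    method: str = "complete",
    is_distance: bool = False,
    panel: VariablePanel | Sequence[str] | None = None,
    standardize_rows: bool = False,
) -> Dendrogram:
    """Agglomerative clustering (complete linkage, Euclidean by default).

    ``rows`` may be a MeasurementTable (one row per region after
    aggregation), a raw matrix / DataFrame, or a precomputed square distance
    matrix (``is_distance=True``).
    """
    from .inference import distance_matrix  # local import; no cycle at module load

    if isinstance(rows, MeasurementTable):
        d = distance_matrix(rows, panel=panel, metric=metric,
                            standardize=standardize_rows)
        labels = list(d.index)
        condensed = squareform(d.to_numpy(), checks=False)
    elif is_distance:
        arr = rows.to_numpy(dtype=float) if isinstance(rows, pd.DataFrame) else np.asarray(rows, dtype=float)
        if labels is None:
            labels = (
                list(rows.index) if isinstance(rows, pd.DataFrame)
                else [str(i) for i in range(arr.shape[0])]
            )
        condensed = squareform(arr, checks=True)
    else:
        arr = rows.to_numpy(dtype=float) if isinstance(rows, pd.DataFrame) else np.asarray(rows, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if labels is None:
            labels = (
                list(rows.index) if isinstance(rows, pd.DataFrame)
                else [str(i) for i in range(arr.shape[0])]
            )
        if standardize_rows:
            sd = arr.std(axis=0, ddof=1)
            arr = (arr - arr.mean(axis=0)) / sd
        d = distance_matrix(pd.DataFrame(arr), metric=metric)
        condensed = squareform(d.to_numpy(), checks=False)
    if not np.all(np.isfinite(condensed)):
        raise DomainError("hcluster: non-finite distances")
    if len(labels) < 2:
        raise DomainError("hcluster: need >= 2 rows")
    merges = hierarchy.linkage(condensed, method=method)
    return Dendrogram(merges=merges, labels=list(labels), metric=metric, method=method)


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cluster labels from cutting the merge history at *k* groups.

    Labels are canonicalized to 1..k by first appearance in row order.
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise DomainError(f"cut_clusters: k must be in [1, {n}]")
    raw = hierarchy.fcluster(dendrogram.merges, t=k, criterion="maxclust")
    mapping: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, cluster in zip(dendrogram.labels, raw):
        mapping.setdefault(int(cluster), len(mapping) + 1)
        out[label] = mapping[int(cluster)]
    return out
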