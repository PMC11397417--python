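"""Group comparison, correlation matrices and the Mantel matrix-association test.

Duncan's new multiple range test is implemented from the studentized-range
distribution with the protection level ``alpha_p = 1 - (1 - alpha)**(p - 1)``
for means *p* ranks apart, rather than from printed critical-value tables,
so it generalizes to any error degrees of freedom.  Non-significant spans
are converted to a compact letter display by insert-and-absorb.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core_data import MeasurementTable, VariablePanel
from .errors import DesignError, DomainError, ValidationError

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    variable: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    mse: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    degenerate: bool = False  # zero within- and between-group variance


def one_way_anova(
    table: MeasurementTable, variable: str, group: str = "region"
) -> AnovaResult:
    """Classical fixed-effects one-way decomposition; p from the F distribution."""
    table.require_complete([variable], stage="anova")
    df = table.data
    groups: dict[str, np.ndarray] = {}
    for level in df[group].unique():
        vals = df.loc[df[group] == level, variable].to_numpy(dtype=float)
        groups[level] = vals
    if len(groups) < 2:
        raise DesignError("one_way_anova: need >= 2 groups")
    for level, vals in groups.items():
        if len(vals) < 2:
            raise DesignError(
                f"one_way_anova: group {level!r} has < 2 replicates"
            )
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(groups)
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0.0:
        if ms_between == 0.0:
            return AnovaResult(
                variable, float("nan"), df_between, df_within, float("nan"),
                0.0, {g: float(v.mean()) for g, v in groups.items()},
                {g: len(v) for g, v in groups.items()}, degenerate=True,
            )
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / mse
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        variable=variable,
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        mse=float(mse),
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_ns={g: len(v) for g, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# Duncan's new multiple range test + compact letter display
# ---------------------------------------------------------------------------


@dataclass
class LetterDisplay:
    variable: str
    alpha: float
    entries: list[tuple[str, float, str]]  # (group, mean, letters), means descending

    def letters(self) -> dict[str, str]:
        return {g: ltrs for g, _, ltrs in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["group", "mean", "letters"])


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, span: int, df: int) -> float:
    """Studentized-range critical value at Duncan's protection level.

    alpha_p = 1 - (1-alpha)**(span-1), i.e. the upper quantile is taken at
    cumulative probability (1-alpha)**(span-1).
    """
    q = stats.studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df)
    if not np.isfinite(q):
        raise DomainError(
            f"studentized-range quantile unavailable for span={span}, df={df}"
        )
    return float(q)


def duncan_significance(
    means: Sequence[float],
    ns: Sequence[int],
    mse: float,
    df_within: int,
    alpha: float = 0.05,
) -> np.ndarray:
    """Pairwise significance matrix for means sorted in DESCENDING order.

    Means p ranks apart differ iff their difference exceeds
    ``R_p = q(alpha_p, p, df) * sqrt(MSE / n_h)`` with ``n_h`` the harmonic
    mean of the two group sizes, subject to the step-down protection rule: a
    range contained in any non-significant range is itself non-significant.
    """
    means = np.asarray(means, dtype=float)
    k = means.size
    if np.any(np.diff(means) > 0):
        raise ValueError("means must be sorted descending")
    sig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        q = _duncan_q(alpha, span, df_within)
        for i in range(0, k - span + 1):
            j = i + span - 1
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            r_p = q * np.sqrt(mse / n_h)
            raw = (means[i] - means[j]) > r_p
            protected = True
            if i > 0 and not sig[i - 1, j]:
                protected = False
            if j < k - 1 and not sig[i, j + 1]:
                protected = False
            if span == k:
                protected = True
            sig[i, j] = sig[j, i] = raw and protected
    return sig


def _letters_from_significance(sig: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    Groups (indexed in descending-mean order) share a letter iff they are
    not significantly different; letters are assigned a..z (then aa, ab, ...)
    in order of first appearance from the top mean down.
    """
    k = sig.shape[0]
    sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for s in list(sets):
            if i in s and j in s:
                sets.remove(s)
                for dropped in (i, j):
                    ns = s - {dropped}
                    if ns and not any(ns <= other for other in sets):
                        sets.append(ns)
        sets = [s for s in sets if not any(s < other for other in sets)]
    # order letter sets by their smallest (highest-mean) member
    sets.sort(key=lambda s: (min(s), -len(s)))

    def letter(idx: int) -> str:
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        if idx < 26:
            return alphabet[idx]
        return alphabet[idx // 26 - 1] + alphabet[idx % 26]

    out = ["" for _ in range(k)]
    for s_idx, s in enumerate(sets):
        for member in sorted(s):
            out[member] += letter(s_idx)
    return out


def duncan_mrt(anova: AnovaResult, alpha: float = 0.05) -> LetterDisplay:
    """Duncan's new multiple range test on an ANOVA result."""
    if anova.degenerate:
        raise DomainError("duncan_mrt: degenerate ANOVA (no variance at all)")
    if len(anova.group_means) < 2:
        raise DesignError("duncan_mrt: need >= 2 groups")
    if anova.df_within < 1:
        raise DomainError("duncan_mrt: df_within < 1")
    order = sorted(
        anova.group_means, key=lambda g: (-anova.group_means[g], g)
    )
    means = [anova.group_means[g] for g in order]
    ns = [anova.group_ns[g] for g in order]
    sig = duncan_significance(means, ns, anova.mse, anova.df_within, alpha)
    letters = _letters_from_significance(sig)
    entries = [(g, m, ltr) for g, m, ltr in zip(order, means, letters)]
    return LetterDisplay(variable=anova.variable, alpha=alpha, entries=entries)


def compare_groups(
    table: MeasurementTable,
    variables: Sequence[str] | VariablePanel,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA + Duncan letters for each variable; one row per (variable, group)."""
    if isinstance(variables, VariablePanel):
        variables.check_against(table)
        variables = variables.members
    rows = []
    for var in variables:
        res = one_way_anova(table, var)
        display = duncan_mrt(res, alpha=alpha)
        for group, mean, letters in display.entries:
            rows.append(
                {
                    "variable": var,
                    "group": group,
                    "mean": mean,
                    "letters": letters,
                    "f_stat": res.f_stat,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pearson correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int


def pearson_matrix(
    table: MeasurementTable | pd.DataFrame,
    panel: VariablePanel | Sequence[str] | None = None,
) -> CorrelationResult:
    """Pairwise Pearson r with two-tailed p from the t transform.

    ``t = r * sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom; stars follow
    the 0.05 / 0.01 / 0.001 thresholds.
    """
    if isinstance(table, MeasurementTable):
        if panel is None:
            panel = table.variables
        data = table.values(panel)
    else:
        data = table if panel is None else table.loc[:, list(
            panel.members if isinstance(panel, VariablePanel) else panel
        )]
    variables = list(data.columns)
    n = len(data)
    if n < 3:
        raise DesignError("pearson_matrix: need >= 3 observations")
    if data.isna().any().any():
        bad = [v for v in variables if data[v].isna().any()]
        raise ValidationError(f"pearson_matrix: missing values in {bad}")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    zero_var = [v for v, s in zip(variables, sd) if s == 0]
    p_mat = np.zeros((len(variables), len(variables)))
    r_mat = np.eye(len(variables))
    for i, j in itertools.combinations(range(len(variables)), 2):
        if variables[i] in zero_var or variables[j] in zero_var:
            r_mat[i, j] = r_mat[j, i] = np.nan
            p_mat[i, j] = p_mat[j, i] = np.nan
            continue
        r = float(np.corrcoef(x[:, i], x[:, j])[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
        r_mat[i, j] = r_mat[j, i] = r
        p_mat[i, j] = p_mat[j, i] = p
    r_df = pd.DataFrame(r_mat, index=variables, columns=variables)
    p_df = pd.DataFrame(p_mat, index=variables, columns=variables)
    stars = p_df.map(lambda p: "" if np.isnan(p) else p_to_stars(p))
    for v in variables:
        stars.loc[v, v] = ""
    return CorrelationResult(variables=variables, r=r_df, p=p_df, stars=stars, n=n)


# ---------------------------------------------------------------------------
# Distance matrices and the Mantel test
# ---------------------------------------------------------------------------


def distance_matrix(
    table: MeasurementTable | pd.DataFrame,
    panel: VariablePanel | Sequence[str] | None = None,
    metric: str = "euclidean",
    standardize: bool = False,
) -> pd.DataFrame:
    """Pairwise distances between rows over the panel variables.

    ``euclidean`` optionally on z-scored (n-1) columns; ``bray_curtis`` is
    ``sum|x_i - x_j| / sum(x_i + x_j)`` and requires non-negative data.
    """
    if isinstance(table, MeasurementTable):
        if panel is None:
            panel = table.variables
        data = table.values(panel)
        index = table.data["sample_id"] if "sample_id" in table.data else data.index
    else:
        cols = (
            list(panel.members)
            if isinstance(panel, VariablePanel)
            else (list(panel) if panel is not None else list(table.columns))
        )
        data = table.loc[:, cols]
        index = data.index
    if data.isna().any().any():
        raise ValidationError("distance_matrix: missing values")
    x = data.to_numpy(dtype=float)
    if metric == "euclidean":
        if standardize:
            sd = x.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise DomainError("distance_matrix: zero-variance column")
            x = (x - x.mean(axis=0)) / sd
        d = squareform(pdist(x, metric="euclidean"))
    elif metric == "bray_curtis":
        if np.any(x < 0):
            raise DomainError("distance_matrix: bray_curtis requires non-negative values")
        d = squareform(pdist(x, metric="braycurtis"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    labels = list(index)
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class MantelResult:
    r_obs: float
    p_value: float
    n_permutations: int
    metric_a: str
    metric_b: str
    seed: int
    r_defined: bool = True


def _as_square(d) -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("mantel_test: matrices must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValidationError("mantel_test: matrices must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValidationError("mantel_test: matrices must have zero diagonal")
    return arr


def mantel_test(
    d_a,
    d_b,
    n_permutations: int = 999,
    seed: int | None = None,
    metric_a: str = "",
    metric_b: str = "",
) -> MantelResult:
    """One-tailed (positive) Mantel permutation test.

    ``r_obs`` is the Pearson correlation of the upper-triangle vectors; the
    null distribution jointly permutes rows and columns of ``d_b``;
    ``p = (1 + #(r_perm >= r_obs)) / (n_permutations + 1)``.
    """
    a = _as_square(d_a)
    b = _as_square(d_b)
    if a.shape != b.shape:
        raise ValidationError("mantel_test: size mismatch")
    n = a.shape[0]
    if n < 4:
        raise ValidationError("mantel_test: need matrices of size >= 4")
    if seed is None:
        raise ValidationError("mantel_test: seed is required")
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if va.std() == 0:
        return MantelResult(float("nan"), float("nan"), n_permutations,
                            metric_a, metric_b, seed, r_defined=False)

    za = (va - va.mean()) / va.std()

    def corr_with(mat: np.ndarray) -> float:
        vb = mat[iu]
        s = vb.std()
        if s == 0:
            return 0.0
        zb = (vb - vb.mean()) / s
        return float(np.mean(za * zb))

    r_obs = corr_with(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr_with(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return MantelResult(
        r_obs=r_obs,
        p_value=p,
        n_permutations=n_permutations,
        metric_a=metric_a,
        metric_b=metric_b,
        seed=seed,
    )
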