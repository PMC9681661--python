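"""Compositional statistics: cell-fraction tables, Bray-Curtis beta
diversity, Fisher linear discriminant projections, per-day Z-score
trajectories and cross-over detection, and condition log-ratios.

Bray-Curtis dissimilarity between nonnegative abundance vectors u, v is
BC(u, v) = 1 − 2·Σᵢ min(uᵢ, vᵢ) / (Σᵢ uᵢ + Σᵢ vᵢ), the ecology beta-diversity
index with cell types in place of species. It is computed on counts when
available and on fractions otherwise (with equal per-sample totals the two
coincide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

from .events import ConfigurationError

logger = logging.getLogger(__name__)

#: the eight lineage-level cell types used for composition analyses
CANONICAL_CELL_TYPES = (
    "B", "basophil", "CD4 T", "CD8 T", "eosinophil", "MP", "NK", "neutrophil",
)


def cell_fractions(
    annotations: pd.DataFrame,
    grouping: tuple[str, ...] = ("sample_id", "compartment"),
    cell_type_col: str = "cell_type",
    cell_types: tuple[str, ...] | None = None,
    denominator: str = "all immune cells in compartment",
) -> pd.DataFrame:
    """Counts and fractions of cell types per group.

    ``annotations`` has one row per cell with grouping columns and a cell-type
    label. Zero-count types appear with fraction 0. Groups with an empty
    denominator are dropped with a warning. The denominator declaration is
    carried in the output's ``denominator`` column.
    """
    if cell_type_col not in annotations.columns:
        raise ConfigurationError(f"annotations lack a {cell_type_col!r} column")
    types = tuple(cell_types) if cell_types is not None else tuple(
        sorted(annotations[cell_type_col].unique())
    )
    rows = []
    carry = [c for c in ("mouse", "day", "treatment") if c in annotations.columns]
    for key, g in annotations.groupby(list(grouping), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        g = g[g[cell_type_col].isin(types)]
        total = len(g)
        if total == 0:
            logger.warning("empty denominator for group %s: row dropped", key)
            continue
        counts = g[cell_type_col].value_counts()
        for t in types:
            n = int(counts.get(t, 0))
            row = dict(zip(grouping, key))
            for c in carry:
                row[c] = g[c].iloc[0]
            row.update(
                {"cell_type": t, "count": n, "fraction": n / total,
                 "total": total, "denominator": denominator}
            )
            rows.append(row)
    return pd.DataFrame(rows)


def fraction_matrix(
    fractions: pd.DataFrame,
    index: tuple[str, ...] = ("sample_id", "compartment"),
    values: str = "fraction",
) -> pd.DataFrame:
    """Pivot a tidy fraction table to rows = groups, columns = cell types."""
    wide = fractions.pivot_table(
        index=list(index), columns="cell_type", values=values, fill_value=0.0
    )
    wide.columns.name = None
    return wide


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity in [0, 1] between nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ConfigurationError("composition vectors differ in length")
    if (u < 0).any() or (v < 0).any():
        raise ConfigurationError("compositions must be nonnegative")
    if u.sum() == 0 and v.sum() == 0:
        raise ConfigurationError("both compositions are all-zero")
    return float(_scipy_braycurtis(u, v))


@dataclass
class DissimilarityResult:
    """Pairwise dissimilarities for two groups plus the group comparison."""

    values_a: np.ndarray
    values_b: np.ndarray
    mean_a: float
    mean_b: float
    fold_change: float
    t_statistic: float
    p_value: float


def pairwise_dissimilarity(
    wide: pd.DataFrame,
    group_col_values: pd.Series,
    pair: tuple[str, str],
    within: pd.Series | None = None,
) -> pd.DataFrame:
    """Bray-Curtis between two compartments/conditions.

    When ``within`` is given (e.g. mouse ids), samples are paired within each
    level of it (matched design); otherwise all cross-group pairs are used.
    """
    a_label, b_label = pair
    mask_a = group_col_values == a_label
    mask_b = group_col_values == b_label
    rows = []
    if within is not None:
        for key in pd.unique(within):
            ia = wide.index[mask_a & (within == key)]
            ib = wide.index[mask_b & (within == key)]
            for i in ia:
                for j in ib:
                    rows.append(
                        {"a": i, "b": j, "within": key,
                         "dissimilarity": bray_curtis(wide.loc[i], wide.loc[j])}
                    )
    else:
        for i in wide.index[mask_a]:
            for j in wide.index[mask_b]:
                rows.append(
                    {"a": i, "b": j, "within": None,
                     "dissimilarity": bray_curtis(wide.loc[i], wide.loc[j])}
                )
    return pd.DataFrame(rows)


def dissimilarity_compare(
    group_a: np.ndarray | pd.Series, group_b: np.ndarray | pd.Series
) -> DissimilarityResult:
    """Fold change of mean dissimilarities (B over A) and unpaired t test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each group needs >= 2 pairwise values")
    t, p = stats.ttest_ind(b, a)
    if np.isnan(t):  # identical constant groups
        t, p = 0.0, 1.0
    return DissimilarityResult(
        values_a=a, values_b=b, mean_a=float(a.mean()), mean_b=float(b.mean()),
        fold_change=float(b.mean() / a.mean()), t_statistic=float(t), p_value=float(p),
    )


@dataclass
class DiscriminantModel:
    """Fisher linear discriminant: coefficients, class means, projections."""

    classes: tuple[str, ...]
    features: tuple[str, ...]
    coefficients: np.ndarray  # features × axes
    class_means_projected: pd.DataFrame
    training_projections: pd.DataFrame
    grand_mean: np.ndarray

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients,
            index=self.features,
            columns=[f"LD{i + 1}" for i in range(self.coefficients.shape[1])],
        )


def lda_fit(
    fractions: pd.DataFrame, class_labels: pd.Series | np.ndarray, ridge: float = 1e-8
) -> DiscriminantModel:
    """Fit the Fisher discriminant of cell fractions on class labels.

    Solves the generalized eigenproblem of between-class versus pooled
    within-class scatter; the within-class scatter receives a ridge of
    ``ridge · trace(Sw)/p`` on its diagonal so near-singular scatter (few
    samples, many cell types) stays invertible. Axes ≤ classes − 1.
    """
    X = fractions.to_numpy(dtype=float)
    y = np.asarray(class_labels)
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ConfigurationError("need >= 2 classes")
    n, p = X.shape
    if n < len(classes) + 1:
        raise ConfigurationError("need at least classes + 1 samples")
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        if len(Xc) < 2:
            raise ConfigurationError(f"class {c!r} has fewer than 2 samples")
        mu = Xc.mean(axis=0)
        d = Xc - mu
        Sw += d.T @ d
        m = (mu - grand).reshape(-1, 1)
        Sb += len(Xc) * (m @ m.T)
    eps = ridge * np.trace(Sw) / p
    Sw_r = Sw + eps * np.eye(p)
    vals, vecs = linalg.eigh(Sb, Sw_r)
    order = np.argsort(vals)[::-1]
    n_axes = min(len(classes) - 1, p)
    W = vecs[:, order[:n_axes]]
    if not np.all(np.isfinite(W)):
        raise ConfigurationError("discriminant coefficients are not finite")
    proj = (X - grand) @ W
    axis_names = [f"LD{i + 1}" for i in range(n_axes)]
    training = pd.DataFrame(proj, index=fractions.index, columns=axis_names)
    training["class"] = y
    class_means = training.groupby("class")[axis_names].mean()
    return DiscriminantModel(
        classes=classes,
        features=tuple(fractions.columns),
        coefficients=W,
        class_means_projected=class_means,
        training_projections=training,
        grand_mean=grand,
    )


def lda_project(model: DiscriminantModel, new_fractions: pd.DataFrame) -> pd.DataFrame:
    """Project held-out samples (e.g. a perturbed arm) onto trained axes."""
    X = new_fractions[list(model.features)].to_numpy(dtype=float)
    proj = (X - model.grand_mean) @ model.coefficients
    return pd.DataFrame(
        proj,
        index=new_fractions.index,
        columns=[f"LD{i + 1}" for i in range(model.coefficients.shape[1])],
    )


def zscore_by_day(
    fractions: pd.DataFrame,
    compartment: str,
    cell_type: str,
    day_col: str = "day",
) -> pd.Series:
    """Per-day mean fraction standardized across days (sample sd, ddof=1)."""
    sel = fractions[
        (fractions["compartment"] == compartment)
        & (fractions["cell_type"] == cell_type)
    ]
    by_day = sel.groupby(day_col)["fraction"].mean().sort_index()
    if len(by_day) < 2:
        raise ConfigurationError("need >= 2 days with data")
    sd = by_day.std(ddof=1)
    if sd == 0:
        raise ConfigurationError("zero variance across days")
    return (by_day - by_day.mean()) / sd


def day_trend_series(
    fractions: pd.DataFrame,
    compartment: str,
    cell_type: str,
    day_col: str = "day",
) -> pd.Series:
    """Per-day values of the least-squares linear day trend of one cell type.

    Pools all samples of the compartment into one OLS fit of fraction on day
    and evaluates it on the observed day grid — the linear-intersection
    estimate of where two types' abundances cross. Preferred over raw per-day
    means when few mice per day make those means noisy.
    """
    sel = fractions[
        (fractions["compartment"] == compartment)
        & (fractions["cell_type"] == cell_type)
    ]
    if sel[day_col].nunique() < 2:
        raise ConfigurationError("need >= 2 days with data")
    d = sel[day_col].to_numpy(dtype=float)
    f = sel["fraction"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(d, f, 1)
    days = np.unique(d)
    return pd.Series(intercept + slope * days, index=days, name=cell_type)


@dataclass
class Crossing:
    start: float
    end: float
    point: bool = False

    def contains(self, day: float) -> bool:
        return self.start <= day <= self.end


def detect_crossover(
    z_a: pd.Series | np.ndarray, z_b: pd.Series | np.ndarray,
    days: np.ndarray | None = None,
) -> list[Crossing]:
    """Day intervals where the sign of z_a − z_b changes.

    Exact zeros are reported as point crossings at that day. No crossing
    returns an empty list.
    """
    if days is None:
        if not isinstance(z_a, pd.Series):
            raise ConfigurationError("days required when z-series are not indexed")
        days = z_a.index.to_numpy(dtype=float)
    days = np.asarray(days, dtype=float)
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if a.shape != b.shape or a.shape != days.shape:
        raise ConfigurationError("z-series must share one day grid")
    diff = a - b
    out: list[Crossing] = []
    for i, d in enumerate(days):
        if diff[i] == 0:
            out.append(Crossing(d, d, point=True))
    for i in range(len(days) - 1):
        if diff[i] * diff[i + 1] < 0:
            out.append(Crossing(days[i], days[i + 1]))
    return out


@dataclass
class LogRatioRow:
    cell_type: str
    log2_ratio: float
    mean_treated: float
    mean_control: float
    p_value: float
    significant: bool


def log2_condition_ratio(
    fractions_treated: pd.DataFrame,
    fractions_control: pd.DataFrame,
    pseudo_fraction: float = 1e-4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """log2(mean treated fraction / mean control fraction) per cell type,
    with an uncorrected two-sample t-test flag at ``alpha``.

    Zero control means are replaced by ``pseudo_fraction`` (logged).
    Input frames are tidy fraction tables sharing cell types; ratios are
    computed within whatever grouping the caller pre-filtered (typically one
    compartment).
    """
    rows = []
    types = sorted(set(fractions_treated["cell_type"]) & set(fractions_control["cell_type"]))
    if not types:
        raise ConfigurationError("conditions share no cell types")
    for t in types:
        a = fractions_treated.loc[fractions_treated["cell_type"] == t, "fraction"].to_numpy()
        b = fractions_control.loc[fractions_control["cell_type"] == t, "fraction"].to_numpy()
        mean_t, mean_c = float(a.mean()), float(b.mean())
        denom = mean_c
        if denom == 0:
            logger.warning("zero control mean for %s: pseudo-fraction %g applied",
                           t, pseudo_fraction)
            denom = pseudo_fraction
        num = mean_t if mean_t > 0 else pseudo_fraction
        if len(a) >= 2 and len(b) >= 2 and (a.std() > 0 or b.std() > 0):
            _, p = stats.ttest_ind(a, b)
            p = float(p)
        else:
            p = 1.0
        rows.append(
            LogRatioRow(t, float(np.log2(num / denom)), mean_t, mean_c, p, p < alpha)
        )
    return pd.DataFrame([r.__dict__ for r in rows])
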