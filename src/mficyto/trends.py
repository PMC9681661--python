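"""Temporal inference across gestation.

Covers: ordinary least-squares prediction of embryonic day from cell-type
fractions (training and cross-validated R², early/late gestational windows);
trend regressions with heteroskedasticity-robust (HC0 sandwich) standard
errors — algebraically the independence-working-correlation GEE with
singleton clusters — including quadratic day terms and compartment contrasts
against peripheral blood; per-marker differential expression with Bonferroni
correction; variance-homogeneity-dispatched ANOVA (classic + Tukey HSD vs.
Welch + Games-Howell); and the Taylor-series ratio test
V(X/Y) = E(X²)·E(1/Y²) − [E(X)·E(1/Y)]², applied to the sampling
distribution of the two arm means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .events import ConfigurationError

logger = logging.getLogger(__name__)

EARLY_WINDOW = (10.5, 13.5)
LATE_WINDOW = (14.5, 18.5)


# ---------------------------------------------------------------------------
# embryonic-day regression


@dataclass
class DayRegressionResult:
    window: str
    coefficients: pd.Series
    intercept: float
    training_r2: float
    cv_r2: np.ndarray
    n_samples: int

    @property
    def cv_r2_mean(self) -> float:
        return float(np.mean(self.cv_r2))


def _window_mask(days: np.ndarray, window: str) -> np.ndarray:
    if window == "all":
        return np.ones(len(days), dtype=bool)
    if window == "early":
        lo, hi = EARLY_WINDOW
    elif window == "late":
        lo, hi = LATE_WINDOW
    else:
        raise ConfigurationError(f"unknown window {window!r}")
    return (days >= lo) & (days <= hi)


def fit_day_regression(
    fractions: pd.DataFrame,
    days: pd.Series | np.ndarray,
    window: str = "all",
    k_folds: int = 5,
    seed: int = 0,
    ridge_alpha: float | None = None,
) -> DayRegressionResult:
    """OLS of embryonic day on cell-type fractions within a gestational window.

    Returns the training R² and per-fold cross-validated R² (k-fold, seeded).
    Designs with more features than samples are refused unless a ridge
    penalty is enabled.
    """
    from sklearn.linear_model import LinearRegression, Ridge
    from sklearn.metrics import r2_score
    from sklearn.model_selection import KFold

    X_all = fractions.to_numpy(dtype=float)
    y_all = np.asarray(days, dtype=float)
    mask = _window_mask(y_all, window)
    X, y = X_all[mask], y_all[mask]
    if len(y) < 3:
        raise ConfigurationError(f"window {window!r} has {len(y)} samples (< 3)")
    if X.shape[1] > X.shape[0] and ridge_alpha is None:
        raise ConfigurationError(
            "more features than samples; enable ridge_alpha to fit anyway"
        )

    def make_model():
        return Ridge(alpha=ridge_alpha) if ridge_alpha else LinearRegression()

    model = make_model().fit(X, y)
    training_r2 = float(model.score(X, y))
    k = min(k_folds, len(y))
    cv_scores = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        m = make_model().fit(X[train_idx], y[train_idx])
        cv_scores.append(r2_score(y[test_idx], m.predict(X[test_idx])))
    return DayRegressionResult(
        window=window,
        coefficients=pd.Series(model.coef_, index=fractions.columns),
        intercept=float(model.intercept_),
        training_r2=training_r2,
        cv_r2=np.asarray(cv_scores),
        n_samples=len(y),
    )


@dataclass
class WindowComparison:
    ratio: float
    t_statistic: float
    p_value: float
    mode: str


def compare_windows(
    result_a: DayRegressionResult,
    result_b: DayRegressionResult,
    mode: str = "cv_folds",
) -> WindowComparison:
    """Ratio of mean R² (A over B) with a two-sample t test across folds."""
    if mode != "cv_folds":
        raise ConfigurationError("only the cv_folds comparison mode is implemented")
    a, b = result_a.cv_r2, result_b.cv_r2
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("need >= 2 folds per window")
    t, p = stats.ttest_ind(a, b)
    if np.isnan(t):
        t, p = 0.0, 1.0
    return WindowComparison(
        ratio=float(np.mean(a) / np.mean(b)), t_statistic=float(t),
        p_value=float(p), mode=mode,
    )


# ---------------------------------------------------------------------------
# robust trend regression


@dataclass
class TrendFitResult:
    """Tidy coefficient table plus the robust covariance and diagnostics."""

    table: pd.DataFrame  # term, estimate, robust_se, z, p
    cov: pd.DataFrame
    residuals: np.ndarray
    fitted: np.ndarray
    formula: str
    cov_type: str

    def coef(self, term: str) -> pd.Series:
        row = self.table.set_index("term").loc[term]
        return row


def build_trend_design(
    day: np.ndarray,
    compartment: np.ndarray | None = None,
    quadratic: bool = False,
    interactions: bool = False,
    reference: str = "PB",
    center_day: bool = True,
) -> pd.DataFrame:
    """Design matrix: intercept, (centered) day, optional day², compartment
    dummies against the reference level, optional day × compartment terms.

    Day is mean-centered before squaring to reduce collinearity.
    """
    day = np.asarray(day, dtype=float)
    d = day - day.mean() if center_day else day
    cols = {"Intercept": np.ones(len(d)), "day": d}
    if quadratic:
        cols["day2"] = d * d
    levels: list[str] = []
    if compartment is not None:
        compartment = np.asarray(compartment, dtype=object)
        levels = [c for c in pd.unique(compartment) if c != reference]
        if reference not in set(compartment):
            raise ConfigurationError(f"reference level {reference!r} absent")
        for c in sorted(levels):
            cols[f"compartment[{c}]"] = (compartment == c).astype(float)
        if interactions:
            for c in sorted(levels):
                cols[f"day:compartment[{c}]"] = d * (compartment == c)
    return pd.DataFrame(cols)


def robust_trend_fit(
    response: np.ndarray | pd.Series,
    day: np.ndarray | pd.Series,
    compartment: np.ndarray | pd.Series | None = None,
    quadratic: bool = False,
    interactions: bool = False,
    cov_type: str = "HC0",
    reference: str = "PB",
) -> TrendFitResult:
    """OLS point estimates with the heteroskedasticity-robust sandwich
    covariance (X'X)⁻¹ X' diag(e²) X (X'X)⁻¹ and Wald z p-values.

    HC0 is the default, matching a GEE with independence working correlation
    and cluster size 1; HC1 adds the n/(n−p) small-sample factor.
    """
    y = np.asarray(response, dtype=float)
    X = build_trend_design(
        np.asarray(day, dtype=float),
        None if compartment is None else np.asarray(compartment, dtype=object),
        quadratic=quadratic,
        interactions=interactions,
        reference=reference,
    )
    n, p = X.shape
    if n < p + 2:
        raise ConfigurationError(f"need at least {p + 2} observations for {p} parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ConfigurationError("rank-deficient design")
    fit = sm.OLS(y, X).fit(cov_type=cov_type, use_t=False)
    table = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "robust_se": fit.bse.to_numpy(),
            "z": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    parts = ["day"] + (["day2"] if quadratic else [])
    if compartment is not None:
        parts.append("compartment")
        if interactions:
            parts.append("day:compartment")
    return TrendFitResult(
        table=table,
        cov=pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        formula="response ~ " + " + ".join(parts),
        cov_type=cov_type,
    )


def sandwich_covariance(X: np.ndarray, residuals: np.ndarray, hc1: bool = False) -> np.ndarray:
    """Plain-matrix HC0/HC1 sandwich (X'X)⁻¹ X' diag(e²) X (X'X)⁻¹."""
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (e ** 2)[:, None])
    cov = bread @ meat @ bread
    if hc1:
        n, p = X.shape
        cov = cov * n / (n - p)
    return cov


# ---------------------------------------------------------------------------
# differential marker expression


def differential_expression(
    medians_a: pd.DataFrame,
    medians_b: pd.DataFrame,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Volcano table of per-marker t tests on per-mouse median intensities.

    Rows of each input are mice, columns are markers. Markers with fewer than
    two mice per group are skipped with a warning. P-values are adjusted by
    the requested method (Bonferroni by default); the significant set is
    adjusted p ≤ ``alpha``.
    """
    from statsmodels.stats.multitest import multipletests

    markers = [m for m in medians_a.columns if m in medians_b.columns]
    rows = []
    for m in markers:
        a = medians_a[m].dropna().to_numpy()
        b = medians_b[m].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            logger.warning("marker %s skipped: fewer than 2 mice per group", m)
            continue
        t, p = stats.ttest_ind(a, b)
        if np.isnan(t):
            t, p = 0.0, 1.0
        rows.append(
            {"marker": m, "mean_diff": float(a.mean() - b.mean()),
             "t": float(t), "p": float(p)}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    _, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method=correction)
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] <= alpha
    return out


# ---------------------------------------------------------------------------
# ANOVA dispatch


@dataclass
class AnovaResult:
    method: str  # "classic" | "welch"
    levene_p: float
    f_statistic: float
    p_value: float
    omnibus: pd.DataFrame
    posthoc: pd.DataFrame


def anova_dispatch(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Variance-homogeneity-dispatched one-way ANOVA with matched post hocs.

    Levene's test decides the branch: equal variances → classic ANOVA with
    Tukey HSD; unequal (or any zero-variance group) → Welch ANOVA with
    Games-Howell.
    """
    import pingouin as pg

    if len(groups) < 3:
        raise ConfigurationError("need >= 3 groups")
    for name, v in groups.items():
        if len(np.asarray(v)) < 2:
            raise ConfigurationError(f"group {name!r} has n < 2")
    long = pd.concat(
        [pd.DataFrame({"value": np.asarray(v, dtype=float), "group": k})
         for k, v in groups.items()],
        ignore_index=True,
    )
    zero_var = any(np.asarray(v, dtype=float).std() == 0 for v in groups.values())
    hom = pg.homoscedasticity(long, dv="value", group="group", method="levene")
    levene_p = float(hom["pval"].iloc[0]) if np.isfinite(hom["pval"].iloc[0]) else 0.0
    equal_var = bool(hom["equal_var"].iloc[0]) and not zero_var
    if equal_var:
        omnibus = pg.anova(long, dv="value", between="group")
        posthoc = pg.pairwise_tukey(long, dv="value", between="group")
        method = "classic"
    else:
        omnibus = pg.welch_anova(long, dv="value", between="group")
        posthoc = pg.pairwise_gameshowell(long, dv="value", between="group")
        method = "welch"
    p_col = "p_unc" if "p_unc" in omnibus.columns else "p-unc"
    f = float(omnibus["F"].iloc[0])
    p = float(omnibus[p_col].iloc[0])
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    return AnovaResult(
        method=method, levene_p=levene_p, f_statistic=f, p_value=p,
        omnibus=omnibus, posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# Taylor-series ratio test


@dataclass
class RatioTestResult:
    ratio: float
    variance: float
    sd: float
    n: int
    pseudo_count_applied: bool = False


def ratio_test(
    counts_a: np.ndarray | pd.Series,
    counts_b: np.ndarray | pd.Series,
    pseudo_count: float = 0.5,
) -> RatioTestResult:
    """Ratio of arm means with its Taylor-series variance.

    The ratio X̄/Ȳ compares treated (X) with control (Y) per-mouse counts.
    Its variance applies V(X/Y) = E(X²)·E(1/Y²) − [E(X)·E(1/Y)]² to the
    sampling distribution of the two means, expanding the inverse moments of
    Ȳ to second order — the delta-method variance for a ratio of independent
    means. Zeros in the control arm trigger the declared pseudo-count policy
    (both arms shifted by ``pseudo_count``, logged). Accurate for control
    coefficients of variation below ~0.2.
    """
    x = np.asarray(counts_a, dtype=float)
    y = np.asarray(counts_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("both arms need n >= 2")
    pseudo = False
    if (y == 0).any():
        logger.warning("control arm contains zeros: pseudo-count %g applied", pseudo_count)
        x = x + pseudo_count
        y = y + pseudo_count
        pseudo = True
    if y.mean() <= 0:
        raise ConfigurationError("control mean must be positive")
    xb, yb = x.mean(), y.mean()
    vx = x.var(ddof=1) / len(x)  # Var(X̄)
    vy = y.var(ddof=1) / len(y)  # Var(Ȳ)
    e_x2 = xb ** 2 + vx
    e_inv_y = (1.0 / yb) * (1.0 + vy / yb ** 2)
    e_inv_y2 = (1.0 / yb ** 2) * (1.0 + 3.0 * vy / yb ** 2)
    variance = max(0.0, e_x2 * e_inv_y2 - (xb * e_inv_y) ** 2)
    return RatioTestResult(
        ratio=float(xb / yb), variance=float(variance), sd=float(np.sqrt(variance)),
        n=min(len(x), len(y)), pseudo_count_applied=pseudo,
    )


def compare_ratios(r1: RatioTestResult, r2: RatioTestResult) -> tuple[float, float]:
    """Two-sample t test from descriptive statistics on two ratio estimates
    (e.g. the E12.5 vs E14.5 treated/control count ratios)."""
    t, p = stats.ttest_ind_from_stats(
        mean1=r1.ratio, std1=r1.sd, nobs1=r1.n,
        mean2=r2.ratio, std2=r2.sd, nobs2=r2.n,
    )
    return float(t), float(p)
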