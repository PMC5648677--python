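"""Evaluating soil-map attributes against field-measured cation data.

Covers the map-evaluation statistics: per-class cation summaries (how wide
the within-class ranges are), one-way ANOVA with Tukey–Kramer pairwise
contrasts between dominant classes, the cation–CEC Pearson correlation, and
ordinary-least-squares models predicting log cation concentration from
class-probability layers (optionally plus CEC) with forward–backward
stepwise selection by AIC.

Cation concentrations are log-transformed with the natural log throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ClassSummary",
    "AnovaTukeyResult",
    "RegressionFit",
    "GradientVector",
    "class_cation_summary",
    "anova_tukey",
    "pearson_corr",
    "gaussian_aic",
    "stepwise_aic",
    "fit_cation_model",
    "predict_cation",
]

#: adjusted-p threshold used to flag significant class contrasts
TUKEY_ALPHA = 0.001


@dataclass(frozen=True)
class ClassSummary:
    """Cation summary of one dominant soil class.

    ``orders_of_magnitude`` is log10(max/min) of the measured
    concentrations; classes spanning >= 2 are flagged as thematically
    heterogeneous (field values differ a hundredfold within one map class).
    """

    dominant_class: str
    n: int
    min: float
    max: float
    mean: float
    orders_of_magnitude: float
    flagged: bool


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA on log cation by class, plus all pairwise contrasts."""

    f_statistic: float
    p_value: float
    df: tuple[int, int]
    groups: list[str]
    tukey_p: pd.DataFrame  # symmetric matrix of Tukey-Kramer adjusted p
    dropped: list[str] = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.tukey_p < TUKEY_ALPHA


@dataclass
class RegressionFit:
    """A stepwise-selected OLS model of log cation concentration.

    ``coefficients`` maps predictor name to slope; ``intercept`` is
    separate.  ``aic`` follows the Gaussian convention
    ``n ln(RSS/n) + 2 (p + 2)`` with p selected predictors (intercept and
    error variance both counted), constant across the package so model
    comparisons are internally consistent.
    """

    response: str
    candidates: list[str]
    selected: list[str]
    intercept: float
    coefficients: dict[str, float]
    aic: float
    adj_r2: float
    p_value: float
    n: int
    n_dropped: int = 0


@dataclass
class GradientVector:
    """Per-plot values of one edaphic gradient.

    ``gradient_id`` identifies the axis (``measured_log_cation``,
    ``predicted_log_cation(<model>)`` or ``cec``); values are indexed by
    plot id.
    """

    values: pd.Series
    gradient_id: str
    provenance: str = ""


def class_cation_summary(
    classes: pd.Series | Sequence[str], cation: pd.Series | Sequence[float]
) -> pd.DataFrame:
    """Summarize measured cation concentration per dominant soil class.

    Returns one row per class, ordered by mean concentration, with the
    within-class range expressed in orders of magnitude and a flag for
    classes spanning two or more.
    """
    df = pd.DataFrame({"dominant_class": np.asarray(classes, dtype=object),
                       "cation": np.asarray(cation, dtype=float)}).dropna()
    if df.empty:
        raise ValueError("no classified plots with cation values")
    rows = []
    for cls, grp in df.groupby("dominant_class", sort=False):
        v = grp["cation"]
        oom = float(np.log10(v.max() / v.min()))
        rows.append(
            ClassSummary(str(cls), len(v), float(v.min()), float(v.max()),
                         float(v.mean()), oom, oom >= 2.0)
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).sort_values("mean", ignore_index=True)
    return out


def anova_tukey(
    log_values: Sequence[float] | pd.Series,
    classes: Sequence[str] | pd.Series,
    min_group_size: int = 2,
) -> AnovaTukeyResult:
    """One-way ANOVA on log cation by dominant class, with Tukey contrasts.

    Groups smaller than ``min_group_size`` are dropped with a warning.  The
    pairwise contrasts use the Tukey–Kramer studentized-range procedure,
    which remains valid for unequal group sizes and reduces to classical
    Tukey HSD on balanced designs.
    """
    df = pd.DataFrame({"v": np.asarray(log_values, dtype=float),
                       "g": np.asarray(classes, dtype=object)}).dropna()
    sizes = df.groupby("g").size()
    dropped = [str(g) for g in sizes[sizes < min_group_size].index]
    if dropped:
        warnings.warn(f"dropping groups with < {min_group_size} samples: {dropped}")
    keep = sizes[sizes >= min_group_size].index
    if len(keep) < 2:
        raise ValueError("need at least 2 groups with enough samples")
    groups = [df.loc[df["g"] == g, "v"].to_numpy() for g in keep]
    f_stat, p = stats.f_oneway(*groups)
    n_total = sum(len(g) for g in groups)
    hsd = stats.tukey_hsd(*groups)
    labels = [str(g) for g in keep]
    pmat = pd.DataFrame(hsd.pvalue, index=labels, columns=labels)
    np.fill_diagonal(pmat.values, np.nan)
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        df=(len(groups) - 1, n_total - len(groups)),
        groups=labels,
        tukey_p=pmat,
        dropped=dropped,
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value.

    Pairs with a missing member are dropped; constant vectors are an error.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float)}).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete pairs")
    if df["x"].nunique() == 1 or df["y"].nunique() == 1:
        raise ValueError("constant input vector")
    r, p = stats.pearsonr(df["x"], df["y"])
    return float(r), float(p)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def gaussian_aic(y: np.ndarray, X: np.ndarray) -> float:
    """AIC of a Gaussian OLS fit: ``n ln(RSS/n) + 2 (k + 1)``.

    ``k`` is the number of columns of the design matrix (intercept
    included); the +1 counts the error variance.  Additive constants are
    dropped, so only differences between models on the same response are
    meaningful.
    """
    n = len(y)
    # floor RSS at the square of the numerical noise an exact least-squares
    # fit leaves, so exact fits of different sizes compare only by penalty
    floor = n * (np.finfo(float).eps * max(1.0, float(np.linalg.norm(y)))) ** 2
    rss = max(_rss(y, X), floor)
    return n * float(np.log(rss / n)) + 2.0 * (X.shape[1] + 1)


def stepwise_aic(
    y: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    start: str = "empty",
) -> list[str]:
    """Forward–backward stepwise selection minimizing Gaussian AIC.

    Starting from the intercept-only model (``start='empty'``) or the full
    model (``start='full'``), each step evaluates every single-term addition
    and deletion and applies the move with the lowest AIC, stopping when no
    move improves on the current model.  Ties resolve to the earliest move
    in input-column order, so the procedure is deterministic.
    """
    if start not in ("empty", "full"):
        raise ValueError("start must be 'empty' or 'full'")
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    names = list(candidates.columns)
    cols = {c: candidates[c].to_numpy(float) for c in names}
    ones = np.ones(n)

    def design(sel: list[str]) -> np.ndarray:
        return np.column_stack([ones] + [cols[c] for c in sel])

    selected = list(names) if start == "full" else []
    current_aic = gaussian_aic(yv, design(selected))
    while True:
        best_aic, best_move = current_aic, None
        for c in names:  # additions, input order
            if c in selected:
                continue
            a = gaussian_aic(yv, design(selected + [c]))
            if a < best_aic - 1e-10:
                best_aic, best_move = a, ("add", c)
        for c in selected:  # deletions
            a = gaussian_aic(yv, design([s for s in selected if s != c]))
            if a < best_aic - 1e-10:
                best_aic, best_move = a, ("drop", c)
        if best_move is None:
            return selected
        op, c = best_move
        if op == "add":
            selected.append(c)
        else:
            selected.remove(c)
        current_aic = best_aic


def fit_cation_model(
    data: pd.DataFrame,
    predictors: Sequence[str],
    include_cec: bool = False,
    response: str = "cation_cmolkg",
    start: str = "empty",
) -> RegressionFit:
    """Fit a stepwise-selected OLS model of log cation concentration.

    ``data`` holds the response (cmol(+)/kg, log-transformed internally)
    and one column per candidate predictor — typically the per-class
    occurrence probabilities extracted from a soil-map stack, plus ``cec``
    when ``include_cec`` is set.  Rows with missing predictors or a missing
    or non-positive response are excluded and counted.
    """
    cand = list(predictors) + (["cec"] if include_cec and "cec" not in predictors else [])
    missing_cols = [c for c in cand + [response] if c not in data.columns]
    if missing_cols:
        raise KeyError(f"columns absent from data: {missing_cols}")
    sub = data[[response] + cand].apply(pd.to_numeric)
    ok = sub.notna().all(axis=1) & (sub[response] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} plots with missing data or non-positive cation")
    sub = sub[ok]
    n = len(sub)
    if n <= len(cand) + 1:
        raise ValueError(f"n={n} too small for {len(cand)} candidate predictors")
    logy = np.log(sub[response].to_numpy())
    selected = stepwise_aic(logy, sub[cand], start=start)

    X = sm.add_constant(sub[selected].to_numpy(), has_constant="add")
    res = sm.OLS(logy, X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design after selection")
    coefs = dict(zip(selected, [float(b) for b in res.params[1:]]))
    return RegressionFit(
        response="log_" + response,
        candidates=cand,
        selected=selected,
        intercept=float(res.params[0]),
        coefficients=coefs,
        aic=gaussian_aic(logy, X),
        adj_r2=float(res.rsquared_adj) if selected else 0.0,
        p_value=float(res.f_pvalue) if selected else float("nan"),
        n=n,
        n_dropped=n_dropped,
    )


def predict_cation(
    fit: RegressionFit,
    new_data: pd.DataFrame,
    gradient_id: str | None = None,
) -> GradientVector:
    """Predicted log cation concentration for new plots.

    Applies the fitted linear predictor on the log scale.  Rows missing any
    selected predictor yield a missing prediction, with a warning.
    """
    missing_cols = [c for c in fit.selected if c not in new_data.columns]
    if missing_cols:
        raise KeyError(f"selected predictors absent from new data: {missing_cols}")
    pred = np.full(len(new_data), fit.intercept, dtype=float)
    for c in fit.selected:
        pred = pred + fit.coefficients[c] * new_data[c].to_numpy(float)
    n_missing = int(np.isnan(pred).sum())
    if n_missing:
        warnings.warn(f"{n_missing} plots lack selected predictors; predictions missing")
    gid = gradient_id or f"predicted_log_cation({'+'.join(fit.selected) or 'intercept'})"
    return GradientVector(
        values=pd.Series(pred, index=new_data.index, name=gid),
        gradient_id=gid,
        provenance=f"OLS on {fit.selected}, n={fit.n}",
    )
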