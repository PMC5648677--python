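"""Weighted-averaging niche statistics along edaphic gradients.

A taxon's *optimum* is the abundance-weighted average of the gradient value
over the plots where it occurs; its *tolerance* is the abundance-weighted
root-mean-squared deviation around that optimum.  Optima rankings along two
gradients are compared with Kendall's tau-b (tie-corrected), and optimum ±
tolerance intervals from several datasets can be merged into a combined
envelope per taxon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GradientVector

__all__ = [
    "NicheEstimate",
    "ComparisonResult",
    "CombinedEnvelope",
    "wa_optimum",
    "wa_tolerance",
    "niche_table",
    "rank_correlation",
    "combine_envelopes",
]


@dataclass(frozen=True)
class NicheEstimate:
    """Optimum and tolerance of one taxon along one gradient."""

    taxon: str
    gradient_id: str
    optimum: float
    tolerance: float
    n_occurrences: int
    total_abundance: float


@dataclass(frozen=True)
class ComparisonResult:
    """Kendall rank comparison of taxon optima between two gradients."""

    gradient_a: str
    gradient_b: str
    tau: float
    p_value: float
    n_taxa: int
    n_dropped: int = 0


@dataclass(frozen=True)
class CombinedEnvelope:
    """Cross-dataset tolerance envelope of one taxon.

    The interval is [min over datasets of (u - t), max over datasets of
    (u + t)]; the per-dataset optima are retained because no principled
    combined optimum exists.
    """

    taxon: str
    optima: dict[str, float]
    lower: float
    upper: float


def _occupied(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("abundance and gradient vectors differ in length")
    occ = y > 0
    if not occ.any():
        raise ValueError("taxon absent from all plots; optimum undefined")
    if np.isnan(x[occ]).any():
        raise ValueError("gradient undefined at an occupied plot")
    return y[occ], x[occ]


def wa_optimum(abundances: Sequence[float], gradient: Sequence[float]) -> float:
    """Abundance-weighted average of the gradient over occupied plots."""
    y, x = _occupied(np.asarray(abundances), np.asarray(gradient))
    return float(np.sum(y * x) / np.sum(y))


def wa_tolerance(
    abundances: Sequence[float], gradient: Sequence[float], optimum: float | None = None
) -> float:
    """Abundance-weighted RMSE of the gradient around the optimum."""
    y, x = _occupied(np.asarray(abundances), np.asarray(gradient))
    u = wa_optimum(y, x) if optimum is None else optimum
    return float(np.sqrt(np.sum(y * (x - u) ** 2) / np.sum(y)))


def niche_table(
    abundances: pd.DataFrame,
    gradients: Sequence[GradientVector],
    reference: str | None = None,
) -> pd.DataFrame:
    """Optima and tolerances of every taxon along every gradient.

    ``abundances`` is a plots x taxa count matrix indexed by plot id; each
    gradient supplies per-plot values on the same index.  Plots where a
    gradient is missing are dropped for that gradient only.  Taxa are
    sorted by their optimum along the reference gradient (default: the
    first); taxa with no defined estimate along a gradient appear with
    missing optimum/tolerance.
    """
    rows = []
    for grad in gradients:
        x = grad.values.reindex(abundances.index)
        if x.isna().all():
            raise ValueError(f"gradient {grad.gradient_id!r} shares no plots with the abundances")
        for taxon in abundances.columns:
            y = abundances[taxon].to_numpy(float)
            usable = np.isfinite(x.to_numpy())
            yy, xx = y[usable], x.to_numpy()[usable]
            if (yy > 0).sum() == 0:
                rows.append((taxon, grad.gradient_id, np.nan, np.nan, 0, 0.0))
                continue
            u = wa_optimum(yy, xx)
            t = wa_tolerance(yy, xx, u)
            rows.append((taxon, grad.gradient_id, u, t, int((yy > 0).sum()), float(yy.sum())))
    df = pd.DataFrame(
        rows,
        columns=["taxon", "gradient_id", "optimum", "tolerance", "n_occurrences", "total_abundance"],
    )
    ref = reference or gradients[0].gradient_id
    order = (
        df[df["gradient_id"] == ref].set_index("taxon")["optimum"].sort_values().index
    )
    rank = {t: i for i, t in enumerate(order)}
    df["__rank"] = df["taxon"].map(lambda t: rank.get(t, len(rank)))
    df = df.sort_values(["gradient_id", "__rank"], ignore_index=True).drop(columns="__rank")
    return df


def rank_correlation(
    optima_a: Mapping[str, float] | pd.Series,
    optima_b: Mapping[str, float] | pd.Series,
    gradient_a: str = "A",
    gradient_b: str = "B",
) -> ComparisonResult:
    """Kendall's tau-b between two sets of taxon optima, matched by name.

    Taxa missing either estimate are dropped (and counted); at least three
    shared taxa are required.  The tie-corrected tau-b variant is used
    because model-predicted gradients can assign identical optima.
    """
    a = pd.Series(optima_a, dtype=float)
    b = pd.Series(optima_b, dtype=float)
    joined = pd.concat([a, b], axis=1, keys=["a", "b"])
    n_dropped = int(joined.isna().any(axis=1).sum())
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 taxa with estimates along both gradients")
    tau, p = stats.kendalltau(joined["a"], joined["b"], variant="b")
    return ComparisonResult(gradient_a, gradient_b, float(tau), float(p), len(joined), n_dropped)


def combine_envelopes(
    estimates_by_dataset: Mapping[str, pd.DataFrame],
) -> list[CombinedEnvelope]:
    """Merge per-dataset optimum ± tolerance intervals per taxon.

    Each dataset contributes the interval [u - t, u + t]; the combined
    envelope spans the union of the contributing intervals.  Taxa absent
    from every dataset are omitted.
    """
    taxa: dict[str, dict[str, tuple[float, float]]] = {}
    for ds, df in estimates_by_dataset.items():
        sub = df.dropna(subset=["optimum"])
        for row in sub.itertuples(index=False):
            taxa.setdefault(row.taxon, {})[ds] = (float(row.optimum), float(row.tolerance))
    out = []
    for taxon, per_ds in taxa.items():
        lows = [u - t for u, t in per_ds.values()]
        highs = [u + t for u, t in per_ds.values()]
        out.append(
            CombinedEnvelope(
                taxon=taxon,
                optima={ds: u for ds, (u, _) in per_ds.items()},
                lower=float(min(lows)),
                upper=float(max(highs)),
            )
        )
    return out
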