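"""Assigning soil-map attributes to field plots.

Plots are treated as point locations in the map CRS.  Class lookup is
point-in-polygon against the polygon layer (first covering polygon in layer
order wins on shared boundaries); raster lookup is nearest-cell, never
interpolated, because class probabilities and CEC are areal attributes.
Plots without map coverage come back missing and are counted in a warning —
extraction never invents values.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .core import GridMismatchError, PlotRecord, PolygonLayer, SoilMapStack

logger = logging.getLogger(__name__)


class UnmappedClassError(KeyError):
    """A detailed soil-class code has no entry in the aggregation table."""

    def __init__(self, codes: Sequence[str]):
        self.codes = sorted(set(codes))
        super().__init__(f"unmapped soil-class codes: {', '.join(self.codes)}")


@dataclass(frozen=True)
class ClassAggregationTable:
    """Detailed soil-class code -> WRB-FAO dominant class (e.g. ACh -> Acrisols)."""

    mapping: Mapping[str, str]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassAggregationTable":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls({r["detailed_code"]: r["dominant_class"] for r in rows})

    @classmethod
    def default(cls) -> "ClassAggregationTable":
        """The bundled aggregation covering the common Amazonian classes."""
        ref = resources.files("edaphoniche.data") / "wrb_aggregation.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["detailed_code", "dominant_class"])
            for k, v in self.mapping.items():
                w.writerow([k, v])


def _plot_xy(plots: Sequence[PlotRecord] | pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    if isinstance(plots, pd.DataFrame):
        ids = [str(i) for i in plots.index]
        return ids, plots["x"].to_numpy(float), plots["y"].to_numpy(float)
    ids = [p.plot_id for p in plots]
    return ids, np.array([p.x for p in plots]), np.array([p.y for p in plots])


def extract_class_at_points(
    polygons: PolygonLayer, plots: Sequence[PlotRecord] | pd.DataFrame
) -> pd.Series:
    """Detailed soil class of the polygon containing each plot.

    Boundary points resolve to the first covering polygon in layer order.
    Plots outside all polygons are missing (NaN) and counted in a warning.
    """
    if len(polygons) == 0:
        raise ValueError("empty polygon layer")
    ids, xs, ys = _plot_xy(plots)
    points = shapely.points(xs, ys)
    out = np.full(len(ids), None, dtype=object)
    unassigned = np.ones(len(ids), dtype=bool)
    for geom, cls in zip(polygons.geometries, polygons.classes):
        if not unassigned.any():
            break
        hit = unassigned & shapely.covers(geom, points)
        out[hit] = cls
        unassigned &= ~hit
    n_miss = int(unassigned.sum())
    if n_miss:
        warnings.warn(f"{n_miss} of {len(ids)} plots fall outside the polygon layer")
        logger.info("extract_class_at_points: %d/%d plots without coverage", n_miss, len(ids))
    return pd.Series(out, index=pd.Index(ids, name="plot_id"), name="detailed_class")


def extract_raster_at_points(
    stack: SoilMapStack, plots: Sequence[PlotRecord] | pd.DataFrame
) -> pd.DataFrame:
    """Per-plot class probabilities and CEC by nearest-cell lookup.

    Returns one row per plot, one column per probability layer plus
    ``cec``.  Points outside the raster extent get an all-missing row.
    """
    specs = {layer.spec for layer in stack.prob_layers.values()} | {stack.cec.spec}
    if len(specs) != 1:
        raise GridMismatchError("probability and CEC layers are not on one grid")
    ids, xs, ys = _plot_xy(plots)
    cols = {name: layer.value_at(xs, ys) for name, layer in stack.prob_layers.items()}
    cols["cec"] = stack.cec.value_at(xs, ys)
    return pd.DataFrame(cols, index=pd.Index(ids, name="plot_id"))


def aggregate_classes(
    detailed: pd.Series | Sequence[str | None], table: ClassAggregationTable
) -> pd.Series:
    """Replace detailed class codes by their WRB dominant class.

    Missing inputs stay missing; any observed code absent from the table
    raises :class:`UnmappedClassError` naming the offending codes.
    """
    s = detailed if isinstance(detailed, pd.Series) else pd.Series(list(detailed))
    observed = {c for c in s.dropna().unique()}
    unknown = [c for c in observed if c not in table.mapping]
    if unknown:
        raise UnmappedClassError(unknown)
    return s.map(lambda c: table.mapping.get(c) if pd.notna(c) else None).rename("dominant_class")
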