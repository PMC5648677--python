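"""Core spatial containers and plain-text geospatial I/O.

Rasters are kept as :class:`RasterGrid` (a 2-D array plus an affine-free
grid description: lower-left origin and square cell size) and serialized as
ESRI ASCII grids (``.asc``).  Polygon layers are shapely geometries with a
``wrb_class`` attribute, serialized as GeoJSON.  Coordinates are planar
(meters); all layers of a stack must share one grid and one CRS by
construction — there is no reprojection engine here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

NODATA = -9999.0


class GridMismatchError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-celled raster grid.

    ``origin`` is the (x, y) of the grid's lower-left corner; row index 0 of
    the data array is the *bottom* row, so ``y`` increases with row index.
    """

    origin: tuple[float, float]
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must contain at least one cell")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) center coordinates, each of shape (nrows, ncols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices for point coordinates.

        Returns (row, col, inside) where ``inside`` marks points within the
        grid extent; indices for outside points are clipped placeholders.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y - y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return np.clip(row, 0, self.nrows - 1), np.clip(col, 0, self.ncols - 1), inside


@dataclass
class RasterGrid:
    """A single-band raster: float data on a :class:`GridSpec`.

    Missing cells are NaN in memory and ``NODATA`` on disk.
    """

    spec: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.spec.nrows, self.spec.ncols):
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid ({self.spec.nrows}, {self.spec.ncols})"
            )

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup (no interpolation); outside-extent -> NaN."""
        row, col, inside = self.spec.index_of(x, y)
        out = self.data[row, col].astype(float)
        out[~inside] = np.nan
        return out

    def shifted(self, dcols: int, drows: int) -> "RasterGrid":
        """Shift content by whole cells on the fixed grid; vacated cells NaN."""
        out = np.full_like(self.data, np.nan)
        nr, nc = self.data.shape
        r0, r1 = max(drows, 0), min(nr + drows, nr)
        c0, c1 = max(dcols, 0), min(nc + dcols, nc)
        if r0 < r1 and c0 < c1:
            out[r0:r1, c0:c1] = self.data[r0 - drows : r1 - drows, c0 - dcols : c1 - dcols]
        return RasterGrid(self.spec, out)

    # --- ESRI ASCII grid (.asc) codec -------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        x0, y0 = self.spec.origin
        header = (
            f"ncols {self.spec.ncols}\n"
            f"nrows {self.spec.nrows}\n"
            f"xllcorner {x0!r}\n"
            f"yllcorner {y0!r}\n"
            f"cellsize {self.spec.cell_size!r}\n"
            f"NODATA_value {NODATA}\n"
        )
        body = np.where(np.isnan(self.data), NODATA, self.data)
        with open(path, "w") as fh:
            fh.write(header)
            # ASCII grids are written north-to-south: flip the bottom-up rows.
            # 17 significant digits round-trip float64 exactly
            np.savetxt(fh, body[::-1], fmt="%.17g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            body = np.loadtxt(fh)
        body = np.atleast_2d(body)[::-1].copy()
        nodata = meta.get("nodata_value", NODATA)
        body[body == nodata] = np.nan
        spec = GridSpec(
            origin=(meta["xllcorner"], meta["yllcorner"]),
            cell_size=meta["cellsize"],
            nrows=int(meta["nrows"]),
            ncols=int(meta["ncols"]),
        )
        return cls(spec, body)


@dataclass
class PolygonLayer:
    """An ordered polygon layer with one soil-class attribute per geometry.

    Layer order matters: points on shared boundaries resolve to the first
    covering polygon in order.
    """

    geometries: list[BaseGeometry]
    classes: list[str]

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.classes):
            raise ValueError("one class per geometry required")

    def __len__(self) -> int:
        return len(self.geometries)

    def translated(self, dx: float, dy: float) -> "PolygonLayer":
        geoms = [shapely.affinity.translate(g, dx, dy) for g in self.geometries]
        return PolygonLayer(geoms, list(self.classes))

    def write_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"wrb_class": cls},
                "geometry": geom_mapping(geom),
            }
            for geom, cls in zip(self.geometries, self.classes)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def read_geojson(cls, path: str | Path) -> "PolygonLayer":
        with open(path) as fh:
            fc = json.load(fh)
        geoms = [geom_shape(f["geometry"]) for f in fc["features"]]
        classes = [str(f["properties"]["wrb_class"]) for f in fc["features"]]
        return cls(geoms, classes)


@dataclass
class SoilMapStack:
    """Polygon class map + per-class probability rasters + CEC raster.

    All rasters share one :class:`GridSpec`; probability values lie in
    [0, 1] and sum to at most 1 per cell.
    """

    polygons: PolygonLayer | None
    prob_layers: dict[str, RasterGrid]
    cec: RasterGrid

    def __post_init__(self) -> None:
        for name, layer in self.prob_layers.items():
            if layer.spec != self.cec.spec:
                raise GridMismatchError(f"layer {name!r} is not on the CEC grid")
            vals = layer.data[np.isfinite(layer.data)]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(f"probability layer {name!r} has values outside [0, 1]")

    @property
    def spec(self) -> GridSpec:
        return self.cec.spec

    def write(self, directory: str | Path) -> None:
        """Write the stack as text layers: .asc rasters + GeoJSON polygons."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, layer in self.prob_layers.items():
            layer.write_ascii(directory / f"prob_{name}.asc")
        self.cec.write_ascii(directory / "cec.asc")
        if self.polygons is not None:
            self.polygons.write_geojson(directory / "classes.geojson")

    @classmethod
    def read(cls, directory: str | Path) -> "SoilMapStack":
        directory = Path(directory)
        prob_layers = {
            p.stem.removeprefix("prob_"): RasterGrid.read_ascii(p)
            for p in sorted(directory.glob("prob_*.asc"))
        }
        cec = RasterGrid.read_ascii(directory / "cec.asc")
        poly_path = directory / "classes.geojson"
        polygons = PolygonLayer.read_geojson(poly_path) if poly_path.exists() else None
        return cls(polygons, prob_layers, cec)


@dataclass
class PlotRecord:
    """One field plot: location, dataset tag, measured soil chemistry, ferns.

    ``cation_cmolkg`` is the exchangeable Ca+Mg+K concentration of the top
    5 cm of mineral soil, in cmol(+)/kg.  ``abundances`` maps taxon name to
    a non-negative individual count.  ``true_cation`` is populated only for
    synthetic plots, where the generating field is known.
    """

    plot_id: str
    dataset: str
    x: float
    y: float
    cation_cmolkg: float | None = None
    abundances: dict[str, int] = field(default_factory=dict)
    true_cation: float | None = None

    def __post_init__(self) -> None:
        if self.cation_cmolkg is not None and not np.isnan(self.cation_cmolkg):
            if self.cation_cmolkg <= 0:
                raise ValueError(f"plot {self.plot_id}: cation concentration must be > 0")
        for taxon, count in self.abundances.items():
            if count < 0:
                raise ValueError(f"plot {self.plot_id}: negative abundance for {taxon}")


def plots_to_frame(plots: Sequence[PlotRecord]) -> pd.DataFrame:
    """Tabulate plots as the canonical CSV layout (one row per plot)."""
    rows = []
    for p in plots:
        row = {
            "plot_id": p.plot_id,
            "dataset": p.dataset,
            "x": p.x,
            "y": p.y,
            "cation_cmolkg": p.cation_cmolkg,
        }
        if p.true_cation is not None:
            row["true_cation"] = p.true_cation
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id")


def frame_to_plots(df: pd.DataFrame) -> list[PlotRecord]:
    df = df.reset_index() if df.index.name == "plot_id" else df
    plots = []
    for row in df.itertuples(index=False):
        plots.append(
            PlotRecord(
                plot_id=str(row.plot_id),
                dataset=str(row.dataset),
                x=float(row.x),
                y=float(row.y),
                cation_cmolkg=float(row.cation_cmolkg)
                if "cation_cmolkg" in df.columns and pd.notna(row.cation_cmolkg)
                else None,
                true_cation=float(row.true_cation)
                if "true_cation" in df.columns and pd.notna(row.true_cation)
                else None,
            )
        )
    return plots


def abundance_frame(plots: Sequence[PlotRecord], taxa: Iterable[str] | None = None) -> pd.DataFrame:
    """Plots x taxa count matrix from the per-plot abundance dicts."""
    if taxa is None:
        seen: dict[str, None] = {}
        for p in plots:
            for t in p.abundances:
                seen.setdefault(t)
        taxa = list(seen)
    data = {t: [p.abundances.get(t, 0) for p in plots] for t in taxa}
    return pd.DataFrame(data, index=pd.Index([p.plot_id for p in plots], name="plot_id"))
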