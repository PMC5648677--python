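"""Synthetic soil landscapes, error-laden map layers, and fern communities.

The generator emulates the statistical situation a digital-soil-map user
faces in lowland Amazonia: a mosaic of WRB soil-class patches whose
within-class exchangeable-cation concentrations overlap broadly (spanning
up to two orders of magnitude), per-class occurrence-probability rasters, a
cation-exchange-capacity (CEC) surrogate only weakly correlated with the
base-cation gradient, and rigid georeferencing displacement of the map
relative to the ground truth.  Fern communities respond to the log-cation
gradient through unimodal Gaussian (coenocline) curves with Poisson counts.

Everything is a pure function of (config, seed): identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .core import GridSpec, PlotRecord, PolygonLayer, RasterGrid, SoilMapStack

#: WRB-FAO dominant soil classes common in lowland Amazonia.
DOMINANT_CLASSES = [
    "Acrisols",
    "Ferralsols",
    "Gleysols",
    "Podzols",
    "Cambisols",
    "Plinthosols",
    "Alisols",
    "Arenosols",
    "Lixisols",
    "Fluvisols",
]

#: Fraction of a boundary cell's probability mass spread to neighbor classes.
BOUNDARY_EPS = 0.2


@dataclass(frozen=True)
class SpeciesResponseParams:
    """Gaussian response of one taxon to the log-cation gradient.

    ``true_optimum`` and ``true_tolerance`` are on the natural-log
    cmol(+)/kg scale; ``max_abundance`` is the expected count at optimum.
    """

    taxon: str
    true_optimum: float
    true_tolerance: float
    max_abundance: float

    def __post_init__(self) -> None:
        if self.true_tolerance <= 0:
            raise ValueError("true_tolerance must be > 0")
        if self.max_abundance < 0:
            raise ValueError("max_abundance must be >= 0")


def default_species() -> list[SpeciesResponseParams]:
    """Thirteen fern taxa with well-separated optima spanning the gradient.

    The taxa are those routinely used as edaphic indicators in Amazonian
    fern inventories; optima are spread evenly over the log-cation range the
    default landscape produces, with narrow tolerances so the community
    segregates clearly along the gradient.
    """
    names = [
        "Adiantum pulverulentum",
        "Adiantum tomentosum",
        "Cyathea pungens",
        "Cyclopeltis semicordata",
        "Lindsaea guianensis",
        "Metaxya",
        "Pteris pungens",
        "Saccoloma inaequale",
        "Schizaea elegans",
        "Thelypteris macrophylla",
        "Trichomanes elegans",
        "Trichomanes martiusii",
        "Triplophyllum",
    ]
    optima = np.linspace(-2.0, 3.0, len(names))
    amplitudes = [12, 20, 8, 15, 25, 10, 18, 9, 14, 22, 11, 16, 13]
    return [
        SpeciesResponseParams(n, float(u), 0.5, float(a))
        for n, u, a in zip(names, optima, amplitudes)
    ]


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic soil landscape.

    extent : (xmin, ymin, xmax, ymax) in planar meters.
    cell_size : raster cell edge, meters.
    n_classes : number of WRB dominant classes present.
    class_patch_scale : characteristic soil-polygon size, meters.
    class_cation_params : per-class (log-mean, log-sd) of the lognormal
        cation concentration in cmol(+)/kg (natural log).
    cec_correlation : target Pearson correlation between the CEC raster and
        the true log-cation field (the study system's value is ~0.1).
    smoothness : share of within-class log variance carried by a smooth
        spatial field rather than cell-level noise, in [0, 1).
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 100_000.0, 100_000.0)
    cell_size: float = 500.0
    n_classes: int = 8
    class_patch_scale: float = 10_000.0
    class_cation_params: tuple[tuple[float, float], ...] | None = None
    cec_correlation: float = 0.1
    smoothness: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if abs(self.cec_correlation) > 1:
            raise ValueError("|cec_correlation| must be <= 1")
        if not 0 <= self.smoothness < 1:
            raise ValueError("smoothness must be in [0, 1)")
        xmin, ymin, xmax, ymax = self.extent
        if xmax - xmin < self.cell_size or ymax - ymin < self.cell_size:
            raise ValueError("extent smaller than one cell")
        if self.class_cation_params is not None:
            if len(self.class_cation_params) != self.n_classes:
                raise ValueError("need one (log-mean, log-sd) pair per class")
            for _, sd in self.class_cation_params:
                if sd < 0:
                    raise ValueError("log-sd must be >= 0")

    def cation_params(self) -> list[tuple[float, float]]:
        if self.class_cation_params is not None:
            return list(self.class_cation_params)
        # Class log-means spread over ~0.3-15 cmol/kg; log-sd 1.2 makes the
        # central 95% of each class span about two orders of magnitude.
        mus = np.linspace(np.log(0.3), np.log(15.0), self.n_classes)
        return [(float(m), 1.2) for m in mus]

    def class_names(self) -> list[str]:
        names = list(DOMINANT_CLASSES)
        while len(names) < self.n_classes:
            names.append(f"Class{len(names) + 1}")
        return names[: self.n_classes]

    def grid_spec(self) -> GridSpec:
        xmin, ymin, xmax, ymax = self.extent
        ncols = int((xmax - xmin) // self.cell_size)
        nrows = int((ymax - ymin) // self.cell_size)
        return GridSpec((xmin, ymin), self.cell_size, nrows, ncols)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated landscape."""

    cation_field: RasterGrid  # cmol(+)/kg, strictly positive
    class_index: np.ndarray  # int per cell, indexes class_names
    class_names: list[str]
    species: list[SpeciesResponseParams] = field(default_factory=default_species)

    @property
    def log_cation(self) -> np.ndarray:
        return np.log(self.cation_field.data)

    def true_class_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col, inside = self.cation_field.spec.index_of(x, y)
        out = np.array([self.class_names[i] for i in self.class_index[row, col]], dtype=object)
        out[~inside] = None
        return out


def _smooth_standard_field(rng: np.random.Generator, spec: GridSpec, scale_cells: float) -> np.ndarray:
    """Standardized smooth Gaussian random field on the grid."""
    f = gaussian_filter(rng.standard_normal((spec.nrows, spec.ncols)), sigma=scale_cells)
    sd = f.std()
    if sd == 0:  # single-cell grids
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def _region_polygons(region_id: np.ndarray, spec: GridSpec) -> list[shapely.Polygon]:
    """One polygon per Voronoi region, as the union of its cells.

    Cells of a region are merged into per-row runs first, which keeps the
    number of boxes handed to GEOS small.
    """
    x0, y0 = spec.origin
    cs = spec.cell_size
    polys = []
    for rid in range(region_id.max() + 1):
        boxes = []
        for r in np.unique(np.nonzero(region_id == rid)[0]):
            cols = np.nonzero(region_id[r] == rid)[0]
            # split into consecutive runs
            breaks = np.nonzero(np.diff(cols) > 1)[0]
            for run in np.split(cols, breaks + 1):
                boxes.append(
                    shapely.box(
                        x0 + run[0] * cs, y0 + r * cs, x0 + (run[-1] + 1) * cs, y0 + (r + 1) * cs
                    )
                )
        polys.append(shapely.union_all(boxes))
    return polys


def generate_landscape(
    config: LandscapeConfig, build_polygons: bool = True
) -> tuple[SoilMapStack, SyntheticTruth]:
    """Generate a soil-map stack and its ground truth.

    The class mosaic is a Voronoi tessellation of uniformly seeded points
    (patch scale set by the seed density).  The true log-cation value of a
    cell is drawn from its class's normal law, with a configurable share of
    the variance carried by a smooth spatial field so that neighboring cells
    co-vary and classes overlap.  The CEC raster mixes the standardized
    log-cation field with an orthogonalized independent smooth field so its
    empirical correlation with log cation equals ``cec_correlation``
    (exactly, up to float round-off).  Probability rasters give the true
    class 1 - eps at patch boundaries, 1 in patch interiors.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    spec = config.grid_spec()
    xmin, ymin, xmax, ymax = config.extent

    # --- Voronoi class mosaic --------------------------------------------
    area = (xmax - xmin) * (ymax - ymin)
    n_seeds = max(config.n_classes, int(round(area / config.class_patch_scale**2)))
    seeds = np.column_stack(
        [rng.uniform(xmin, xmax, n_seeds), rng.uniform(ymin, ymax, n_seeds)]
    )
    seed_class = np.concatenate(
        [np.arange(config.n_classes), rng.integers(0, config.n_classes, n_seeds - config.n_classes)]
    )
    X, Y = spec.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    _, region_flat = cKDTree(seeds).query(centers)
    region_id = region_flat.reshape(spec.nrows, spec.ncols)
    class_index = seed_class[region_id]

    # --- true cation field ------------------------------------------------
    params = config.cation_params()
    mus = np.array([p[0] for p in params])[class_index]
    sds = np.array([p[1] for p in params])[class_index]
    w = np.sqrt(config.smoothness)
    scale_cells = max(config.class_patch_scale / config.cell_size / 2.0, 1.0)
    smooth = _smooth_standard_field(rng, spec, scale_cells)
    noise = rng.standard_normal((spec.nrows, spec.ncols))
    log_cation = mus + sds * (w * smooth + np.sqrt(1 - w**2) * noise)
    cation_field = RasterGrid(spec, np.exp(log_cation))

    # --- CEC raster: exact target correlation with log cation -------------
    z = log_cation.ravel()
    z_std = (z - z.mean()) / z.std()
    f = _smooth_standard_field(rng, spec, scale_cells).ravel() + 0.3 * rng.standard_normal(z.size)
    f = f - f.mean()
    f -= (f @ z_std) / (z_std @ z_std) * z_std  # orthogonalize against log cation
    f_std = f / f.std()
    r = config.cec_correlation
    cec_std = r * z_std + np.sqrt(1 - r**2) * f_std
    # affine map onto a plausible CEC scale (cmol(+)/kg); clipping at 0.1
    # affects <0.1% of cells and leaves the correlation within tolerance
    cec = np.maximum(10.0 + 3.0 * cec_std, 0.1).reshape(spec.nrows, spec.ncols)
    cec_grid = RasterGrid(spec, cec)

    # --- per-class probability rasters ------------------------------------
    names = config.class_names()
    prob = np.zeros((config.n_classes, spec.nrows, spec.ncols))
    np.put_along_axis(prob, class_index[None], 1.0, axis=0)
    shifts = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    diff_count = np.zeros(class_index.shape, dtype=int)
    neighbor_cls = []
    for dr, dc in shifts:
        nb = np.full(class_index.shape, -1)
        src = class_index
        nb[max(dr, 0) or None : spec.nrows + min(dr, 0) or None,
           max(dc, 0) or None : spec.ncols + min(dc, 0) or None] = src[
            max(-dr, 0) or None : spec.nrows + min(-dr, 0) or None,
            max(-dc, 0) or None : spec.ncols + min(-dc, 0) or None,
        ]
        differs = (nb >= 0) & (nb != class_index)
        diff_count += differs
        neighbor_cls.append((nb, differs))
    boundary = diff_count > 0
    for nb, differs in neighbor_cls:
        share = np.zeros_like(prob[0])
        share[differs] = BOUNDARY_EPS / diff_count[differs]
        rows, cols = np.nonzero(differs)
        np.add.at(prob, (nb[differs], rows, cols), share[differs])
    true_at_boundary = class_index[boundary]
    rows, cols = np.nonzero(boundary)
    prob[true_at_boundary, rows, cols] -= BOUNDARY_EPS
    prob_layers = {names[k]: RasterGrid(spec, prob[k]) for k in range(config.n_classes)}

    polygons = None
    if build_polygons:
        geoms = _region_polygons(region_id, spec)
        polygons = PolygonLayer(geoms, [names[seed_class[i]] for i in range(n_seeds)])

    stack = SoilMapStack(polygons, prob_layers, cec_grid)
    truth = SyntheticTruth(cation_field, class_index, names)
    return stack, truth


def displace_map(stack: SoilMapStack, dx: float, dy: float) -> SoilMapStack:
    """Rigidly displace a soil-map stack by (dx, dy) meters.

    Polygons translate exactly; raster content shifts by whole cells
    (nearest-cell snap of the displacement) on the fixed analysis grid, with
    vacated cells marked missing.  Emulates georeferencing error, e.g. the
    tens-of-km offsets of floodplain soil classes in legacy soil maps.
    """
    spec = stack.spec
    dcols = int(round(dx / spec.cell_size))
    drows = int(round(dy / spec.cell_size))
    if abs(dcols) >= spec.ncols or abs(drows) >= spec.nrows:
        raise ValueError("displacement moves the map entirely off the analysis extent")
    prob = {name: layer.shifted(dcols, drows) for name, layer in stack.prob_layers.items()}
    cec = stack.cec.shifted(dcols, drows)
    polygons = stack.polygons.translated(dx, dy) if stack.polygons is not None else None
    return SoilMapStack(polygons, prob, cec)


def sample_plots(
    truth: SyntheticTruth,
    n: int,
    noise_sd: float,
    seed: int,
    dataset: str = "synthetic",
    id_prefix: str | None = None,
) -> list[PlotRecord]:
    """Draw n field plots uniformly over the extent.

    The measured cation concentration is the true cell value perturbed by
    multiplicative lognormal noise of the given log-sd, standing in for
    laboratory measurement error (the field protocols differ between the
    Mehlich I and ammonium-acetate extractions; noise_sd is the knob).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    xmin, ymin, xmax, ymax = truth.cation_field.spec.extent
    xs = rng.uniform(xmin, xmax, n)
    ys = rng.uniform(ymin, ymax, n)
    true = truth.cation_field.value_at(xs, ys)
    measured = true * np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else true.copy()
    prefix = id_prefix if id_prefix is not None else dataset
    return [
        PlotRecord(
            plot_id=f"{prefix}-{i:05d}",
            dataset=dataset,
            x=float(xs[i]),
            y=float(ys[i]),
            cation_cmolkg=float(measured[i]),
            true_cation=float(true[i]),
        )
        for i in range(n)
    ]


def simulate_abundances(
    plots: Sequence[PlotRecord],
    params: Sequence[SpeciesResponseParams],
    seed: int,
) -> pd.DataFrame:
    """Simulate fern counts from Gaussian responses to the log-cation axis.

    Expected abundance of taxon k at plot i is
    ``A_k * exp(-(x_i - u_k)^2 / (2 t_k^2))`` with x_i the log *true*
    cation concentration; realized counts are Poisson.  The counts are also
    written into each plot's ``abundances`` dict.
    """
    missing = [p.plot_id for p in plots if p.true_cation is None]
    if missing:
        raise ValueError(f"plots lack true cation values: {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.log([p.true_cation for p in plots])
    mat = np.empty((len(plots), len(params)), dtype=int)
    for k, sp in enumerate(params):
        mean = sp.max_abundance * np.exp(-((x - sp.true_optimum) ** 2) / (2 * sp.true_tolerance**2))
        mat[:, k] = rng.poisson(mean)
    df = pd.DataFrame(
        mat,
        index=pd.Index([p.plot_id for p in plots], name="plot_id"),
        columns=[sp.taxon for sp in params],
    )
    for i, p in enumerate(plots):
        p.abundances = {sp.taxon: int(mat[i, k]) for k, sp in enumerate(params)}
    return df
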