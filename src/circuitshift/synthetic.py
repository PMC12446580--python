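"""Synthetic landscape generators.

The pipeline is exercised end to end on generated landscapes that carry
the statistical structure the analysis assumes: spatially autocorrelated
climate fields with additive scenario warming, clumped categorical
landcover, rasterised linear features (rivers/roads), occurrence records
sampled from a known logistic suitability model, Voronoi reporting zones
and blob-shaped protected-area masks.  Because the generating model is
known, downstream stages can be tested for *recovery* (e.g. the logistic
learner recovering the true coefficients, current maps concentrating in
a planted corridor) rather than only for internal consistency.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .occurrences import OccurrenceSet
from .raster import Raster, RasterStack

__all__ = [
    "TrueModel",
    "gen_climate_stack",
    "gen_landcover",
    "gen_linear_features",
    "gen_occurrences",
    "gen_zones",
    "gen_protected_mask",
    "gen_corridor_fixture",
    "smooth_field",
]


@dataclass
class TrueModel:
    """Ground-truth logistic occurrence model.

    ``coefficients[0]`` is the intercept; ``coefficients[1:]`` multiply the
    predictor layers in stack order.  Occurrence probability per cell is
    ``sigmoid(b0 + sum_k b_k * layer_k)``.
    """

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def probability(self, stack: RasterStack) -> np.ndarray:
        arr = stack.as_array()
        if arr.shape[0] != len(self.coefficients) - 1:
            raise ValueError(
                f"model expects {len(self.coefficients) - 1} layers, stack has {arr.shape[0]}"
            )
        eta = self.coefficients[0] + np.tensordot(self.coefficients[1:], arr, axes=1)
        return 1.0 / (1.0 + np.exp(-eta))


def _check_dims(n_rows: int, n_cols: int) -> None:
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("raster dimensions must be positive")


def smooth_field(n_rows: int, n_cols: int, rng: np.random.Generator, *, sigma: float | None = None) -> np.ndarray:
    """Smoothed seeded white noise, standardised to mean 0 / sd 1.

    Gaussian blur of white noise gives a random field whose autocorrelation
    range is set by ``sigma`` (default: 1/10 of the short grid side, at
    least 2 cells).
    """
    _check_dims(n_rows, n_cols)
    if sigma is None:
        sigma = max(2.0, min(n_rows, n_cols) / 10.0)
    noise = rng.standard_normal((n_rows, n_cols))
    fld = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    fld -= fld.mean()
    sd = fld.std()
    if sd > 0:
        fld /= sd
    return fld


def gen_climate_stack(
    n_rows: int,
    n_cols: int,
    n_layers: int,
    scenario_shift: float | np.ndarray = 0.0,
    seed: int = 0,
    *,
    cell_size: float = 1000.0,
) -> RasterStack:
    """Generate a stack of smooth climate-like layers.

    Each layer is a low-frequency random field plus a north-south linear
    gradient (amplitude 1 across the grid), emulating the broad latitudinal
    structure of temperature/precipitation surfaces.  ``scenario_shift`` is
    an additive per-layer offset emulating warming between climate
    scenarios; the underlying field depends only on the seed, so shifted
    and unshifted stacks differ by exactly the shift.
    """
    _check_dims(n_rows, n_cols)
    if n_layers < 2:
        raise ValueError("need at least 2 climate layers")
    shifts = np.broadcast_to(np.asarray(scenario_shift, dtype=float), (n_layers,))
    rng = np.random.default_rng(seed)
    gradient = np.linspace(0.5, -0.5, n_rows)[:, None] * np.ones((1, n_cols))
    layers = []
    for k in range(n_layers):
        fld = smooth_field(n_rows, n_cols, rng) + gradient + shifts[k]
        layers.append(Raster(fld, cell_size=cell_size))
    names = [f"bio{k + 1}" for k in range(n_layers)]
    return RasterStack(layers, names)


def gen_landcover(n_rows: int, n_cols: int, n_classes: int, seed: int = 0, *, cell_size: float = 1000.0) -> Raster:
    """Clumped categorical landcover with codes ``1..n_classes``.

    A smooth random field is cut at its own equal-frequency quantiles, so
    every class is present and patches are spatially contiguous.
    """
    _check_dims(n_rows, n_cols)
    if not 2 <= n_classes <= 15:
        raise ValueError("n_classes must be between 2 and 15")
    rng = np.random.default_rng(seed)
    fld = smooth_field(n_rows, n_cols, rng)
    qs = np.quantile(fld, np.linspace(0, 1, n_classes + 1)[1:-1])
    codes = np.digitize(fld, qs) + 1
    return Raster(codes.astype(np.int32), cell_size=cell_size, nodata=-9999)


def gen_linear_features(n_rows: int, n_cols: int, n_lines: int, seed: int = 0, *, cell_size: float = 1000.0) -> Raster:
    """Binary raster of rasterised polylines crossing the grid.

    Each feature starts and ends on different boundary edges, with a couple
    of interior waypoints, and is drawn with 8-connected Bresenham segments
    so every feature is one connected component.
    """
    from skimage.draw import line as sk_line

    _check_dims(n_rows, n_cols)
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_rows, n_cols), dtype=np.int32)

    def edge_point(edge: int) -> tuple[int, int]:
        if edge == 0:  # top
            return 0, int(rng.integers(0, n_cols))
        if edge == 1:  # bottom
            return n_rows - 1, int(rng.integers(0, n_cols))
        if edge == 2:  # left
            return int(rng.integers(0, n_rows)), 0
        return int(rng.integers(0, n_rows)), n_cols - 1  # right

    for _ in range(n_lines):
        e0, e1 = rng.choice(4, size=2, replace=False)
        pts = [edge_point(int(e0))]
        for _ in range(2):
            pts.append((int(rng.integers(0, n_rows)), int(rng.integers(0, n_cols))))
        pts.append(edge_point(int(e1)))
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = sk_line(r0, c0, r1, c1)
            out[rr, cc] = 1
    return Raster(out, cell_size=cell_size, nodata=-9999)


def gen_occurrences(
    true_model: TrueModel,
    predictor_stack: RasterStack,
    n_presence: int,
    seed: int = 0,
) -> OccurrenceSet:
    """Sample presence cells with probability proportional to the true suitability.

    At most one record per cell (sampling without replacement); records are
    placed at cell centres.
    """
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    geom = predictor_stack.geometry
    n_cells = geom.n_rows * geom.n_cols
    if n_presence > n_cells:
        raise ValueError(f"n_presence={n_presence} exceeds cell count {n_cells}")
    rng = np.random.default_rng(seed)
    p = true_model.probability(predictor_stack).ravel()
    idx = rng.choice(n_cells, size=n_presence, replace=False, p=p / p.sum())
    idx.sort()
    rows, cols = np.unravel_index(idx, geom.shape)
    xs, ys = [], []
    for r, c in zip(rows, cols):
        x, y = geom.cell_center(int(r), int(c))
        xs.append(x)
        ys.append(y)
    return OccurrenceSet.from_records(xs, ys, np.ones(n_presence, dtype=int))


def gen_zones(n_rows: int, n_cols: int, n_zones: int, seed: int = 0, *, cell_size: float = 1000.0) -> Raster:
    """Voronoi partition of the grid into ``n_zones`` contiguous zones, codes 1..n."""
    _check_dims(n_rows, n_cols)
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    n_cells = n_rows * n_cols
    if n_zones > n_cells:
        raise ValueError("n_zones exceeds cell count")
    rng = np.random.default_rng(seed)
    seeds_flat = rng.choice(n_cells, size=n_zones, replace=False)
    sr, sc = np.unravel_index(seeds_flat, (n_rows, n_cols))
    tree = cKDTree(np.column_stack([sr, sc]))
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    codes = (nearest + 1).reshape(n_rows, n_cols)
    return Raster(codes.astype(np.int32), cell_size=cell_size, nodata=-9999)


def gen_protected_mask(
    n_rows: int, n_cols: int, coverage_fraction: float, seed: int = 0, *, cell_size: float = 1000.0
) -> Raster:
    """Blob-shaped binary protection mask with the requested areal coverage.

    A smooth field thresholded at its ``1 - coverage`` quantile yields
    contiguous blobs whose total area matches the target coverage to well
    within 2 percentage points.
    """
    _check_dims(n_rows, n_cols)
    if not 0 <= coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if coverage_fraction == 0:
        mask = np.zeros((n_rows, n_cols))
    elif coverage_fraction == 1:
        mask = np.ones((n_rows, n_cols))
    else:
        fld = smooth_field(n_rows, n_cols, rng)
        thr = np.quantile(fld, 1 - coverage_fraction)
        mask = (fld >= thr).astype(float)
    return Raster(mask.astype(np.int32), cell_size=cell_size, nodata=-9999)


def gen_corridor_fixture(
    n_rows: int,
    n_cols: int,
    corridor_width: int,
    background_resistance: float,
    corridor_resistance: float,
    *,
    cell_size: float = 1000.0,
) -> Raster:
    """Uniform-background resistance raster with one straight low-resistance band.

    The corridor is a horizontal band of ``corridor_width`` rows centred on
    the grid, spanning the full width — the simplest landscape in which a
    connectivity method must concentrate current.
    """
    _check_dims(n_rows, n_cols)
    if corridor_resistance > background_resistance:
        raise ValueError("corridor_resistance must not exceed background_resistance")
    if corridor_width >= min(n_rows, n_cols):
        raise ValueError("corridor width must be smaller than the grid")
    vals = np.full((n_rows, n_cols), float(background_resistance))
    r0 = (n_rows - corridor_width) // 2
    vals[r0 : r0 + corridor_width, :] = corridor_resistance
    return Raster(vals, cell_size=cell_size)
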