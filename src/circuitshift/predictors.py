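"""Model-ready predictor derivation.

Four standard raster preparations feed the distribution models:

* :func:`grid_distance` — eight-directional shortest-path distance to the
  nearest feature cell (rivers, roads), with orthogonal steps costing one
  cell size and diagonal steps sqrt(2) cell sizes;
* :func:`tpi` — topographic position index, the cell elevation minus the
  mean of a square focal window;
* :func:`aggregate` — block aggregation to a coarser resolution by mean
  (continuous layers) or mode (categorical layers);
* :func:`collinearity_filter` — greedy Pearson-correlation screen that
  drops layers correlated above a threshold with an already-retained
  layer, in a caller-supplied ecological priority order.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .raster import Raster, RasterStack

__all__ = ["grid_distance", "tpi", "aggregate", "collinearity_filter"]

SQRT2 = math.sqrt(2.0)


def grid_distance(feature_raster: Raster) -> Raster:
    """Eight-directional lattice distance to the nearest feature cell.

    Distances are shortest paths on the 8-neighbour lattice where an
    orthogonal step costs ``cell_size`` and a diagonal step
    ``sqrt(2) * cell_size``.  On an obstacle-free grid the two-pass chamfer
    sweep below computes this exactly (every shortest path can be ordered
    into a forward-then-backward monotone sequence of moves).
    """
    feat = np.asarray(feature_raster.values)
    mask = (feat == 1) & feature_raster.valid_mask()
    if not mask.any():
        raise ValueError("no feature cells: distance is undefined")
    n_rows, n_cols = mask.shape
    d = np.where(mask, 0.0, np.inf)

    ortho, diag = 1.0, SQRT2
    # forward pass: neighbours above and to the left
    for r in range(n_rows):
        for c in range(n_cols):
            best = d[r, c]
            if c > 0 and d[r, c - 1] + ortho < best:
                best = d[r, c - 1] + ortho
            if r > 0:
                if d[r - 1, c] + ortho < best:
                    best = d[r - 1, c] + ortho
                if c > 0 and d[r - 1, c - 1] + diag < best:
                    best = d[r - 1, c - 1] + diag
                if c < n_cols - 1 and d[r - 1, c + 1] + diag < best:
                    best = d[r - 1, c + 1] + diag
            d[r, c] = best
    # backward pass: neighbours below and to the right
    for r in range(n_rows - 1, -1, -1):
        for c in range(n_cols - 1, -1, -1):
            best = d[r, c]
            if c < n_cols - 1 and d[r, c + 1] + ortho < best:
                best = d[r, c + 1] + ortho
            if r < n_rows - 1:
                if d[r + 1, c] + ortho < best:
                    best = d[r + 1, c] + ortho
                if c < n_cols - 1 and d[r + 1, c + 1] + diag < best:
                    best = d[r + 1, c + 1] + diag
                if c > 0 and d[r + 1, c - 1] + diag < best:
                    best = d[r + 1, c - 1] + diag
            d[r, c] = best

    return feature_raster.copy_with(d * feature_raster.cell_size)


def tpi(dem: Raster, window_radius_cells: int) -> Raster:
    """Topographic position index with a truncated square focal window.

    Per cell: elevation minus the mean elevation of the
    ``(2r+1) x (2r+1)`` window centred on the cell; at the grid edges the
    window is truncated rather than wrapped or padded.
    """
    if window_radius_cells < 1:
        raise ValueError("window_radius_cells must be >= 1")
    z = np.asarray(dem.values, dtype=float)
    n_rows, n_cols = z.shape
    if 2 * window_radius_cells + 1 > max(n_rows, n_cols):
        raise ValueError("focal window larger than the grid")

    # truncated focal mean via 2-D summed-area tables of values and counts
    pad = window_radius_cells
    csum = np.zeros((n_rows + 1, n_cols + 1))
    csum[1:, 1:] = z.cumsum(0).cumsum(1)
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    r0 = np.clip(rows - pad, 0, n_rows)
    r1 = np.clip(rows + pad + 1, 0, n_rows)
    c0 = np.clip(cols - pad, 0, n_cols)
    c1 = np.clip(cols + pad + 1, 0, n_cols)
    window_sum = csum[r1, c1] - csum[r0, c1] - csum[r1, c0] + csum[r0, c0]
    window_n = (r1 - r0) * (c1 - c0)
    return dem.copy_with(z - window_sum / window_n)


def aggregate(raster: Raster, factor: int, method: str = "mean") -> Raster:
    """Aggregate to a coarser grid by ``factor`` x ``factor`` blocks.

    ``method='mean'`` for continuous layers, ``'mode'`` for categorical
    codes (smallest code wins ties).  Dimensions not divisible by the
    factor are padded with nodata; nodata cells are excluded from block
    statistics and all-nodata blocks stay nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if method not in {"mean", "mode"}:
        raise ValueError("method must be 'mean' or 'mode'")
    if factor == 1:
        return raster.copy_with(np.asarray(raster.values).copy())

    vals = np.asarray(raster.values, dtype=float)
    valid = raster.valid_mask()
    n_rows, n_cols = vals.shape
    out_rows = -(-n_rows // factor)
    out_cols = -(-n_cols // factor)
    padded = np.full((out_rows * factor, out_cols * factor), np.nan)
    padded[:n_rows, :n_cols] = np.where(valid, vals, np.nan)
    blocks = padded.reshape(out_rows, factor, out_cols, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(out_rows, out_cols, factor * factor)

    if method == "mean":
        with np.errstate(invalid="ignore"):
            out = np.nanmean(blocks, axis=2)
        out = np.where(np.isnan(out), raster.nodata, out)
    else:
        out = np.full((out_rows, out_cols), float(raster.nodata))
        for i in range(out_rows):
            for j in range(out_cols):
                b = blocks[i, j]
                b = b[~np.isnan(b)]
                if b.size:
                    codes, counts = np.unique(b, return_counts=True)
                    out[i, j] = codes[np.argmax(counts)]
    new_y0 = raster.origin[1] + (n_rows - out_rows * factor) * raster.cell_size
    return Raster(out, cell_size=raster.cell_size * factor, origin=(raster.origin[0], new_y0), nodata=raster.nodata)


def collinearity_filter(
    stack: RasterStack,
    threshold: float = 0.70,
    priority: list[str] | None = None,
) -> tuple[RasterStack, pd.DataFrame]:
    """Greedy collinearity screen on absolute Pearson correlation.

    Layers are scanned in ``priority`` order (the caller's ecological
    ranking); a layer is retained iff its |r| with every already-retained
    layer is <= ``threshold``.  Correlations use listwise-complete cells
    (cells where no layer is nodata).  Returns the retained sub-stack in
    original stack order and a report table
    ``layer, retained, max_abs_r_with_retained``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if priority is None:
        priority = list(stack.names)
    if set(priority) != set(stack.names):
        raise ValueError("priority must cover exactly the stack's layer names")
    if len(stack) < 2:
        report = pd.DataFrame(
            {"layer": stack.names, "retained": [True] * len(stack), "max_abs_r_with_retained": [0.0] * len(stack)}
        )
        return stack, report

    mask = stack.joint_valid_mask()
    data = {name: stack[name].values[mask].astype(float) for name in stack.names}
    retained: list[str] = []
    rows = []
    for name in priority:
        max_r = 0.0
        for kept in retained:
            r = abs(np.corrcoef(data[name], data[kept])[0, 1])
            max_r = max(max_r, r)
        keep = max_r <= threshold
        if keep:
            retained.append(name)
        rows.append({"layer": name, "retained": keep, "max_abs_r_with_retained": max_r})
    kept_in_order = [n for n in stack.names if n in retained]
    return stack.subset(kept_in_order), pd.DataFrame(rows)
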