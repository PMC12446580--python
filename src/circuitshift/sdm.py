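"""Species distribution modelling: from occurrence records to suitability surfaces.

The stages mirror standard presence/pseudo-absence ensemble SDM practice:

1. :func:`grid_records` thins presence records to one per grid cell;
2. :func:`sample_pseudo_absences` draws background cells (default three per
   presence) as pseudo-absences;
3. :func:`assign_spatial_blocks` tessellates the extent into hexagonal
   blocks and deals blocks into cross-validation folds, so evaluation
   folds are spatially separated;
4. :func:`fit_logistic` fits a (optionally quadratic) logistic regression
   by IRLS — the native learner; other learners plug in through the same
   :class:`FittedLearner` contract;
5. :func:`evaluate` scores held-out predictions with ROC-AUC (rank form,
   tie-corrected) and the true skill statistic maximised over thresholds;
6. members with adequate ROC form an :class:`EnsembleModel`, combined by
   committee averaging (fraction of members voting presence at their own
   best thresholds) or a TSS-weighted mean;
7. :func:`project` applies the ensemble to a climate-scenario predictor
   stack and :func:`mess_count` flags extrapolation by counting, per cell,
   how many climate predictors remain inside their training range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .occurrences import OccurrenceSet
from .raster import Raster, RasterStack

__all__ = [
    "FoldAssignment",
    "FittedLearner",
    "LogisticLearner",
    "EvaluationScores",
    "EnsembleModel",
    "grid_records",
    "sample_pseudo_absences",
    "assign_spatial_blocks",
    "fit_logistic",
    "evaluate",
    "committee_average",
    "weighted_mean_ensemble",
    "project",
    "mess_count",
    "extract_predictors",
]


# ---------------------------------------------------------------------------
# record preparation
# ---------------------------------------------------------------------------


def grid_records(points: OccurrenceSet, grid: Raster) -> OccurrenceSet:
    """Thin records to at most one presence per grid cell, snapped to cell centres.

    Output ordering is deterministic (row-major over cells).
    """
    cells: set[tuple[int, int]] = set()
    for x, y in zip(points.x, points.y):
        if grid.contains(x, y):
            cells.add(grid.index_of(x, y))
    if not cells:
        raise ValueError("all points fall outside the grid extent")
    xs, ys = [], []
    for r, c in sorted(cells):
        x, y = grid.cell_center(r, c)
        xs.append(x)
        ys.append(y)
    return OccurrenceSet.from_records(xs, ys, np.ones(len(xs), dtype=int))


def sample_pseudo_absences(
    presences: OccurrenceSet, grid: Raster, ratio: int = 3, seed: int = 0
) -> OccurrenceSet:
    """Draw ``ratio`` pseudo-absences per presence, uniformly over non-presence cells.

    Sampling is without replacement and excludes any cell holding a
    presence record; valid (non-nodata) cells only.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    n_presence = len(presences.presences())
    n_abs = ratio * n_presence
    if n_abs == 0:
        return OccurrenceSet.from_records([], [], [])
    presence_cells = {grid.index_of(x, y) for x, y in zip(presences.x, presences.y)}
    valid = grid.valid_mask()
    candidates = [
        (r, c)
        for r in range(grid.n_rows)
        for c in range(grid.n_cols)
        if valid[r, c] and (r, c) not in presence_cells
    ]
    if n_abs > len(candidates):
        raise ValueError(f"need {n_abs} pseudo-absence cells, only {len(candidates)} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_abs, replace=False)
    xs, ys = [], []
    for i in sorted(chosen):
        x, y = grid.cell_center(*candidates[i])
        xs.append(x)
        ys.append(y)
    return OccurrenceSet.from_records(xs, ys, np.zeros(n_abs, dtype=int))


# ---------------------------------------------------------------------------
# spatial block cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Per-record block and fold ids (all records of a block share a fold)."""

    block_id: np.ndarray
    fold_id: np.ndarray

    def __post_init__(self) -> None:
        self.block_id = np.asarray(self.block_id, dtype=int)
        self.fold_id = np.asarray(self.fold_id, dtype=int)
        for b in np.unique(self.block_id):
            folds = np.unique(self.fold_id[self.block_id == b])
            if len(folds) != 1:
                raise ValueError(f"block {b} spans multiple folds")


def _hex_index(x: np.ndarray, y: np.ndarray, size: float) -> np.ndarray:
    """Axial hex-bin index for points, pointy-top hexes of edge length ``size``."""
    qf = (math.sqrt(3) / 3 * x - y / 3) / size
    rf = (2 / 3 * y) / size
    # cube rounding
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    q = rx.astype(int)
    r = rz.astype(int)
    # pair to a single id
    return q * 100003 + r


def assign_spatial_blocks(
    records: OccurrenceSet,
    extent: tuple[float, float, float, float],
    n_blocks: int = 40,
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Hexagonal spatial blocking with random block-to-fold allocation.

    The extent is tessellated with hexagons sized so that roughly
    ``n_blocks`` hexes tile it (starting from the convention of block edge
    ~1/20 of the square root of the extent area and rescaling to the
    requested count).  Each occupied block is allocated uniformly at
    random to one of ``n_folds`` folds; records inherit their block's fold.
    """
    if n_folds > n_blocks:
        raise ValueError("n_folds cannot exceed n_blocks")
    xmin, ymin, xmax, ymax = extent
    area = (xmax - xmin) * (ymax - ymin)
    if area <= 0:
        raise ValueError("degenerate extent")
    # hex area = (3*sqrt(3)/2) * edge^2; choose edge so n_blocks hexes tile the extent
    edge = math.sqrt(2 * area / (3 * math.sqrt(3) * n_blocks))
    hex_ids = _hex_index(records.x - xmin, records.y - ymin, edge)
    blocks, block_id = np.unique(hex_ids, return_inverse=True)
    n_occupied = len(blocks)
    if n_occupied < n_folds:
        raise ValueError(f"only {n_occupied} occupied blocks for {n_folds} folds")
    rng = np.random.default_rng(seed)
    block_folds = rng.integers(1, n_folds + 1, size=n_occupied)
    return FoldAssignment(block_id=block_id, fold_id=block_folds[block_id])


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


@dataclass
class FittedLearner:
    """Contract every ensemble member satisfies: a name and a predict map.

    ``predict`` takes an ``(n, p)`` design-matrix of raw predictor values
    (one column per training layer, in training order) and returns
    occurrence probabilities in [0, 1].
    """

    kind: str
    layer_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class LogisticLearner(FittedLearner):
    coef: np.ndarray = field(default_factory=lambda: np.zeros(1))
    quadratic: bool = False
    separation_flag: bool = False

    def design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        parts = [np.ones((len(X), 1)), X]
        if self.quadratic:
            parts.append(X**2)
        return np.hstack(parts)

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.design(X) @ self.coef
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def extract_predictors(records: OccurrenceSet, predictors: RasterStack) -> tuple[np.ndarray, np.ndarray]:
    """Sample the stack at record locations.

    Returns ``(X, ok)`` where ``X`` is (n, p) raw predictor values and
    ``ok`` flags records whose cell is valid in every layer.
    """
    geom = predictors.geometry
    arr = predictors.as_array()
    valid = predictors.joint_valid_mask()
    n = len(records)
    X = np.full((n, len(predictors)), np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, (x, y) in enumerate(zip(records.x, records.y)):
        if not geom.contains(x, y):
            continue
        r, c = geom.index_of(x, y)
        if valid[r, c]:
            X[i] = arr[:, r, c]
            ok[i] = True
    return X, ok


def fit_logistic(
    train: OccurrenceSet,
    predictors: RasterStack,
    quadratic: bool = True,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticLearner:
    """Maximum-likelihood logistic regression by iteratively reweighted least squares.

    Design matrix: intercept + one linear term per layer (+ squared terms
    when ``quadratic``).  Convergence: log-likelihood change below ``tol``
    or ``max_iter`` sweeps.  On perfect separation (divergent coefficients
    or a singular weighted normal system) the fit is repeated with a small
    ridge penalty (1e-6) and flagged.
    """
    X, ok = extract_predictors(train, predictors)
    y = train.presence[ok]
    X = X[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both presences and absences")

    learner = LogisticLearner(kind="glm", layer_names=list(predictors.names), quadratic=quadratic)
    D = learner.design(X)

    def irls(ridge: float) -> tuple[np.ndarray, bool]:
        beta = np.zeros(D.shape[1])
        ll_old = -np.inf
        converged = False
        for _ in range(max_iter):
            eta = np.clip(D @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1 - p)
            ll = float(np.sum(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)))
            ll -= 0.5 * ridge * float(beta @ beta)
            if abs(ll - ll_old) < tol:
                converged = True
                break
            ll_old = ll
            z = eta + (y - p) / np.maximum(w, 1e-10)
            A = D.T @ (D * w[:, None]) + ridge * np.eye(D.shape[1])
            # lstsq tolerates rank-deficient designs (e.g. constant predictors)
            beta = np.linalg.lstsq(A, D.T @ (w * z), rcond=None)[0]
            if not np.all(np.isfinite(beta)):
                return beta, False
        return beta, converged

    def is_separated(beta: np.ndarray) -> bool:
        if not np.all(np.isfinite(beta)):
            return True
        p = 1.0 / (1.0 + np.exp(-np.clip(D @ beta, -500, 500)))
        return bool(p[y == 1].min() > 0.99 and p[y == 0].max() < 0.01)

    beta, converged = irls(0.0)
    if not converged or is_separated(beta):
        if is_separated(beta):
            learner.separation_flag = True
        beta, _ = irls(1e-6)
    learner.coef = beta
    return learner


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationScores:
    """TSS / ROC-AUC scores and the TSS-maximising threshold."""

    tss: float
    roc_auc: float
    best_threshold: float


def evaluate(pred: np.ndarray, truth: np.ndarray) -> EvaluationScores:
    """Score probabilistic predictions against binary truth.

    ROC-AUC uses the rank (Mann-Whitney) formulation with mid-rank tie
    correction; TSS = max over observed-prediction thresholds of
    (sensitivity + specificity - 1), with a cell voting presence when its
    probability is >= the threshold.
    """
    from scipy.stats import rankdata

    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("truth must contain both classes")

    ranks = rankdata(pred)
    auc = (ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    best_tss, best_thr = -np.inf, 0.5
    for thr in np.unique(pred):
        vote = pred >= thr
        sens = np.sum(vote & (truth == 1)) / n1
        spec = np.sum(~vote & (truth == 0)) / n0
        tss = sens + spec - 1
        if tss > best_tss:
            best_tss, best_thr = tss, float(thr)
    return EvaluationScores(tss=float(best_tss), roc_auc=float(auc), best_threshold=best_thr)


# ---------------------------------------------------------------------------
# ensembles and projection
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Retained learners with their evaluation scores.

    ``retention_rule`` is the minimum ROC-AUC an individual member needs;
    members below it never contribute to predictions.
    """

    members: list[tuple[FittedLearner, EvaluationScores]]
    retention_rule: float = 0.70
    mode: str = "committee"

    def retained(self) -> list[tuple[FittedLearner, EvaluationScores]]:
        return [(m, s) for m, s in self.members if s.roc_auc >= self.retention_rule]


def _member_probability(learner: FittedLearner, predictors: RasterStack) -> np.ndarray:
    geom = predictors.geometry
    stack = predictors.subset(learner.layer_names)
    arr = stack.as_array()
    valid = stack.joint_valid_mask()
    X = arr.reshape(len(stack), -1).T
    p = np.full(X.shape[0], np.nan)
    flat_ok = valid.ravel()
    if flat_ok.any():
        p[flat_ok] = learner.predict(X[flat_ok])
    return p.reshape(geom.shape)


def _require_layers(ensemble: EnsembleModel, predictors: RasterStack) -> None:
    for learner, _ in ensemble.retained():
        missing = [n for n in learner.layer_names if n not in predictors]
        if missing:
            raise ValueError(f"predictor stack is missing layers {missing}")


def committee_average(ensemble: EnsembleModel, predictors: RasterStack) -> Raster:
    """Fraction of retained members voting presence, each binarised at its own best threshold."""
    members = ensemble.retained()
    if not members:
        raise ValueError("no retained ensemble members")
    _require_layers(ensemble, predictors)
    geom = predictors.geometry
    votes = np.zeros(geom.shape)
    nan_mask = np.zeros(geom.shape, dtype=bool)
    for learner, scores in members:
        p = _member_probability(learner, predictors)
        nan_mask |= np.isnan(p)
        votes += np.where(np.isnan(p), 0.0, (p >= scores.best_threshold).astype(float))
    out = votes / len(members)
    out[nan_mask] = geom.nodata
    return geom.copy_with(out)


def weighted_mean_ensemble(ensemble: EnsembleModel, predictors: RasterStack) -> Raster:
    """TSS-weighted mean of member probabilities (weights normalised to sum 1)."""
    members = ensemble.retained()
    if not members:
        raise ValueError("no retained ensemble members")
    _require_layers(ensemble, predictors)
    weights = np.array([max(s.tss, 0.0) for _, s in members])
    if weights.sum() <= 0:
        raise ValueError("all member TSS weights are non-positive")
    weights = weights / weights.sum()
    geom = predictors.geometry
    out = np.zeros(geom.shape)
    nan_mask = np.zeros(geom.shape, dtype=bool)
    for w, (learner, _) in zip(weights, members):
        p = _member_probability(learner, predictors)
        nan_mask |= np.isnan(p)
        out += w * np.where(np.isnan(p), 0.0, p)
    out[nan_mask] = geom.nodata
    return geom.copy_with(out)


def project(ensemble: EnsembleModel, scenario_stack: RasterStack) -> Raster:
    """Project the ensemble onto a scenario predictor stack.

    The stack must contain every layer the members were trained on
    (scenario-varying climate plus the static layers held fixed across
    scenarios).  Cells with any nodata predictor become nodata.
    """
    _require_layers(ensemble, scenario_stack)
    if ensemble.mode == "weighted_mean":
        return weighted_mean_ensemble(ensemble, scenario_stack)
    return committee_average(ensemble, scenario_stack)


def mess_count(training_ranges: dict[str, tuple[float, float]], scenario_stack: RasterStack) -> Raster:
    """Per-cell count of climate predictors inside their training min/max range.

    A low count flags cells where the projection extrapolates beyond the
    conditions the model was calibrated on.
    """
    if not training_ranges:
        raise ValueError("empty training range table")
    missing = [n for n in training_ranges if n not in scenario_stack]
    if missing:
        raise ValueError(f"scenario stack missing layers {missing}")
    geom = scenario_stack.geometry
    count = np.zeros(geom.shape, dtype=np.int32)
    for name, (lo, hi) in training_ranges.items():
        v = scenario_stack[name].values.astype(float)
        count += ((v >= lo) & (v <= hi)).astype(np.int32)
    return Raster(count, cell_size=geom.cell_size, origin=geom.origin, nodata=-9999)
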