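import numpy as np
import pytest

from circuitshift import sdm
from circuitshift import synthetic as syn
from circuitshift.occurrences import OccurrenceSet
from circuitshift.raster import Raster, RasterStack


@pytest.fixture
def grid():
    return Raster(np.zeros((10, 10)), cell_size=100.0)


class TestGridRecords:
    def test_duplicates_collapse_to_one_record(self, grid):
        x, y = grid.cell_center(4, 4)
        occ = OccurrenceSet.from_records([x, x + 1, x - 2, x + 3, x], [y] * 5, [1] * 5)
        out = sdm.grid_records(occ, grid)
        assert len(out) == 1

    def test_distinct_cells_kept(self, grid):
        pts = [grid.cell_center(r, c) for r, c in [(0, 0), (3, 3), (9, 9)]]
        occ = OccurrenceSet.from_records([p[0] for p in pts], [p[1] for p in pts], [1, 1, 1])
        assert len(sdm.grid_records(occ, grid)) == 3

    def test_pigeonhole_bound(self, grid, rng):
        xs = rng.uniform(0, 1000, size=1000)
        ys = rng.uniform(0, 1000, size=1000)
        occ = OccurrenceSet.from_records(xs, ys, np.ones(1000, dtype=int))
        assert len(sdm.grid_records(occ, grid)) <= 100

    def test_all_outside_raises(self, grid):
        occ = OccurrenceSet.from_records([1e6], [1e6], [1])
        with pytest.raises(ValueError):
            sdm.grid_records(occ, grid)


class TestPseudoAbsences:
    def test_table_ratio_count(self, rng):
        """262 presences at ratio 3 yield 786 pseudo-absences."""
        grid = Raster(np.zeros((40, 40)), cell_size=100.0)
        cells = rng.choice(1600, size=262, replace=False)
        pts = [grid.cell_center(*np.unravel_index(c, (40, 40))) for c in cells]
        pres = OccurrenceSet.from_records([p[0] for p in pts], [p[1] for p in pts], np.ones(262, dtype=int))
        absn = sdm.sample_pseudo_absences(pres, grid, ratio=3, seed=1)
        assert len(absn) == 786

    def test_zero_ratio_gives_empty_set(self, grid):
        x, y = grid.cell_center(1, 1)
        pres = OccurrenceSet.from_records([x], [y], [1])
        assert len(sdm.sample_pseudo_absences(pres, grid, ratio=0, seed=1)) == 0

    def test_absences_avoid_presence_cells(self, grid, rng):
        cells = rng.choice(100, size=10, replace=False)
        pts = [grid.cell_center(*np.unravel_index(c, (10, 10))) for c in cells]
        pres = OccurrenceSet.from_records([p[0] for p in pts], [p[1] for p in pts], np.ones(10, dtype=int))
        absn = sdm.sample_pseudo_absences(pres, grid, ratio=3, seed=7)
        assert len(absn) == 30
        pres_cells = {grid.index_of(x, y) for x, y in zip(pres.x, pres.y)}
        abs_cells = {grid.index_of(x, y) for x, y in zip(absn.x, absn.y)}
        assert pres_cells.isdisjoint(abs_cells)
        assert len(abs_cells) == 30  # without replacement

    def test_reproducible(self, grid):
        x, y = grid.cell_center(5, 5)
        pres = OccurrenceSet.from_records([x], [y], [1])
        a = sdm.sample_pseudo_absences(pres, grid, ratio=3, seed=9)
        b = sdm.sample_pseudo_absences(pres, grid, ratio=3, seed=9)
        np.testing.assert_array_equal(a.x, b.x)

    def test_insufficient_cells_raises(self):
        grid = Raster(np.zeros((2, 2)), cell_size=100.0)
        x, y = grid.cell_center(0, 0)
        pres = OccurrenceSet.from_records([x], [y], [1])
        with pytest.raises(ValueError):
            sdm.sample_pseudo_absences(pres, grid, ratio=5, seed=0)


class TestSpatialBlocks:
    def _records(self, rng, n=500, extent=10000.0):
        xs = rng.uniform(0, extent, size=n)
        ys = rng.uniform(0, extent, size=n)
        return OccurrenceSet.from_records(xs, ys, np.ones(n, dtype=int))

    def test_single_fold_assigns_everyone_fold_one(self, rng):
        recs = self._records(rng, 50)
        fa = sdm.assign_spatial_blocks(recs, (0, 0, 10000, 10000), n_blocks=10, n_folds=1, seed=0)
        assert set(fa.fold_id) == {1}

    def test_clustered_records_share_one_fold(self):
        xs = np.full(20, 5000.0) + np.arange(20)
        ys = np.full(20, 5000.0)
        recs = OccurrenceSet.from_records(xs, ys, np.ones(20, dtype=int))
        fa = sdm.assign_spatial_blocks(recs, (0, 0, 100000, 100000), n_blocks=40, n_folds=1, seed=3)
        assert len(set(fa.block_id)) == 1
        assert len(set(fa.fold_id)) == 1

    def test_every_fold_nonempty_on_uniform_records(self, rng):
        recs = self._records(rng, 500)
        fa = sdm.assign_spatial_blocks(recs, (0, 0, 10000, 10000), n_blocks=40, n_folds=5, seed=9)
        assert set(fa.fold_id) == {1, 2, 3, 4, 5}

    def test_records_inherit_their_blocks_fold(self, rng):
        recs = self._records(rng, 300)
        fa = sdm.assign_spatial_blocks(recs, (0, 0, 10000, 10000), n_blocks=30, n_folds=5, seed=2)
        for b in np.unique(fa.block_id):
            assert len(np.unique(fa.fold_id[fa.block_id == b])) == 1

    def test_occupied_block_count_near_target(self, rng):
        recs = self._records(rng, 2000)
        fa = sdm.assign_spatial_blocks(recs, (0, 0, 10000, 10000), n_blocks=40, n_folds=5, seed=2)
        n_occ = len(np.unique(fa.block_id))
        assert 20 <= n_occ <= 60

    def test_too_few_blocks_for_folds_raises(self):
        recs = OccurrenceSet.from_records([1.0], [1.0], [1])
        with pytest.raises(ValueError):
            sdm.assign_spatial_blocks(recs, (0, 0, 100, 100), n_blocks=5, n_folds=5, seed=0)


class TestFitLogistic:
    def _stack_and_records(self, beta, n, seed, n_rows=60, n_cols=60):
        stack = syn.gen_climate_stack(n_rows, n_cols, 2, 0.0, seed=seed)
        rng = np.random.default_rng(seed + 1)
        arr = stack.as_array()
        eta = beta[0] + beta[1] * arr[0] + (beta[2] * arr[1] if len(beta) > 2 else 0.0)
        p = 1 / (1 + np.exp(-eta))
        y = (rng.random(p.shape) < p).astype(int)
        # subsample n cells
        flat = rng.choice(p.size, size=n, replace=False)
        rows, cols = np.unravel_index(flat, p.shape)
        xs, ys = zip(*[stack.geometry.cell_center(int(r), int(c)) for r, c in zip(rows, cols)])
        recs = OccurrenceSet.from_records(xs, ys, y[rows, cols])
        return stack, recs

    def test_intercept_only_closed_form(self):
        """30 presences / 90 absences with flat predictors: intercept = log(1/3)."""
        stack = RasterStack([Raster(np.zeros((12, 10))), Raster(np.zeros((12, 10)))], ["a", "b"])
        cells = [(r, c) for r in range(12) for c in range(10)]
        pts = [stack.geometry.cell_center(r, c) for r, c in cells]
        y = np.array([1] * 30 + [0] * 90)
        recs = OccurrenceSet.from_records([p[0] for p in pts], [p[1] for p in pts], y)
        learner = sdm.fit_logistic(recs, stack, quadratic=False)
        assert learner.coef[0] == pytest.approx(np.log(30 / 90), abs=1e-6)
        np.testing.assert_allclose(learner.coef[1:], 0.0, atol=1e-6)

    def test_recovers_true_slope(self):
        stack, recs = self._stack_and_records([0.0, 2.0], n=2000, seed=42)
        learner = sdm.fit_logistic(recs, stack, quadratic=False)
        assert abs(learner.coef[1] - 2.0) <= 0.3

    def test_bias_shrinks_with_sample_size(self):
        biases = []
        for n in (500, 5000):
            errs = []
            for seed in (1, 2, 3):
                stack, recs = self._stack_and_records([0.0, 1.5], n=n, seed=seed, n_rows=80, n_cols=80)
                learner = sdm.fit_logistic(recs, stack, quadratic=False)
                errs.append(learner.coef[1] - 1.5)
            biases.append(abs(np.mean(errs)))
        assert biases[1] <= biases[0] + 0.05

    def test_single_class_raises(self):
        stack = RasterStack([Raster(np.zeros((5, 5))), Raster(np.zeros((5, 5)))], ["a", "b"])
        pts = [stack.geometry.cell_center(r, c) for r in range(5) for c in range(5)]
        recs = OccurrenceSet.from_records([p[0] for p in pts], [p[1] for p in pts], np.ones(25, dtype=int))
        with pytest.raises(ValueError):
            sdm.fit_logistic(recs, stack, quadratic=False)

    def test_separation_flagged_and_finite(self, rng):
        vals = np.linspace(-2, 2, 100).reshape(10, 10)
        stack = RasterStack([Raster(vals), Raster(np.zeros((10, 10)))], ["a", "b"])
        pts = [stack.geometry.cell_center(r, c) for r in range(10) for c in range(10)]
        y = (vals.ravel() > 0).astype(int)  # perfectly separable
        recs = OccurrenceSet.from_records([p[0] for p in pts], [p[1] for p in pts], y)
        learner = sdm.fit_logistic(recs, stack, quadratic=False)
        assert learner.separation_flag
        assert np.all(np.isfinite(learner.coef))


class TestEvaluate:
    def test_perfect_separation(self):
        scores = sdm.evaluate(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert scores.tss == pytest.approx(1.0)
        assert scores.roc_auc == pytest.approx(1.0)

    def test_constant_predictions_tie_corrected(self):
        scores = sdm.evaluate(np.full(10, 0.5), np.array([1, 0] * 5))
        assert scores.roc_auc == pytest.approx(0.5)
        assert scores.tss == pytest.approx(0.0)

    def test_known_four_record_auc(self):
        scores = sdm.evaluate(np.array([0.9, 0.8, 0.4, 0.2]), np.array([1, 0, 1, 0]))
        assert scores.roc_auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        truth = rng.integers(0, 2, size=n)
        if truth.sum() in (0, n):
            truth[0] = 1 - truth[0]
        pred = np.round(rng.random(n), 2)  # ties likely
        scores = sdm.evaluate(pred, truth)
        pos = pred[truth == 1]
        neg = pred[truth == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert scores.roc_auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_auc_matches_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, size=200)
        truth[0], truth[1] = 0, 1
        pred = rng.random(200)
        assert sdm.evaluate(pred, truth).roc_auc == pytest.approx(roc_auc_score(truth, pred), abs=1e-12)

    def test_tss_in_range_and_antisymmetric_under_label_flip(self, rng):
        pred = rng.random(80)
        truth = (rng.random(80) < 0.4).astype(int)
        truth[:2] = [0, 1]
        s = sdm.evaluate(pred, truth)
        assert -1 <= s.tss <= 1
        # flipping labels reverses the ranking quality
        s_flip = sdm.evaluate(pred, 1 - truth)
        assert s_flip.roc_auc == pytest.approx(1 - s.roc_auc, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            sdm.evaluate(np.array([0.5, 0.6]), np.array([1, 1]))


def _make_member(threshold, probs_raster, tss=0.8, auc=0.9):
    class _Const(sdm.FittedLearner):
        def __init__(self, vals):
            super().__init__(kind="const", layer_names=["a"])
            self._vals = np.asarray(vals, dtype=float).ravel()

        def predict(self, X):
            # constant per-cell probabilities keyed on the layer value
            return np.interp(X[:, 0], np.arange(len(self._vals)), self._vals)

    learner = _Const(probs_raster)
    scores = sdm.EvaluationScores(tss=tss, roc_auc=auc, best_threshold=threshold)
    return learner, scores


class TestEnsembles:
    @pytest.fixture
    def stack(self):
        # layer values are cell ids so constant learners can look up per-cell probs
        ids = np.arange(16.0).reshape(4, 4)
        return RasterStack([Raster(ids)], ["a"])

    def test_committee_unanimous_vote(self, stack):
        members = [_make_member(0.5, np.full(16, 0.9)) for _ in range(3)]
        ens = sdm.EnsembleModel(members=members, retention_rule=0.7)
        out = sdm.committee_average(ens, stack)
        np.testing.assert_allclose(out.values, 1.0)

    def test_committee_half_vote(self, stack):
        members = [_make_member(0.5, np.full(16, 0.9)), _make_member(0.5, np.full(16, 0.9)),
                   _make_member(0.5, np.full(16, 0.1)), _make_member(0.5, np.full(16, 0.1))]
        ens = sdm.EnsembleModel(members=members, retention_rule=0.7)
        np.testing.assert_allclose(sdm.committee_average(ens, stack).values, 0.5)

    def test_committee_single_member_is_binarised_map(self, stack):
        probs = np.linspace(0, 1, 16)
        ens = sdm.EnsembleModel(members=[_make_member(0.5, probs)], retention_rule=0.7)
        out = sdm.committee_average(ens, stack)
        np.testing.assert_array_equal(out.values.ravel(), (probs >= 0.5).astype(float))

    def test_committee_values_on_member_lattice(self, stack, rng):
        m = 5
        members = [_make_member(0.5, rng.random(16)) for _ in range(m)]
        ens = sdm.EnsembleModel(members=members, retention_rule=0.0)
        out = sdm.committee_average(ens, stack)
        lattice = np.arange(m + 1) / m
        assert np.all(np.isin(out.values.ravel(), lattice))

    def test_retention_rule_excludes_weak_members(self, stack):
        good = _make_member(0.5, np.full(16, 0.9), auc=0.9)
        bad = _make_member(0.5, np.full(16, 0.1), auc=0.5)
        ens = sdm.EnsembleModel(members=[good, bad], retention_rule=0.7)
        np.testing.assert_allclose(sdm.committee_average(ens, stack).values, 1.0)

    def test_zero_retained_members_raises(self, stack):
        ens = sdm.EnsembleModel(members=[_make_member(0.5, np.full(16, 0.9), auc=0.5)], retention_rule=0.7)
        with pytest.raises(ValueError):
            sdm.committee_average(ens, stack)

    def test_weighted_mean_arithmetic(self, stack):
        a = _make_member(0.5, np.full(16, 1.0), tss=3.0)
        b = _make_member(0.5, np.full(16, 0.0), tss=1.0)
        ens = sdm.EnsembleModel(members=[a, b], retention_rule=0.0)
        np.testing.assert_allclose(sdm.weighted_mean_ensemble(ens, stack).values, 0.75)

    def test_weighted_mean_equal_weights(self, stack):
        a = _make_member(0.5, np.full(16, 0.2), tss=0.5)
        b = _make_member(0.5, np.full(16, 0.8), tss=0.5)
        ens = sdm.EnsembleModel(members=[a, b], retention_rule=0.0)
        np.testing.assert_allclose(sdm.weighted_mean_ensemble(ens, stack).values, 0.5)


class TestProjection:
    def test_shifted_climate_raises_mean_suitability_under_positive_slope(self):
        stack = syn.gen_climate_stack(40, 40, 2, 0.0, seed=5)
        model = syn.TrueModel([0.0, 2.0, 0.0])
        occ = syn.gen_occurrences(model, stack, 200, seed=6)
        absn = sdm.sample_pseudo_absences(occ, stack.geometry, ratio=3, seed=7)
        learner = sdm.fit_logistic(occ.concat(absn), stack, quadratic=False)
        scores = sdm.EvaluationScores(tss=0.5, roc_auc=0.9, best_threshold=0.5)
        ens = sdm.EnsembleModel(members=[(learner, scores)], retention_rule=0.7, mode="weighted_mean")
        base = sdm.project(ens, stack)
        shifted = syn.gen_climate_stack(30, 30, 2, [1.0, 0.0], seed=5)
        up = sdm.project(ens, shifted)
        assert learner.coef[1] > 0
        assert up.values.mean() > base.values.mean()

    def test_missing_layer_raises(self):
        stack = syn.gen_climate_stack(10, 10, 2, 0.0, seed=5)
        learner = sdm.LogisticLearner(kind="glm", layer_names=["bio1", "bio9"], coef=np.zeros(3))
        ens = sdm.EnsembleModel(members=[(learner, sdm.EvaluationScores(0.5, 0.9, 0.5))])
        with pytest.raises(ValueError):
            sdm.project(ens, stack)


class TestMessCount:
    def test_training_stack_all_in_range(self):
        stack = syn.gen_climate_stack(12, 12, 3, 0.0, seed=2)
        ranges = {n: (float(stack[n].values.min()), float(stack[n].values.max())) for n in stack.names}
        out = sdm.mess_count(ranges, stack)
        np.testing.assert_array_equal(out.values, 3)

    def test_fully_shifted_layer_reduces_count_by_one(self):
        stack = syn.gen_climate_stack(12, 12, 3, 0.0, seed=2)
        ranges = {n: (float(stack[n].values.min()), float(stack[n].values.max())) for n in stack.names}
        shift = float(stack["bio1"].values.max() - stack["bio1"].values.min()) + 1.0
        shifted = syn.gen_climate_stack(12, 12, 3, [shift, 0.0, 0.0], seed=2)
        out = sdm.mess_count(ranges, shifted)
        np.testing.assert_array_equal(out.values, 2)

    def test_matches_brute_force_oracle(self, rng):
        stack = syn.gen_climate_stack(15, 15, 4, [0.5, -0.3, 0.0, 1.2], seed=3)
        train = syn.gen_climate_stack(15, 15, 4, 0.0, seed=3)
        ranges = {n: (float(train[n].values.min()), float(train[n].values.max())) for n in train.names}
        out = sdm.mess_count(ranges, stack)
        expected = np.zeros((15, 15), dtype=int)
        for r in range(15):
            for c in range(15):
                for n, (lo, hi) in ranges.items():
                    v = stack[n].values[r, c]
                    expected[r, c] += int(lo <= v <= hi)
        np.testing.assert_array_equal(out.values, expected)

    def test_empty_range_table_raises(self):
        stack = syn.gen_climate_stack(5, 5, 2, 0.0, seed=1)
        with pytest.raises(ValueError):
            sdm.mess_count({}, stack)
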