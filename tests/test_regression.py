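"""MLP training/prediction, fold construction, scenario assembly."""

import numpy as np
import pytest

from emgkin import regression as rg
from emgkin.features import WindowSpec


def _linear_toy(n=400, seed=0):
    """Targets exactly linear in one feature; the rest is noise features."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 10))
    y = 12.0 * x[:, 0] + 5.0
    return x, y


class TestTrainPredict:
    def test_linear_map_fit_closely(self):
        x, y = _linear_toy()
        model = rg.train_mlp(x, y, dof=1, seed=0)
        pred = rg.predict(model, x)
        ss_res = np.sum((pred - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1.0  # residual RMS < 1 deg

    def test_same_seed_identical_weights(self):
        x, y = _linear_toy()
        m1 = rg.train_mlp(x, y, dof=1, seed=7)
        m2 = rg.train_mlp(x, y, dof=1, seed=7)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_different_seed_different_weights(self):
        x, y = _linear_toy()
        m1 = rg.train_mlp(x, y, dof=1, seed=7)
        m2 = rg.train_mlp(x, y, dof=1, seed=8)
        assert not np.array_equal(m1.w1, m2.w1)

    def test_constant_targets_degenerate_model(self):
        x, _ = _linear_toy()
        model = rg.train_mlp(x, np.full(x.shape[0], 42.0), dof=1, seed=0)
        assert model.degenerate_constant == 42.0
        assert np.all(rg.predict(model, x[:5]) == 42.0)

    def test_zero_variance_feature_column_guarded(self):
        x, y = _linear_toy()
        x[:, 3] = 1.0
        model = rg.train_mlp(x, y, dof=1, seed=0)
        assert np.all(np.isfinite(rg.predict(model, x)))

    def test_dimension_mismatch_rejected(self):
        x, y = _linear_toy()
        model = rg.train_mlp(x, y, dof=1, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            rg.predict(model, x[:, :5])

    def test_non_finite_features_rejected(self):
        x, y = _linear_toy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            rg.train_mlp(x, y, dof=1, seed=0)

    def test_row_permutation_permutes_outputs(self):
        x, y = _linear_toy()
        model = rg.train_mlp(x, y, dof=1, seed=0)
        perm = np.random.default_rng(1).permutation(x.shape[0])
        np.testing.assert_allclose(rg.predict(model, x[perm]),
                                   rg.predict(model, x)[perm])

    def test_dof_column_selection(self):
        x, y = _linear_toy()
        y3 = np.column_stack([np.zeros_like(y), np.zeros_like(y), y])
        model = rg.train_mlp(x, y3, dof=3, seed=0)
        assert model.dof == 3
        pred = rg.predict(model, x)
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_save_load_round_trip(self, tmp_path):
        x, y = _linear_toy()
        model = rg.train_mlp(x, y, dof=2, seed=0)
        rg.save_model(tmp_path / "m.json", model)
        back = rg.load_model(tmp_path / "m.json")
        np.testing.assert_allclose(rg.predict(back, x), rg.predict(model, x))


class TestFolds:
    LENGTHS = {("POS1", 1): 1621, ("POS1", 2): 900, ("POS2", 1): 1621,
               ("POS2", 2): 900}

    def test_block_sizes_balanced(self):
        folds = rg.make_folds({("POS1", 1): 1621}, k=5, seed=0, guard=0)
        sizes = sorted(len(f.test[("POS1", 1)]) for f in folds)
        assert sizes == [324, 324, 324, 324, 325]

    def test_test_blocks_partition_each_run(self):
        folds = rg.make_folds(self.LENGTHS, k=5, seed=3, guard=0)
        for key, n in self.LENGTHS.items():
            allidx = np.concatenate([f.test[key] for f in folds])
            assert len(allidx) == n
            assert len(np.unique(allidx)) == n

    def test_blocks_contiguous(self):
        folds = rg.make_folds(self.LENGTHS, k=5, seed=3, guard=0)
        for f in folds:
            for key in self.LENGTHS:
                idx = f.test[key]
                assert np.all(np.diff(idx) == 1)

    def test_deterministic_given_seed(self):
        a = rg.make_folds(self.LENGTHS, k=5, seed=9)
        b = rg.make_folds(self.LENGTHS, k=5, seed=9)
        for fa, fb in zip(a, b):
            for key in self.LENGTHS:
                np.testing.assert_array_equal(fa.test[key], fb.test[key])
        c = rg.make_folds(self.LENGTHS, k=5, seed=10)
        assert any(not np.array_equal(a[0].test[k], c[0].test[k])
                   for k in self.LENGTHS)

    def test_too_short_run_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            rg.make_folds({("POS1", 1): 20}, k=5, guard=2)

    def test_no_training_window_span_overlaps_test_span(self):
        """Guard band: with 102/41 windowing, train/test sample spans disjoint."""
        spec = WindowSpec()
        win, step = spec.window_samples(1024.0), spec.step_samples(1024.0)
        folds = rg.make_folds({("POS1", 1): 500}, k=5, seed=1, spec=spec)
        for f in folds:
            test_spans = {(i * step, i * step + win) for i in f.test[("POS1", 1)]}
            lo = min(s for s, _ in test_spans)
            hi = max(e for _, e in test_spans)
            for i in f.train[("POS1", 1)]:
                s, e = i * step, i * step + win
                assert e <= lo or s >= hi

    def test_train_fraction_near_four_fifths(self):
        folds = rg.make_folds({("POS1", 1): 1621}, k=5, seed=0, guard=0)
        for f in folds:
            frac = len(f.train[("POS1", 1)]) / 1621
            assert frac == pytest.approx(0.8, abs=0.01)


class TestAssemble:
    def _folds(self):
        lengths = {(p, r): 200 for p in ("POS1", "POS2", "POS3")
                   for r in range(1, 8)}
        return rg.make_folds(lengths, k=5, seed=0)

    def test_scenario_run_selection(self):
        assert rg.SCENARIO_RUNS["DoF12"] == (1, 2)
        assert rg.SCENARIO_RUNS["DoF123"] == (1, 2, 3, 4, 5, 6, 7)
        folds = self._folds()
        split = rg.assemble("DoF12", ("POS1",), folds[0])
        assert {k[1] for k in split.train} == {1, 2}
        assert {k[0] for k in split.train} == {"POS1"}

    def test_pooled_training_has_three_positions(self):
        folds = self._folds()
        single = rg.assemble("DoF13", ("POS2",), folds[0])
        pooled = rg.assemble("DoF13", ("POS1", "POS2", "POS3"), folds[0])
        n_single = sum(len(v) for v in single.train.values())
        n_pooled = sum(len(v) for v in pooled.train.values())
        assert n_pooled == pytest.approx(3 * n_single, abs=6)

    def test_inter_position_tests_use_full_runs(self):
        folds = self._folds()
        split = rg.assemble("DoF23", ("POS1",), folds[0])
        assert set(split.test_inter) == {"POS2", "POS3"}
        for sel in split.test_inter.values():
            assert all(len(idx) == 200 for idx in sel.values())

    def test_intra_tests_are_fold_blocks(self):
        folds = self._folds()
        split = rg.assemble("DoF23", ("POS1",), folds[0])
        for key, idx in split.test_intra["POS1"].items():
            np.testing.assert_array_equal(idx, folds[0].test[key])

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            rg.assemble("DoF1", ("POS1",), self._folds()[0])

    def test_empty_training_positions_rejected(self):
        with pytest.raises(ValueError):
            rg.assemble("DoF12", (), self._folds()[0])
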