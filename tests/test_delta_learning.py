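"""Delta-rule training against a noisy, threshold-spoiled unit."""

import numpy as np
import pytest

from srclassify.delta_learning import (
    LearningConfig,
    LearningResult,
    delta_update,
    learning_resonance_scan,
    train,
    weight_error,
)


class TestDeltaUpdate:
    def test_no_error_no_change(self):
        w = np.array([0.4, 0.6])
        out = delta_update(w, np.array([0.3, 0.9]), 1, 1, alpha=0.01)
        np.testing.assert_array_equal(out, w)

    def test_printed_rule(self):
        out = delta_update(
            np.array([0.5, 0.5]), np.array([0.5, 0.2]), 1, 0, alpha=0.01
        )
        np.testing.assert_allclose(out, [0.505, 0.502])

    def test_overprediction_decreases_weights(self):
        w = np.array([0.5, 0.5])
        out = delta_update(w, np.array([0.4, 0.0]), 0, 1, alpha=0.05)
        assert np.all(out <= w)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            delta_update(np.ones(2), np.ones(3), 1, 0, 0.01)


class TestWeightError:
    def test_values_and_symmetry(self):
        assert weight_error([0.7, 0.7], [0.7, 0.7]) == 0.0
        assert weight_error([0.7, 0.7], [0.4, 0.3]) == pytest.approx(0.5)
        assert weight_error([0.4, 0.3], [0.7, 0.7]) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weight_error([1.0], [1.0, 2.0])


class TestTrain:
    def test_one_pass_matches_hand_computation(self):
        """One noiseless pass over a hand-enumerated 3-example set,
        with within-pass sequential updates, reproduced by hand."""
        X = np.array([[0.8, 0.9], [0.2, 0.1], [0.9, 0.9]])
        true_w = [0.7, 0.7]
        cfg = LearningConfig(
            alpha=0.1, T_unspoiled=1.0, T_spoiled=1.0, sigma2=0.0,
            max_passes=1, train_size=3, seed=0, init_weights=(0.5, 0.5),
            error_threshold=0.0,
        )
        res = train(true_w, cfg, training_inputs=X)
        # targets: 0.7*1.7=1.19>1 -> 1; 0.7*0.3=0.21 -> 0; 0.7*1.8=1.26 -> 1
        # step 1: pred 0.5*1.7=0.85<=1 -> 0; delta=1; w += 0.1*(0.8,0.9)
        w = np.array([0.58, 0.59])
        # step 2: pred 0.58*0.2+0.59*0.1=0.175 -> 0; delta=0
        # step 3: pred 0.58*0.9+0.59*0.9=1.053>1 -> 1; delta=0
        np.testing.assert_allclose(res.w_learned, w, atol=1e-12)
        assert res.passes_used == 1

    def test_equivalent_formulations_agree(self):
        """The recursive weight-update form and the explicit
        delta-per-example form are the same rule."""
        X = np.array([[0.8, 0.9], [0.2, 0.1], [0.9, 0.9]])
        cfg = LearningConfig(
            alpha=0.1, max_passes=1, train_size=3, seed=0,
            error_threshold=0.0,
        )
        res = train([0.7, 0.7], cfg, training_inputs=X)
        w = np.array([0.5, 0.5])
        for x in X:
            target = int(x @ np.array([0.7, 0.7]) > 1.0)
            pred = int(x @ w > 1.0)
            w = delta_update(w, x, target, pred, 0.1)
        np.testing.assert_allclose(res.w_learned, w, atol=1e-12)

    def test_noiseless_convergence_matches_reference_loop(self):
        """Noiseless, unspoiled training converges near the true weights
        and agrees exactly with a plain reimplementation of the loop
        consuming the same random streams."""
        true_w = np.array([0.7, 0.7])
        cfg = LearningConfig(T_spoiled=1.0, sigma2=0.0, seed=14)
        res = train(true_w, cfg)
        assert res.weight_error < 0.05

        # independent straightforward loop, same stream consumption
        rng = np.random.default_rng(14)
        X = rng.uniform(size=(1, cfg.train_size, 2))[0]
        targets = (X @ true_w > cfg.T_unspoiled).astype(float)
        w = np.array([0.5, 0.5])
        for _ in range(cfg.max_passes):
            rng.standard_normal((cfg.train_size, 1, 2))  # unused noise draw
            abs_delta = 0.0
            for j in range(cfg.train_size):
                pred = float(X[j] @ w > cfg.T_spoiled)
                delta = targets[j] - pred
                w = w + cfg.alpha * delta * X[j]
                abs_delta += abs(delta)
            if abs_delta / cfg.train_size < cfg.error_threshold:
                break
        np.testing.assert_allclose(res.w_learned, w, atol=1e-12)

    def test_deterministic_for_identical_config(self):
        cfg = LearningConfig(T_spoiled=1.1, sigma2=0.05, seed=5,
                             max_passes=50)
        r1 = train([0.7, 0.7], cfg)
        r2 = train([0.7, 0.7], cfg)
        np.testing.assert_array_equal(r1.w_learned, r2.w_learned)
        assert r1.passes_used == r2.passes_used
        np.testing.assert_array_equal(r1.error_history, r2.error_history)

    def test_zero_learning_rate_freezes_weights(self):
        cfg = LearningConfig(alpha=0.0, T_spoiled=1.1, sigma2=0.1, seed=2,
                             max_passes=20, error_threshold=0.0)
        res = train([0.7, 0.7], cfg)
        np.testing.assert_array_equal(res.w_learned, [0.5, 0.5])
        assert res.weight_error == pytest.approx(
            weight_error([0.7, 0.7], [0.5, 0.5])
        )


class TestResonanceScan:
    @pytest.mark.parametrize("true_w", [(0.7, 0.7), (0.6, 0.8)])
    def test_interior_minimum_exists(self, true_w):
        """Against a spoiled threshold, some intermediate noise beats
        both zero and strong noise (learning resonance), also when the
        two weights differ."""
        cfg = LearningConfig(T_spoiled=1.1, seed=31)
        grid = np.array([0.0, 0.05, 1.0])
        res = learning_resonance_scan(true_w, cfg, grid, replicates=12)
        err = res.table["mean_error"].to_numpy()
        assert err[1] < err[0]
        assert err[2] > err[1]
        assert res.sigma2_opt == pytest.approx(0.05)

    def test_strong_noise_worse_than_minimum(self):
        cfg = LearningConfig(T_spoiled=1.1, seed=8, max_passes=400)
        res = learning_resonance_scan(
            [0.7, 0.7], cfg, np.array([0.0, 0.06, 1.0]), replicates=8
        )
        t = res.table
        assert t.loc[t["sigma2"] == 1.0, "mean_error"].iloc[0] > res.min_error

    def test_replicate_averaging_shrinks_standard_error(self):
        cfg = LearningConfig(T_spoiled=1.1, seed=19, max_passes=300)
        grid = np.array([0.08])
        se = {}
        for reps in (5, 45):
            res = learning_resonance_scan([0.7, 0.7], cfg, grid, reps)
            se[reps] = res.table["se_error"].iloc[0]
        # 9x the replicates ~ 3x smaller SE; allow wide stochastic slack
        assert se[45] < se[5]

    def test_scan_deterministic(self):
        cfg = LearningConfig(T_spoiled=1.1, seed=4, max_passes=100)
        grid = np.array([0.0, 0.1])
        r1 = learning_resonance_scan([0.7, 0.7], cfg, grid, replicates=3)
        r2 = learning_resonance_scan([0.7, 0.7], cfg, grid, replicates=3)
        assert r1.table.equals(r2.table)
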