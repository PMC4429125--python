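"""Toggle-switch circuit: topology, integration, classification."""

import numpy as np
import pytest

from srclassify.grn_circuit import (
    DegenerateClassifierWarning,
    GRNState,
    GRNTopology,
    IntegrationInstabilityError,
    IntegrationSettings,
    NonConvergenceError,
    build_toggle_classifier,
    classify_grid,
    classify_inputs,
    empirical_boundary,
    sigmoid_response,
    simulate,
)


class TestTopology:
    def test_unit_matrix_structure(self):
        """The regulation matrix with unit strengths: threshold gene 0
        represses the output and activates its partner; inputs do the
        reverse; genes 3/4 self-promote and mutually repress."""
        top = build_toggle_classifier(1.0, 1.0)
        expected = np.array(
            [
                [0, 0, 0, -1, 1],
                [0, 0, 0, 1, -1],
                [0, 0, 0, 1, -1],
                [0, 0, 0, 1, -1],
                [0, 0, 0, -1, 1],
            ],
            dtype=float,
        )
        np.testing.assert_array_equal(top.A, expected)

    def test_weight_substitution(self):
        top = build_toggle_classifier(0.7, 0.7)
        assert top.A[1, 3] == 0.7 and top.A[1, 4] == -0.7
        assert top.A[2, 3] == 0.7 and top.A[2, 4] == -0.7
        assert top.input_weights == (0.7, 0.7)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w1": 0.0, "w2": 1.0},
            {"w1": 1.0, "w2": -0.5},
            {"w1": 1.0, "w2": 1.0, "self_strength": 0.0},
            {"w1": 1.0, "w2": 1.0, "threshold_strength": -1.0},
        ],
    )
    def test_nonpositive_strengths_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_toggle_classifier(**kwargs)


class TestSigmoid:
    def test_midpoint_and_complement(self):
        assert sigmoid_response(0.0, 40.0) == 0.5
        for x in [0.03, 0.4, 2.0]:
            total = sigmoid_response(x, 40.0) + sigmoid_response(-x, 40.0)
            assert total == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert sigmoid_response(0.1, 40.0) == pytest.approx(
            1 / (1 + np.exp(-4)), rel=1e-12
        )

    def test_overflow_safe(self):
        assert sigmoid_response(1e4, 40.0) == 1.0
        assert sigmoid_response(-1e4, 40.0) == 0.0


class TestSimulate:
    def test_fixed_point_stays_constant(self):
        """With no regulation and zero offsets, F ≡ 1/2, so m = p = 1/2
        is an exact fixed point of the dynamics."""
        top = GRNTopology(A=np.zeros((5, 5)), theta=np.zeros(5))
        init = GRNState(m=np.full(5, 0.5), p=np.full(5, 0.5))
        traj = simulate(top, init, duration=5.0, dt=0.01)
        np.testing.assert_allclose(traj.m, 0.5, atol=1e-12)
        np.testing.assert_allclose(traj.p, 0.5, atol=1e-12)

    def test_boundedness_from_random_initial_states(self, unit_topology, rng):
        dt = 0.01
        for _ in range(5):
            init = GRNState(m=rng.uniform(size=5), p=rng.uniform(size=5))
            traj = simulate(unit_topology, init, duration=40.0, dt=dt)
            for arr in (traj.m, traj.p):
                assert arr.min() >= -10 * dt
                assert arr.max() <= 1 + 10 * dt

    def test_instability_raises(self):
        top = build_toggle_classifier(1.0, 1.0, gamma=50.0)
        init = GRNState(m=np.full(5, 0.9), p=np.full(5, 0.1))
        with pytest.raises(IntegrationInstabilityError):
            simulate(top, init, duration=20.0, dt=0.5)

    def test_rk4_empirical_order(self, unit_topology):
        """Halving dt on a smooth stretch shrinks the error ~16-fold."""
        m0 = np.array([0.5, 0.6, 0.4, 0.3, 0.7])
        init = GRNState(m=m0, p=m0 * 0.9 + 0.05)
        ref = simulate(unit_topology, init, 5.0, 0.0005).final().p[3]
        errs = [
            abs(simulate(unit_topology, init, 5.0, dt).final().p[3] - ref)
            for dt in (0.04, 0.02, 0.01)
        ]
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) > 3.5

    def test_bistability(self, unit_topology):
        """With silent inputs the toggle holds whichever state it starts
        in: two distinct stable fixed points."""
        finals = []
        for p3, p4 in [(1.0, 0.0), (0.0, 1.0)]:
            m = np.array([0.0, 0.0, 0.0, p3, p4])
            traj = simulate(
                unit_topology, GRNState(m=m, p=m.copy()), 50.0, 0.01
            )
            finals.append(traj.final().p[3:5])
        assert finals[0][0] > 0.95 and finals[0][1] < 0.05
        assert finals[1][0] < 0.05 and finals[1][1] > 0.95

    def test_invalid_dt_rejected(self, unit_topology):
        init = GRNState(m=np.full(5, 0.5), p=np.full(5, 0.5))
        with pytest.raises(ValueError):
            simulate(unit_topology, init, duration=1.0, dt=2.0)


class TestClassification:
    def test_corner_inputs(self, unit_topology, fast_settings):
        assert classify_inputs(unit_topology, 0, 0, 0.5, fast_settings) == 0
        assert classify_inputs(unit_topology, 1, 1, 0.5, fast_settings) == 1

    def test_monotone_in_each_input(self, unit_topology, fast_settings):
        g = np.linspace(0, 1, 12)
        X1, X2 = np.meshgrid(g, g, indexing="ij")
        out, _, _ = classify_grid(
            unit_topology, X1.ravel(), X2.ravel(), 0.5, fast_settings
        )
        out = out.reshape(12, 12)
        assert np.all(np.diff(out, axis=0) >= 0)
        assert np.all(np.diff(out, axis=1) >= 0)

    def test_vanishing_second_weight_ignores_x2(self, fast_settings):
        top = build_toggle_classifier(1.0, 1e-6)
        g = np.linspace(0, 1, 10)
        X1, X2 = np.meshgrid(g, g, indexing="ij")
        out, _, _ = classify_grid(
            top, X1.ravel(), X2.ravel(), 0.3, fast_settings
        )
        out = out.reshape(10, 10)
        # every row (fixed x1) is constant across x2
        assert np.all(out == out[:, :1])

    def test_nonconvergence_reported_with_final_value(self, unit_topology):
        short = IntegrationSettings(duration=0.5, dt=0.01, check_interval=0.5)
        with pytest.raises(NonConvergenceError) as err:
            classify_inputs(unit_topology, 0.4, 0.4, 0.5, short)
        assert 0.0 <= err.value.final_value <= 1.0

    def test_out_of_range_inputs_rejected(self, unit_topology):
        with pytest.raises(ValueError):
            classify_inputs(unit_topology, 1.2, 0.5, 0.5)


class TestEmpiricalBoundary:
    def test_symmetric_weights_give_slope_minus_one(
        self, unit_topology, fast_settings
    ):
        fit = empirical_boundary(unit_topology, 0.5, 30, fast_settings)
        assert fit.slope == pytest.approx(-1.0, abs=0.05)
        assert fit.residual < 0.05
        assert not fit.is_degenerate

    def test_threshold_expression_shifts_boundary_out(self, unit_topology,
                                                      fast_settings):
        """More threshold-gene expression pushes the separating line away
        from the origin: the effective threshold grows with it."""
        f_low = empirical_boundary(unit_topology, 0.3, 30, fast_settings)
        f_high = empirical_boundary(unit_topology, 0.6, 30, fast_settings)
        assert f_high.intercept > f_low.intercept + 0.1
        assert f_high.t_eff > f_low.t_eff

    def test_degenerate_classifier_warns(self, fast_settings):
        # weights too small to ever reach the effective threshold
        top = build_toggle_classifier(0.3, 0.3)
        with pytest.warns(DegenerateClassifierWarning):
            fit = empirical_boundary(top, 1.0, 12, fast_settings)
        assert fit.is_degenerate

    def test_small_resolution_rejected(self, unit_topology):
        with pytest.raises(ValueError):
            empirical_boundary(unit_topology, 0.5, 5)
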