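"""Kinetic-scheme construction, Laplace reduction and simulation."""
import numpy as np
import pytest

from kinfer.errors import InfeasibleSchemeError, MalformedSchemeError
from kinfer.kinetics import (KineticScheme, Transition, convert_to_scheme,
                             scheme_from_parameters, scheme_to_tf,
                             simulate_scheme)
from kinfer.transfer import FirstOrderProcess, combine, make_first_order
from kinfer.classify import ClassificationResult

from conftest import feasible_grid


class TestClosedForms:
    def test_feedback_rates(self):
        s = scheme_from_parameters("feedback", -5, 5, 2, 200)
        assert s.sigma["sigma1"] == pytest.approx(0.2)
        assert s.sigma["sigma2"] == pytest.approx(0.01)
        assert s.sigma["sigma3"] == pytest.approx(0.005)
        assert s.gamma == pytest.approx(-5.0)

    def test_parallel_subtraction_rates(self):
        s = scheme_from_parameters("parallel_sub", -5, 5, 3, 100)
        assert s.sigma["sigma1"] == pytest.approx(0.2)
        assert s.sigma["sigma3"] == pytest.approx(4.1237e-3, rel=1e-4)
        assert s.sigma["sigma2"] == pytest.approx(5.8763e-3, rel=1e-4)
        assert s.gamma == pytest.approx(-0.970, abs=5e-4)
        assert s.n_states == 4

    def test_first_order_rates(self):
        s = scheme_from_parameters("first_order", -1.0, 5.0)
        assert s.sigma["sigma1"] == pytest.approx(0.2)
        assert s.gamma == pytest.approx(-1.0)
        assert s.n_states == 2

    def test_negative_feedback_gain_infeasible(self):
        with pytest.raises(InfeasibleSchemeError):
            scheme_from_parameters("feedback", -5, 5, -2, 200)

    def test_opposite_sign_addition_infeasible(self):
        with pytest.raises(InfeasibleSchemeError):
            scheme_from_parameters("parallel_add", -5, 5, 3, 100)


class TestSchemeToTF:
    def test_first_order_laplace_form(self):
        # G_kin = gamma sigma1 / (s + sigma1)
        s = scheme_from_parameters("first_order", 2.0, 50.0)
        G = scheme_to_tf(s)
        assert np.allclose(G.num, [2.0 * 0.02])
        assert np.allclose(G.den, [1.0, 0.02])

    def test_feedback_round_trip_exact(self):
        s = scheme_from_parameters("feedback", -5, 5, 2, 200)
        G_kin = scheme_to_tf(s)
        G = combine(FirstOrderProcess(-5, 5), FirstOrderProcess(2, 200), "feedback")
        assert np.allclose(G_kin.num, G.num, rtol=1e-9)
        assert np.allclose(G_kin.den, G.den, rtol=1e-9)

    @pytest.mark.parametrize("config,k_a,k_b,tau_a,tau_b", [
        pt for pt in feasible_grid()[::7]    # stride keeps this a spot check
    ])
    def test_round_trip_across_grid(self, config, k_a, k_b, tau_a, tau_b):
        s = scheme_from_parameters(config, k_a, tau_a, k_b, tau_b)
        G_kin = scheme_to_tf(s)
        if config == "first_order":
            G = make_first_order(k_a, tau_a)
        else:
            mode = "parallel" if config.startswith("parallel") else config
            G = combine(FirstOrderProcess(k_a, tau_a),
                        FirstOrderProcess(k_b, tau_b), mode)
        width = max(len(G.num), len(G_kin.num))
        num_a = np.pad(G_kin.num, (width - len(G_kin.num), 0))
        num_b = np.pad(G.num, (width - len(G.num), 0))
        assert np.allclose(num_a, num_b, rtol=1e-8, atol=1e-12)
        assert np.allclose(G_kin.den, G.den, rtol=1e-8)

    def test_missing_transition_is_singular(self):
        s = KineticScheme(states=("S1", "S2", "S3"),
                          transitions=(Transition(0, 1, 0.2),),
                          observable=1, gamma=-1.0, configuration="cascade")
        with pytest.raises(MalformedSchemeError):
            scheme_to_tf(s)


class TestConvert:
    def test_classification_to_scheme(self):
        G = combine(FirstOrderProcess(-5, 5), FirstOrderProcess(2, 200), "feedback")
        res = ClassificationResult(configuration="feedback",
                                   recovered=(-5.0, 2.0, 5.0, 200.0))
        s = convert_to_scheme(G, res)
        assert s.configuration == "feedback"
        assert s.sigma["sigma1"] == pytest.approx(0.2)

    def test_unknown_configuration_rejected(self):
        G = make_first_order(1, 5)
        res = ClassificationResult(configuration="higher_order")
        with pytest.raises(Exception):
            convert_to_scheme(G, res)


class TestSimulate:
    def test_first_order_step_closed_form(self):
        s = scheme_from_parameters("first_order", -1.0, 5.0)
        traj = simulate_scheme(s, step_time=0.0, duration=60.0, Ts=0.05)
        expected = 1.0 - np.exp(-0.2 * traj.t)
        assert np.allclose(traj.z[1], expected, atol=1e-9)
        assert traj.y[-1] == pytest.approx(-1.0, abs=1e-4)

    def test_feedback_final_value(self):
        # final-value theorem: y(inf) = G(0) = b_a w_b / (w_a (w_b + b_b))
        s = scheme_from_parameters("feedback", -5, 5, 2, 200)
        traj = simulate_scheme(s, step_time=0.0, duration=2500.0, Ts=0.5)
        assert traj.y[-1] == pytest.approx(-5.0 / 3.0, rel=1e-4)

    def test_subtraction_pool_conservation(self):
        s = scheme_from_parameters("parallel_sub", -5, 5, 3, 100)
        traj = simulate_scheme(s, step_time=30.0, duration=700.0, Ts=0.25)
        u = np.where(traj.t >= 30.0, 1.0, 0.0)
        pool = traj.z[list(s.mass_pool)].sum(axis=0)
        assert np.max(np.abs(pool - u)) < 1e-9

    def test_occupancy_bounds_without_inversion(self):
        s = scheme_from_parameters("feedback", -5, 5, 2, 200)
        traj = simulate_scheme(s, step_time=10.0, duration=1500.0, Ts=0.5)
        assert traj.z.min() > -1e-9
        assert traj.z.max() < 1.0 + 1e-9
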