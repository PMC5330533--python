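"""Configuration decision flow and the dual constrained optimizations."""
import numpy as np
import pytest

from kinfer import Bounds, ClassifyOptions, classify, solve_config_problem
from kinfer.errors import InvalidParameterError
from kinfer.transfer import FirstOrderProcess, RationalTF, combine, make_first_order

from conftest import CAPTION_BOUNDS


@pytest.fixture(scope="module")
def G_parallel():
    return combine(FirstOrderProcess(-5, 5), FirstOrderProcess(3, 100), "parallel")


@pytest.fixture(scope="module")
def G_feedback():
    return combine(FirstOrderProcess(-5, 5), FirstOrderProcess(2, 200), "feedback")


class TestSolveConfigProblem:
    def test_parallel_truth_recovered(self, G_parallel):
        params, cost = solve_config_problem(G_parallel, "parallel", CAPTION_BOUNDS)
        assert cost < 1e-9
        assert params == pytest.approx((-5.0, 3.0, 5.0, 100.0), rel=1e-4)

    def test_feedback_excluded_by_speed_prior(self, G_parallel):
        # a feedback realization of this G needs tau_b at the zero (242.5 ms);
        # a prior that confines the slow process near 100 ms excludes it
        bounds = Bounds.around_processes(5.0, 100.0)
        _, cost = solve_config_problem(G_parallel, "feedback", bounds)
        assert cost > 1e-4

    def test_feedback_truth_recovered(self, G_feedback):
        params, cost = solve_config_problem(G_feedback, "feedback", CAPTION_BOUNDS)
        assert cost < 1e-9
        assert params == pytest.approx((-5.0, 2.0, 5.0, 200.0), rel=1e-4)

    def test_requires_two_pole_G(self):
        with pytest.raises(InvalidParameterError):
            solve_config_problem(make_first_order(1, 5), "parallel", CAPTION_BOUNDS)


class TestClassify:
    def test_parallel_demo(self, G_parallel):
        res = classify(G_parallel, CAPTION_BOUNDS)
        assert res.configuration == "parallel_sub"
        assert res.recovered == pytest.approx((-5.0, 3.0, 5.0, 100.0), rel=1e-3)

    def test_feedback_demo(self, G_feedback):
        res = classify(G_feedback, CAPTION_BOUNDS)
        assert res.configuration == "feedback"
        assert res.recovered == pytest.approx((-5.0, 2.0, 5.0, 200.0), rel=1e-3)

    def test_cascade_routed_before_optimization(self):
        G = combine(FirstOrderProcess(-1, 5), FirstOrderProcess(1, 100), "cascade")
        res = classify(G, CAPTION_BOUNDS)
        assert res.configuration == "cascade"
        assert res.f_valp is None and res.f_valf is None

    def test_first_order_branch(self):
        res = classify(make_first_order(7, 50), CAPTION_BOUNDS)
        assert res.configuration == "first_order"
        assert res.recovered[0] == pytest.approx(7.0)

    def test_three_pole_is_higher_order(self):
        G = RationalTF.from_zpk([-0.05, -0.004], [-0.2, -0.02, -0.005], -1.0)
        res = classify(G, CAPTION_BOUNDS)
        assert res.configuration == "higher_order"

    def test_winning_cost_is_tiny_on_clean_input(self, G_parallel):
        res = classify(G_parallel, CAPTION_BOUNDS)
        assert min(res.f_valp, res.f_valf) <= 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_decision_invariant_to_multistart_seed(self, G_feedback, seed):
        res = classify(G_feedback, CAPTION_BOUNDS, ClassifyOptions(seed=seed))
        assert res.configuration == "feedback"

    def test_symmetric_margins_declared_ambiguous(self, G_parallel):
        # tau_b interval placed so the true slow process (100 ms) and the
        # feedback alternative (zero at 242.5 ms) sit at equal wall margins
        bounds = Bounds(tau_a=(1, 9), tau_b=(50.0, 292.5),
                        k_a=(-20, 20), k_b=(-20, 20))
        res = classify(G_parallel, bounds)
        assert res.ambiguous
        assert res.configuration is None

    def test_parallel_addition_label(self):
        G = combine(FirstOrderProcess(-5, 5), FirstOrderProcess(-1, 100), "parallel")
        res = classify(G, CAPTION_BOUNDS)
        assert res.configuration == "parallel_add"


class TestS2StyleSweep:
    """Convergence study: tau_a=15, tau_b=150, gain grid, both generators."""

    @pytest.mark.parametrize("k_a", [-10.0, -4.0, 2.0, 8.0])
    @pytest.mark.parametrize("k_b", [-7.0, -2.0, 3.0, 9.0])
    def test_parallel_generator_recovered(self, k_a, k_b):
        if k_a + k_b == 0:
            pytest.skip("degenerate zero-gain sum")
        try:
            G = combine(FirstOrderProcess(k_a, 15.0), FirstOrderProcess(k_b, 150.0),
                        "parallel")
        except Exception:
            pytest.skip("infeasible combination")
        bounds = Bounds.around_processes(15.0, 150.0)
        res = classify(G, bounds)
        want = "parallel_sub" if k_a * k_b < 0 else "parallel_add"
        assert res.configuration == want
        assert res.recovered == pytest.approx((k_a, k_b, 15.0, 150.0), rel=1e-3)

    @pytest.mark.parametrize("k_a", [-10.0, -4.0, 2.0, 8.0])
    @pytest.mark.parametrize("k_b", [1.0, 4.0, 10.0])
    def test_feedback_generator_recovered(self, k_a, k_b):
        G = combine(FirstOrderProcess(k_a, 15.0), FirstOrderProcess(k_b, 150.0),
                    "feedback")
        bounds = Bounds.around_processes(15.0, 150.0)
        res = classify(G, bounds)
        assert res.configuration == "feedback"
        assert res.recovered == pytest.approx((k_a, k_b, 15.0, 150.0), rel=1e-3)


class TestBounds:
    def test_negative_feedback_lower_bound_rejected(self):
        with pytest.raises(InvalidParameterError):
            Bounds(k_b_feedback=(-1.0, 20.0))

    def test_empty_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            Bounds(tau_a=(9.0, 1.0))

    def test_feedback_box_defaults_to_clipped_kb(self):
        b = Bounds(k_b=(-20, 20))
        lo, hi = b.box("feedback")
        assert lo[1] == 0.0 and hi[1] == 20.0
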