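import itertools

import numpy as np
import pytest

from kinfer import Bounds, synth_trace
from kinfer.kinetics import scheme_from_parameters

#: Fig-5-style canonical demonstration pair: two nearly identical traces
#: from different generating mechanisms
PARALLEL_DEMO = dict(config="parallel_sub", k_a=-5.0, k_b=3.0, tau_a=5.0, tau_b=100.0)
FEEDBACK_DEMO = dict(config="feedback", k_a=-5.0, k_b=2.0, tau_a=5.0, tau_b=200.0)

#: caption bounds of the demonstration and noise studies
CAPTION_BOUNDS = Bounds(tau_a=(1, 9), tau_b=(50, 250), k_a=(-20, 20),
                        k_b=(-20, 20), k_b_feedback=(0, 20))

GRID_TAU_A = (2.0, 5.0, 10.0, 20.0)
GRID_TAU_B = (50.0, 100.0, 200.0)
GRID_K = (-5.0, -1.0, 1.0, 3.0)


def feasible_grid():
    """Every (config, k_a, k_b, tau_a, tau_b) the canonical schemes admit.

    Combinations whose closed-form rates are non-positive cannot be
    generated by the corresponding scheme and are excluded up front.
    """
    points = []
    for k_a, tau_a in itertools.product(GRID_K, GRID_TAU_A):
        points.append(("first_order", k_a, None, tau_a, None))
    for tau_a, tau_b in itertools.product(GRID_TAU_A, GRID_TAU_B):
        for k_a, k_b in itertools.product(GRID_K, GRID_K):
            for config in ("cascade", "feedback", "parallel_add", "parallel_sub"):
                if config == "feedback" and k_b < 0:
                    continue
                if config == "parallel_add" and k_a * k_b < 0:
                    continue
                if config == "parallel_sub" and k_a * k_b > 0:
                    continue
                try:
                    scheme_from_parameters(config, k_a, tau_a, k_b, tau_b)
                except Exception:
                    continue
                points.append((config, k_a, k_b, tau_a, tau_b))
    return points


@pytest.fixture(scope="session")
def parallel_trace():
    p = PARALLEL_DEMO
    return synth_trace(p["config"], p["k_a"], p["k_b"], p["tau_a"], p["tau_b"])


@pytest.fixture(scope="session")
def feedback_trace():
    p = FEEDBACK_DEMO
    return synth_trace(p["config"], p["k_a"], p["k_b"], p["tau_a"], p["tau_b"])


@pytest.fixture(scope="session")
def first_order_trace():
    return synth_trace("first_order", 1.0, None, 100.0, None, Ts=1.0,
                       step_time=100.0, duration=900.0)
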