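"""First-order process algebra and canonical second-order combinations."""
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinfer.errors import (InstabilityError, InvalidParameterError,
                           UnsupportedDynamicsError)
from kinfer.transfer import (FirstOrderProcess, RationalTF, combine,
                             make_first_order, tf_features)


class TestMakeFirstOrder:
    def test_fast_negative_process(self):
        G = make_first_order(k=-1.0, tau=5.0)
        f = tf_features(G)
        assert f.tau_poles == pytest.approx([5.0])
        assert f.tau_zeros == ()
        assert f.dc_gain == pytest.approx(-1.0)

    def test_zero_gain_is_identically_zero(self):
        G = make_first_order(k=0.0, tau=10.0)
        assert G.num == (0.0,)
        assert G(1.0 + 0.5j) == 0.0

    def test_rate_coefficients(self):
        p = FirstOrderProcess(k=1.0, tau=100.0)
        assert p.omega == pytest.approx(0.01)
        assert p.b == pytest.approx(0.01)

    @pytest.mark.parametrize("tau", [0.0, -3.0, np.nan])
    def test_invalid_tau_rejected(self, tau):
        with pytest.raises(InvalidParameterError):
            make_first_order(1.0, tau)


class TestCombine:
    def test_parallel_subtraction_closed_form(self):
        # b_a=-1, w_a=0.2, b_b=0.03, w_b=0.01: zero at 0.004124/ms
        G = combine(FirstOrderProcess(-5, 5), FirstOrderProcess(3, 100), "parallel")
        f = tf_features(G)
        assert f.tau_poles == pytest.approx([5.0, 100.0], rel=1e-12)
        assert f.tau_zeros[0] == pytest.approx(1.0 / 0.004123711, rel=1e-6)
        assert f.dc_gain == pytest.approx(-2.0)

    def test_feedback_closed_form(self):
        # second pole at w_b + b_b = 0.005 + 0.01 = 0.015 -> tau 66.67 ms
        G = combine(FirstOrderProcess(-5, 5), FirstOrderProcess(2, 200), "feedback")
        f = tf_features(G)
        assert sorted(f.tau_poles) == pytest.approx([5.0, 200.0 / 3.0], rel=1e-12)
        assert f.tau_zeros == pytest.approx([200.0])

    def test_cascade_gain_product(self):
        G = combine(FirstOrderProcess(-1, 5), FirstOrderProcess(1, 100), "cascade")
        f = tf_features(G)
        assert len(f.tau_poles) == 2 and len(f.tau_zeros) == 0
        assert f.dc_gain == pytest.approx(-1.0)

    def test_positive_feedback_rejected(self):
        with pytest.raises(InstabilityError):
            combine(FirstOrderProcess(-5, 5), FirstOrderProcess(-2, 200), "feedback")

    def test_degenerate_parallel_has_no_zero(self):
        # b_a + b_b = 0: the s-terms cancel, numerator is a constant
        G = combine(FirstOrderProcess(-1, 5), FirstOrderProcess(1, 5), "parallel")
        assert len(G.num) == 1

    def test_unknown_configuration(self):
        with pytest.raises(InvalidParameterError):
            combine(FirstOrderProcess(1, 5), FirstOrderProcess(1, 50), "loop")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    k_a=st.floats(-8, 8).filter(lambda v: abs(v) > 0.05),
    k_b=st.floats(-8, 8).filter(lambda v: abs(v) > 0.05),
    tau_a=st.floats(1, 30),
    tau_b=st.floats(40, 400),
)
def test_combination_signatures(k_a, k_b, tau_a, tau_b):
    """Pole/zero counts and dc-gain identities across the parameter space."""
    a, b = FirstOrderProcess(k_a, tau_a), FirstOrderProcess(k_b, tau_b)
    wa, wb, ba, bb = a.omega, b.omega, a.b, b.b

    Gc = combine(a, b, "cascade")
    assert Gc.order == 2 and len(tf_features(Gc).tau_zeros) == 0
    assert Gc.dc_gain == pytest.approx(k_a * k_b, rel=1e-9)

    Gp = combine(a, b, "parallel")
    assert Gp.order == 2
    assert Gp.dc_gain == pytest.approx(k_a + k_b, rel=1e-9)
    if ba + bb != 0:
        zero = tf_features(Gp).tau_zeros[0]
        assert 1.0 / zero == pytest.approx((ba * wb + bb * wa) / (ba + bb), rel=1e-9)

    if k_b >= 0:
        Gf = combine(a, b, "feedback")
        assert Gf.order == 2 and len(tf_features(Gf).tau_zeros) == 1
        assert Gf.dc_gain == pytest.approx(ba * wb / (wa * (wb + bb)), rel=1e-9)
        poles = sorted(-p for p in Gf.poles.real)
        assert poles == pytest.approx(sorted([wa, wb + bb]), rel=1e-9)


class TestFeatures:
    def test_first_order_features(self):
        f = tf_features(make_first_order(7.0, 50.0))
        assert f.tau_poles == pytest.approx([50.0])
        assert f.tau_zeros == ()
        assert f.dc_gain == pytest.approx(7.0)

    def test_unstable_pole_rejected(self):
        with pytest.raises(InstabilityError):
            tf_features(RationalTF((1.0,), (1.0, -0.1)))

    def test_oscillatory_rejected(self):
        # conjugate pole pair at -0.1 +/- 0.5i
        with pytest.raises(UnsupportedDynamicsError):
            tf_features(RationalTF((1.0,), (1.0, 0.2, 0.26)))


class TestRationalTF:
    def test_json_round_trip(self):
        G = combine(FirstOrderProcess(-5, 5), FirstOrderProcess(3, 100), "parallel")
        G2 = RationalTF.from_dict(json.loads(G.to_json()))
        assert np.allclose(G2.num, G.num) and np.allclose(G2.den, G.den)

    def test_prune_collapses_near_cancellation(self):
        G = RationalTF.from_zpk([-0.1000000001], [-0.1, -0.01], 1.0)
        with pytest.warns(UserWarning):
            Gp = G.prune(rel_tol=1e-2)
        assert Gp.order == 1

    def test_improper_rejected(self):
        with pytest.raises(InvalidParameterError):
            RationalTF((1.0, 2.0, 3.0), (1.0, 1.0))
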