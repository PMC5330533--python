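"""Algebra of first-order processes and their canonical second-order combinations.

A single molecular process (activation, inactivation, G-protein turnover, ...)
is modelled as a first-order linear system

    G_i(s) = b_i / (s + omega_i),   omega_i = 1/tau_i,   b_i = k_i/tau_i,

characterized by a gain ``k_i`` (steady-state output per unit input) and a
time constant ``tau_i`` in milliseconds.  Two such processes combine in
exactly three canonical ways -- cascade, feedback and parallel -- each of
which leaves a distinct signature in the pole/zero/gain pattern of the
resulting second-order transfer function:

    cascade:   G = b_a b_b / ((s+w_a)(s+w_b))                    (2 poles, no zero)
    feedback:  G = b_a (s+w_b) / ((s+w_a)(s+w_b+b_b))            (2 poles, 1 zero)
    parallel:  G = ((b_a+b_b)s + b_a w_b + b_b w_a)
                   / ((s+w_a)(s+w_b))                            (2 poles, 1 zero)

Parallel subtraction is parallel combination with gains of opposite sign.
All systems in scope are stable and non-oscillatory: poles are real and
strictly negative.  Time unit is milliseconds throughout; rates are 1/ms.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InstabilityError, InvalidParameterError, UnsupportedDynamicsError

__all__ = [
    "FirstOrderProcess",
    "RationalTF",
    "TFFeatures",
    "make_first_order",
    "combine",
    "tf_features",
    "CONFIGURATIONS",
]

#: canonical configuration labels for two combined first-order processes
CONFIGURATIONS = ("cascade", "feedback", "parallel")

#: relative pole-zero distance below which the pair is collapsed
CANCEL_TOL = 1e-6


@dataclass(frozen=True)
class FirstOrderProcess:
    """One elementary first-order process.

    Parameters
    ----------
    k : float
        Gain (steady-state output per unit input); may be negative.
    tau : float
        Time constant in milliseconds; must be positive.
    """

    k: float
    tau: float

    def __post_init__(self):
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise InvalidParameterError(f"time constant must be positive, got {self.tau}")
        if not np.isfinite(self.k):
            raise InvalidParameterError(f"gain must be finite, got {self.k}")

    @property
    def omega(self) -> float:
        """Rate constant 1/tau in 1/ms."""
        return 1.0 / self.tau

    @property
    def b(self) -> float:
        """Numerator coefficient k/tau in 1/ms."""
        return self.k / self.tau


@dataclass(frozen=True)
class RationalTF:
    """Continuous rational transfer function G(s) = num(s)/den(s).

    Coefficients are stored in descending powers of ``s`` with a monic
    denominator.  The numerator degree never exceeds the denominator degree.
    """

    num: tuple = field()
    den: tuple = field()

    def __post_init__(self):
        num = np.atleast_1d(np.asarray(self.num, dtype=float))
        den = np.atleast_1d(np.asarray(self.den, dtype=float))
        num = _trim_leading(num)
        den = _trim_leading(den)
        if den.size == 0:
            raise InvalidParameterError("denominator is identically zero")
        if num.size == 0:
            num = np.zeros(1)
        if num.size > den.size:
            raise InvalidParameterError("improper transfer function (num degree > den degree)")
        # normalize to monic denominator
        num = num / den[0]
        den = den / den[0]
        object.__setattr__(self, "num", tuple(num))
        object.__setattr__(self, "den", tuple(den))

    # -- constructors -------------------------------------------------
    @classmethod
    def from_zpk(cls, zeros, poles, gain) -> "RationalTF":
        num = float(gain) * np.atleast_1d(np.poly(np.asarray(zeros)))
        den = np.atleast_1d(np.poly(np.asarray(poles)))
        return cls(tuple(np.real(num)), tuple(np.real(den)))

    # -- structure ----------------------------------------------------
    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    @property
    def zeros(self) -> np.ndarray:
        return np.roots(self.num)

    @property
    def order(self) -> int:
        return len(self.den) - 1

    @property
    def dc_gain(self) -> float:
        """G(0) = num(0)/den(0); inf if there is a pole at the origin."""
        d0 = self.den[-1]
        n0 = self.num[-1]
        if d0 == 0:
            return np.inf if n0 != 0 else np.nan
        return n0 / d0

    # -- evaluation ---------------------------------------------------
    def __call__(self, s):
        s = np.asarray(s, dtype=complex)
        return np.polyval(self.num, s) / np.polyval(self.den, s)

    def freq_response(self, f):
        """|G| evaluated at real frequencies ``f`` in cycles/ms (s = 2*pi*i*f)."""
        return np.abs(self(2j * np.pi * np.asarray(f, dtype=float)))

    def prune(self, rel_tol: float = 1e-2) -> "RationalTF":
        """Collapse pole-zero pairs closer than ``rel_tol`` relative distance."""
        return _prune_pairs(self, rel_tol)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        lead = self.num[0] if any(self.num) else 0.0
        return {
            "zeros": [float(np.real(z)) for z in np.sort_complex(self.zeros)],
            "poles": [float(np.real(p)) for p in np.sort_complex(self.poles)],
            "gain": float(lead),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RationalTF":
        return cls.from_zpk(d["zeros"], d["poles"], d["gain"])


def _trim_leading(c: np.ndarray, rel: float = 1e-12) -> np.ndarray:
    """Drop leading coefficients negligible relative to the largest one."""
    if not np.any(c):
        return np.trim_zeros(c, "f")
    keep = np.abs(c) > rel * np.max(np.abs(c))
    return c[np.argmax(keep):]


@dataclass(frozen=True)
class TFFeatures:
    """Pole/zero time constants (ms, ascending) and dc gain of a transfer function."""

    tau_poles: tuple
    tau_zeros: tuple
    dc_gain: float


def _prune_pairs(G: RationalTF, rel_tol: float) -> RationalTF:
    poles = list(G.poles)
    zeros = list(G.zeros)
    lead = G.num[0] if any(G.num) else 0.0
    pruned = False
    for z in list(zeros):
        if not poles:
            break
        dists = [abs(z - p) / max(abs(z), abs(p), 1e-12) for p in poles]
        j = int(np.argmin(dists))
        if dists[j] < rel_tol:
            poles.pop(j)
            zeros.remove(z)
            pruned = True
    if not pruned:
        return G
    warnings.warn("near pole-zero cancellation collapsed to lower-order system",
                  stacklevel=3)
    return RationalTF.from_zpk(zeros, poles, lead)


def make_first_order(k: float, tau: float) -> RationalTF:
    """Transfer function b/(s+omega) of a single first-order process.

    The dc gain equals ``k``; the single pole sits at -1/tau.
    """
    p = FirstOrderProcess(k=k, tau=tau)
    return RationalTF((p.b,), (1.0, p.omega))


def combine(a: FirstOrderProcess, b: FirstOrderProcess, config: str) -> RationalTF:
    """Combine two first-order processes in a canonical configuration.

    ``config`` is one of ``cascade``, ``feedback``, ``parallel``.  Parallel
    subtraction is expressed by giving ``a`` and ``b`` gains of opposite sign.
    Feedback requires ``b.k >= 0``: negative feedback gain produces an
    unstable positive-feedback loop.
    """
    if config not in CONFIGURATIONS:
        raise InvalidParameterError(f"unknown configuration {config!r}")
    wa, wb = a.omega, b.omega
    ba, bb = a.b, b.b
    if config == "cascade":
        return RationalTF((ba * bb,), np.poly([-wa, -wb]))
    if config == "feedback":
        if b.k < 0:
            raise InstabilityError(
                "feedback with negative b-gain is a positive-feedback loop (unstable)")
        den = np.polymul((1.0, wa), (1.0, wb + bb))
        num = ba * np.asarray((1.0, wb))
        return RationalTF(tuple(num), tuple(den))
    # parallel
    den = np.poly([-wa, -wb])
    b1 = ba + bb
    b0 = ba * wb + bb * wa
    if b1 == 0.0:
        # degenerate: the s-terms cancel exactly, leaving a zero-less numerator
        return RationalTF((b0,), tuple(den))
    return RationalTF((b1, b0), tuple(den))


def tf_features(G: RationalTF) -> TFFeatures:
    """Pole/zero time constants and dc gain of a stable non-oscillatory G(s).

    tau = -1/pole for each pole (sorted ascending); likewise for zeros.
    Complex or non-negative poles are rejected: oscillatory and unstable
    systems are outside the scope of the method.
    """
    poles = G.poles
    if np.any(np.abs(poles.imag) > 1e-9 * np.maximum(np.abs(poles.real), 1.0)):
        raise UnsupportedDynamicsError(f"complex poles (oscillatory system): {poles}")
    poles = poles.real
    if np.any(poles >= 0):
        raise InstabilityError(f"non-negative pole(s): {poles}")
    zeros = G.zeros
    zeros = zeros.real if np.all(np.abs(zeros.imag) < 1e-9) else zeros
    if np.iscomplexobj(zeros):
        raise UnsupportedDynamicsError(f"complex zeros: {zeros}")
    tau_poles = tuple(sorted(-1.0 / poles))
    with np.errstate(divide="ignore"):
        tau_zeros = tuple(sorted(np.where(zeros != 0, -1.0 / zeros, np.inf)))
    return TFFeatures(tau_poles=tau_poles, tau_zeros=tau_zeros, dc_gain=G.dc_gain)
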