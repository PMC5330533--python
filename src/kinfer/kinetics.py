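"""Conversion between transfer functions and Markov-chain kinetic schemes.

A kinetic scheme is a set of molecular states S1..S_N with first-order
transitions at rates ``sigma_k`` (1/ms).  One state is linked to the input:
mass conservation couples the stimulus u(t) to the total occupancy of the
conserved pool of states,

    u(t) = sum_i z_i(t)      (pool states),

and one state is observable: the measured output is proportional to its
occupancy, y(t) = gamma_obs * z_obs(t).

For every canonical configuration of two first-order processes there is a
unique minimal scheme (assuming mass conservation and microscopic
reversibility) whose transfer function equals the canonical G(s):

first_order   S1 -> S2(obs)                                  sigma1 = w_a
cascade       S1 -> S2 -> S3(obs)                            sigma1 = w_a, sigma2 = w_b
feedback      S1 -> S2(obs) <-> S3                           sigma1 = w_a, sigma2 = b_b,
                                                             sigma3 = w_b
parallel_add  S1 -> S2(obs), S1 -> S3 -> S2                  sigma1 = (b_a+b_b)/(k_a+k_b),
                                                             sigma2 = w_fast - sigma1,
                                                             sigma3 = w_slow
parallel_sub  S1 -> S2 -> S3(obs), S1 -> S3, S4 -> S3        sigma1 = w_a,
                                                             sigma3 = zero location,
                                                             sigma2 = w_b - sigma3

In the subtraction scheme the fourth state S4 implements the inverted signal
flow: it lies outside the conserved pool, starts with occupancy ``c`` per
unit input step, and drains into the observable state at rate
sigma1 + sigma2 (an offset flow built from existing rates, so no new degree
of freedom is introduced).  All five schemes were verified symbolically to
reproduce the canonical transfer functions exactly.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.signal import ss2tf

from .errors import (
    ConversionIntegrityError,
    InfeasibleSchemeError,
    InvalidParameterError,
    MalformedSchemeError,
)
from .transfer import FirstOrderProcess, RationalTF, combine, make_first_order

__all__ = [
    "KineticScheme",
    "SchemeTrajectory",
    "scheme_from_parameters",
    "convert_to_scheme",
    "scheme_to_tf",
    "simulate_scheme",
    "SCHEME_CONFIGURATIONS",
]

SCHEME_CONFIGURATIONS = (
    "first_order", "cascade", "feedback", "parallel_add", "parallel_sub",
)

#: coefficient tolerance of the internal round-trip consistency check
INTEGRITY_TOL = 1e-6


@dataclass(frozen=True)
class Transition:
    """Directed transition ``source -> target`` at rate ``sigma`` (1/ms)."""

    source: int
    target: int
    sigma: float


@dataclass(frozen=True)
class KineticScheme:
    """Markov-chain kinetic scheme.

    ``states`` are ordered labels; state 0 is input-linked.  ``mass_pool``
    lists the states whose occupancies sum to the input (mass conservation);
    states outside the pool are inverted-flow reservoirs with initial
    occupancy per unit step given in ``reservoir_init``.  ``gamma`` is the
    reported observable constant of the configuration's closed form;
    ``obs_scale`` is the proportionality constant actually relating z_obs to
    the output (identical to gamma except for the subtraction scheme, whose
    inverted flow rescales the observable).
    """

    states: tuple
    transitions: tuple
    observable: int
    gamma: float
    configuration: str
    input_state: int = 0
    mass_pool: tuple = None
    reservoir_init: dict = field(default_factory=dict)
    obs_scale: float = None
    sigma: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mass_pool is None:
            object.__setattr__(self, "mass_pool", tuple(range(len(self.states))))
        if self.obs_scale is None:
            object.__setattr__(self, "obs_scale", self.gamma)
        n = len(self.states)
        if not (0 <= self.observable < n):
            raise MalformedSchemeError("observable index out of range")
        if self.observable == self.input_state:
            raise MalformedSchemeError("observable state cannot be the input-linked state")
        if self.input_state not in self.mass_pool:
            raise MalformedSchemeError("input-linked state must belong to the mass pool")
        for tr in self.transitions:
            if tr.sigma <= 0:
                raise InfeasibleSchemeError(
                    f"non-positive transition rate {tr.sigma} on "
                    f"{self.states[tr.source]}->{self.states[tr.target]}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def rates(self) -> tuple:
        return tuple(tr.sigma for tr in self.transitions)

    def to_dict(self) -> dict:
        return {
            "configuration": self.configuration,
            "states": list(self.states),
            "observable": self.states[self.observable],
            "input_state": self.states[self.input_state],
            "mass_pool": [self.states[i] for i in self.mass_pool],
            "transitions": [
                {"from": self.states[tr.source], "to": self.states[tr.target],
                 "sigma": float(tr.sigma)}
                for tr in self.transitions
            ],
            "reservoir_init": {self.states[i]: float(c)
                               for i, c in self.reservoir_init.items()},
            "gamma": float(self.gamma),
            "obs_scale": float(self.obs_scale),
            "sigma": {k: float(v) for k, v in self.sigma.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass(frozen=True)
class SchemeTrajectory:
    """Simulated state occupancies and reconstructed output of a scheme."""

    t: np.ndarray
    z: np.ndarray          # (n_states, n_samples) fractional occupancies
    y: np.ndarray          # obs_scale * z_obs
    scheme: KineticScheme


# ----------------------------------------------------------------------
# scheme construction from first-order process parameters
# ----------------------------------------------------------------------

def _sub_reservoir_occupancy(a: FirstOrderProcess, b: FirstOrderProcess) -> float:
    wa, wb, ba, bb = a.omega, b.omega, a.b, b.b
    den = (ba * wa + bb * wb) * (ba * wb + bb * wa)
    if den == 0:
        raise InfeasibleSchemeError("degenerate subtraction parameters (zero reservoir denominator)")
    return (wa - wb) * (ba ** 2 * wb - bb ** 2 * wa) / den


def scheme_from_parameters(config: str, k_a: float, tau_a: float,
                           k_b: float = None, tau_b: float = None) -> KineticScheme:
    """Build the canonical kinetic scheme for a configuration.

    Rates and the observable constant follow the closed forms listed in the
    module docstring.  Any non-positive rate raises
    :class:`~kinfer.errors.InfeasibleSchemeError`: the parameter combination
    cannot arise from that configuration.
    """
    if config not in SCHEME_CONFIGURATIONS:
        raise InvalidParameterError(f"unknown scheme configuration {config!r}")
    a = FirstOrderProcess(k=k_a, tau=tau_a)
    if config == "first_order":
        s1 = a.omega
        return KineticScheme(
            states=("S1", "S2"), transitions=(Transition(0, 1, s1),),
            observable=1, gamma=k_a, configuration=config,
            sigma={"sigma1": s1},
        )
    if k_b is None or tau_b is None:
        raise InvalidParameterError(f"{config} requires both processes")
    b = FirstOrderProcess(k=k_b, tau=tau_b)
    wa, wb, ba, bb = a.omega, b.omega, a.b, b.b

    if config == "cascade":
        return KineticScheme(
            states=("S1", "S2", "S3"),
            transitions=(Transition(0, 1, wa), Transition(1, 2, wb)),
            observable=2, gamma=k_a * k_b, configuration=config,
            sigma={"sigma1": wa, "sigma2": wb},
        )

    if config == "feedback":
        if k_b < 0:
            raise InfeasibleSchemeError("feedback with negative k_b is unstable")
        return KineticScheme(
            states=("S1", "S2", "S3"),
            transitions=(Transition(0, 1, wa), Transition(1, 2, bb),
                         Transition(2, 1, wb)),
            observable=1, gamma=k_a, configuration=config,
            sigma={"sigma1": wa, "sigma2": bb, "sigma3": wb},
        )

    if config == "parallel_add":
        if (k_a + k_b) == 0:
            raise InfeasibleSchemeError("parallel addition with k_a + k_b = 0 is degenerate")
        s1 = (ba + bb) / (k_a + k_b)
        w_fast, w_slow = max(wa, wb), min(wa, wb)
        s2 = w_fast - s1
        s3 = w_slow
        if s1 <= 0 or s2 <= 0:
            raise InfeasibleSchemeError(
                f"parallel addition rates non-positive (sigma1={s1}, sigma2={s2}); "
                "gains of opposite sign belong to the subtraction scheme")
        return KineticScheme(
            states=("S1", "S2", "S3"),
            transitions=(Transition(0, 1, s1), Transition(0, 2, s2),
                         Transition(2, 1, s3)),
            observable=1, gamma=k_a + k_b, configuration=config,
            sigma={"sigma1": s1, "sigma2": s2, "sigma3": s3},
        )

    # parallel_sub
    if (ba + bb) == 0:
        raise InfeasibleSchemeError("parallel subtraction with b_a + b_b = 0 is degenerate")
    s1 = wa
    s3 = (ba * wb + bb * wa) / (ba + bb)   # zero location of the parallel G(s)
    s2 = wb - s3
    if s3 <= 0 or s2 <= 0:
        raise InfeasibleSchemeError(
            f"parallel subtraction rates non-positive (sigma2={s2}, sigma3={s3})")
    gamma = (k_a + k_b) * wa * wb / s3
    c = _sub_reservoir_occupancy(a, b)
    if c < 0:
        raise InfeasibleSchemeError(
            f"negative reservoir occupancy c={c}: parameters outside the "
            "subtraction scheme's feasible region")
    return KineticScheme(
        states=("S1", "S2", "S3", "S4"),
        transitions=(Transition(0, 1, s2), Transition(0, 2, s3),
                     Transition(1, 2, s1), Transition(3, 2, s1 + s2)),
        observable=2, gamma=gamma, configuration=config,
        mass_pool=(0, 1, 2), reservoir_init={3: c},
        obs_scale=k_a + k_b,
        sigma={"sigma1": s1, "sigma2": s2, "sigma3": s3},
    )


# ----------------------------------------------------------------------
# Laplace-domain reduction:  scheme -> state space -> transfer function
# ----------------------------------------------------------------------

def _scheme_state_space(scheme: KineticScheme):
    """State-space realization of the scheme's input-output behaviour.

    ODE states are all states except the input-linked one, whose occupancy is
    the mass-conservation slack  z_in = u - sum(pool states).  Returns
    (A, B, C, x0, idx) where x0 is the reservoir initial condition per unit
    step amplitude and idx maps state index -> row of x.
    """
    n = scheme.n_states
    inp = scheme.input_state
    ode_states = [i for i in range(n) if i != inp]
    idx = {s: r for r, s in enumerate(ode_states)}
    pool_rows = [idx[s] for s in scheme.mass_pool if s != inp]
    m = len(ode_states)
    A = np.zeros((m, m))
    B = np.zeros(m)
    for tr in scheme.transitions:
        if tr.target != inp:
            r = idx[tr.target]
            if tr.source == inp:
                # inflow sigma * z_in = sigma * (u - sum(pool))
                B[r] += tr.sigma
                for pr in pool_rows:
                    A[r, pr] -= tr.sigma
            else:
                A[r, idx[tr.source]] += tr.sigma
        if tr.source != inp:
            A[idx[tr.source], idx[tr.source]] -= tr.sigma
    x0 = np.zeros(m)
    for s, c in scheme.reservoir_init.items():
        x0[idx[s]] = c
    C = np.zeros(m)
    C[idx[scheme.observable]] = scheme.obs_scale
    return A, B, C, x0, idx


def scheme_to_tf(scheme: KineticScheme) -> RationalTF:
    """Transfer function G_kin(s) = Y(s)/U(s) of a kinetic scheme.

    Solves the Laplace-transformed system (transition ODEs + observable
    equation + mass conservation) for the observable occupancy.  Reservoir
    states contribute their initial-condition response, which for step
    inputs is equivalent to the extra term ``s * C (sI-A)^-1 x0`` in the
    transfer function.  Near-cancelling pole-zero pairs arising from the
    reduction are pruned.
    """
    A, B, C, x0, _ = _scheme_state_space(scheme)
    eigs = np.linalg.eigvals(A)
    if np.any(np.abs(eigs) < 1e-14):
        raise MalformedSchemeError("singular Laplace system (zero eigenvalue); "
                                   "scheme is missing a transition")
    num1, den = ss2tf(A, B[:, None], C[None, :], np.zeros((1, 1)))
    num1 = np.atleast_1d(np.squeeze(num1))
    if np.any(x0):
        num2, _ = ss2tf(A, x0[:, None], C[None, :], np.zeros((1, 1)))
        num2 = np.polymul(np.atleast_1d(np.squeeze(num2)), (1.0, 0.0))  # * s
        num = np.polyadd(num1, num2)
    else:
        num = num1
    G = RationalTF(tuple(num), tuple(np.atleast_1d(np.squeeze(den))))
    with warnings.catch_warnings():
        # the reservoir construction always carries one structural
        # pole-zero cancellation; its removal is expected, not a surprise
        warnings.simplefilter("ignore")
        return G.prune(rel_tol=1e-6)


def convert_to_scheme(G: RationalTF, result) -> KineticScheme:
    """Convert a classified transfer function into its kinetic scheme.

    ``result`` is a :class:`~kinfer.classify.ClassificationResult` carrying
    the configuration label and the recovered first-order parameters
    (k_a, k_b, tau_a, tau_b).  The scheme is rebuilt from the closed forms
    and verified by reconstructing its transfer function and comparing it
    coefficient-wise with the canonical transfer function of the recovered
    parameters (the solvability check of the conversion procedure).
    """
    config = result.configuration
    if config not in SCHEME_CONFIGURATIONS:
        raise InvalidParameterError(
            f"cannot convert configuration {config!r} to a kinetic scheme")
    k_a, k_b, tau_a, tau_b = result.recovered
    scheme = scheme_from_parameters(config, k_a, tau_a, k_b, tau_b)

    # canonical TF of the recovered parameters, for the round-trip check
    if config == "first_order":
        G_ref = make_first_order(k_a, tau_a)
    else:
        mode = "parallel" if config.startswith("parallel") else config
        G_ref = combine(FirstOrderProcess(k_a, tau_a), FirstOrderProcess(k_b, tau_b), mode)
    G_kin = scheme_to_tf(scheme)
    err = _coeff_mismatch(G_kin, G_ref)
    if err > INTEGRITY_TOL:
        raise ConversionIntegrityError(
            f"reconstructed G_kin deviates from canonical G (relative coefficient "
            f"error {err:.3g} > {INTEGRITY_TOL:g})")
    return scheme


def _coeff_mismatch(Ga: RationalTF, Gb: RationalTF) -> float:
    na, da = np.asarray(Ga.num), np.asarray(Ga.den)
    nb, db = np.asarray(Gb.num), np.asarray(Gb.den)
    if len(da) != len(db):
        return np.inf
    width = max(len(na), len(nb))
    na = np.pad(na, (width - len(na), 0))
    nb = np.pad(nb, (width - len(nb), 0))
    scale = max(np.max(np.abs(np.concatenate([nb, db]))), 1e-300)
    return float(max(np.max(np.abs(na - nb)), np.max(np.abs(da - db))) / scale)


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------

def simulate_scheme(scheme: KineticScheme, u=None, t=None, *, step_time: float = 0.0,
                    amplitude: float = 1.0, duration: float = None, Ts: float = 0.25,
                    z0=None) -> SchemeTrajectory:
    """Integrate the scheme's linear ODE system and reconstruct the output.

    Either pass a sampled input ``u`` on the grid ``t``, or describe a step
    input with ``step_time``/``amplitude``/``duration``/``Ts``.  The system
    is linear and time-invariant, so integration uses exact matrix-exponential
    stepping on the output grid (zero-order hold between samples).  ``z0``
    optionally overrides the initial ODE-state occupancies (default: all
    occupancy in the input-linked state, reservoirs at their equilibrium
    values scaled by the step amplitude).
    """
    A, B, C, x0_unit, idx = _scheme_state_space(scheme)
    if t is None:
        if duration is None:
            slow = min(abs(np.linalg.eigvals(A).real))
            duration = step_time + 8.0 / max(slow, 1e-12)
        t = np.arange(0.0, duration + 0.5 * Ts, Ts)
    else:
        t = np.asarray(t, dtype=float)
        Ts = t[1] - t[0]
    if u is None:
        u = np.where(t >= step_time, amplitude, 0.0)
    else:
        u = np.asarray(u, dtype=float)
        if u.shape != t.shape:
            raise InvalidParameterError("u and t must have matching shapes")
        amplitude = u[np.argmax(np.abs(u))] if np.any(u) else 0.0

    m = A.shape[0]
    if z0 is None:
        x = np.zeros(m)
        reservoir_armed = bool(scheme.reservoir_init)
    else:
        x = np.asarray(z0, dtype=float).copy()
        if x.shape != (m,):
            raise InvalidParameterError(f"z0 must have shape ({m},)")
        reservoir_armed = False

    # exact LTI stepping: x_{k+1} = Ad x_k + Bd u_k
    M = np.zeros((m + 1, m + 1))
    M[:m, :m] = A * Ts
    M[:m, m] = B * Ts
    E = expm(M)
    Ad, Bd = E[:m, :m], E[:m, m]

    X = np.empty((len(t), m))
    started = False
    for k in range(len(t)):
        if reservoir_armed and not started and u[k] != 0.0:
            # input arrives: reservoirs snap to their per-unit-step occupancy
            x = x + x0_unit * u[k]
            started = True
        X[k] = x
        x = Ad @ x + Bd * u[k]

    z = np.empty((scheme.n_states, len(t)))
    pool_rows = [idx[s] for s in scheme.mass_pool if s != scheme.input_state]
    for s, r in idx.items():
        z[s] = X[:, r]
    z[scheme.input_state] = u - X[:, pool_rows].sum(axis=1)
    y = scheme.obs_scale * z[scheme.observable]

    if not scheme.reservoir_init:
        if np.min(z) < -1e-6 * max(abs(amplitude), 1.0):
            raise MalformedSchemeError(
                f"negative occupancy beyond tolerance (min {np.min(z):.3g})")
    return SchemeTrajectory(t=t, z=z, y=y, scheme=scheme)
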