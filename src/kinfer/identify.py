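"""System identification: ARX prediction-error models plus simulation-focus refinement.

The measured relationship between a sampled stimulus u and response y is
first modelled by the linear difference equation (ARX model)

    y(t) + a_1 y(t-1) + ... + a_na y(t-n_alpha)
        = b_1 u(t-1) + ... + b_nb u(t-n_beta) + e(t),

whose one-step prediction-error minimizer is the ordinary-least-squares
solution of the regression form.  ARX estimates are exact on noise-free
traces and provide the model-structure candidates and initial values.
Because the noise on a macroscopic trace enters at the *output* (measurement
noise) rather than as an equation innovation, the one-step criterion is
biased at realistic noise levels; ``identify`` therefore refines the
continuous-domain model by simulation focus -- a trust-region least-squares
fit of the simulated step response to the observed response -- and selects
the model structure by the corrected Akaike criterion on the simulation
loss.  Near-cancelling pole-zero pairs are pruned so the surviving pole
count reflects the number of underlying first-order processes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import logm
from scipy.optimize import least_squares
from scipy.signal import lsim, ss2tf, tf2ss

from .errors import (
    IdentifiabilityError,
    InstabilityError,
    InvalidParameterError,
    SamplingError,
    UnsupportedDynamicsError,
)
from .transfer import RationalTF, TFFeatures, tf_features

__all__ = [
    "SampledTrace",
    "ARXModel",
    "IdentifyOptions",
    "IdentificationResult",
    "fit_arx",
    "identify",
    "detect_onset",
]

#: samples per fastest time constant below which a warning is issued
MIN_SAMPLES_PER_TAU = 12


@dataclass(frozen=True)
class SampledTrace:
    """Uniformly sampled stimulus-response record.

    ``t`` in ms (strictly increasing, constant spacing ``Ts``), ``u`` the
    stimulus samples, ``y`` the response samples.  ``baseline`` optionally
    gives the pre-stimulus index range (start, stop) used for baseline
    subtraction and noise-variance estimation.
    """

    t: np.ndarray
    u: np.ndarray
    y: np.ndarray
    Ts: float = None
    baseline: tuple = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        u = np.asarray(self.u, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(u) == len(y)):
            raise InvalidParameterError("t, u, y must have equal length")
        if len(t) < 10:
            raise InvalidParameterError("trace too short (need >= 10 samples)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingError("time grid must be strictly increasing")
        Ts = self.Ts if self.Ts is not None else float(np.median(dt))
        dev = np.max(np.abs(dt - Ts)) / Ts
        if dev > 1e-3:
            k = int(np.argmax(np.abs(dt - Ts)))
            raise SamplingError(
                f"non-uniform sampling: spacing deviates by {dev:.2%} at row {k + 1}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "Ts", Ts)

    def __len__(self):
        return len(self.t)

    def with_y(self, y) -> "SampledTrace":
        return replace(self, y=np.asarray(y, dtype=float))


def detect_onset(u: np.ndarray) -> int:
    """Index of the first sample where the stimulus departs from its initial level."""
    u = np.asarray(u, dtype=float)
    du = np.abs(u - u[0])
    span = du.max()
    if span == 0:
        return 0
    return int(np.argmax(du > 0.5 * span))


@dataclass(frozen=True)
class ARXModel:
    """Fitted ARX model with its prediction-error statistics.

    ``lambda_hat`` is the output-referred disturbance variance: the residual
    variance divided by ||[1, alpha]||^2.  The disturbance model is
    v = (1/A(q)) e, so the innovation variance overstates the variance seen
    on the trace by exactly that factor; the normalized estimate matches the
    pre-stimulus sample variance of y.
    """

    n_alpha: int
    n_beta: int
    alpha: np.ndarray       # a_1 .. a_na
    beta: np.ndarray        # b_1 .. b_nb
    lambda_hat: float
    loss: float             # mean squared one-step prediction error

    def discrete_tf(self):
        """(num, den) polynomial coefficients of G(z) in descending powers of z."""
        den = np.concatenate([[1.0], self.alpha])
        num = np.concatenate([self.beta, np.zeros(max(self.n_alpha - self.n_beta, 0))])
        return num, den


@dataclass(frozen=True)
class IdentifyOptions:
    """Options for :func:`identify`.

    ``order_grid``: (n_alpha, n_beta) pairs fitted by ARX; default covers
    1..4 discrete poles with all proper input-tap counts.  ``conversion``:
    ``"zoh"`` (zero-order hold, default; exact for step stimuli) or
    ``"bilinear"``.  ``refine``: enable the simulation-focus stage (default).
    ``structures``: (n_poles, n_zeros) continuous structures considered in
    refinement.  ``prune_tol``: relative pole-zero distance below which
    pairs cancel.  ``expected_tau_fastest``: optional fastest expected time
    constant (ms) for the sampling-adequacy warning.
    """

    order_grid: tuple = tuple(
        (na, nb) for na in (1, 2, 3, 4) for nb in range(1, na + 1))
    conversion: str = "zoh"
    refine: bool = True
    structures: tuple = ((1, 0), (2, 0), (2, 1), (3, 2))
    prune_tol: float = 1e-2
    baseline: tuple = None
    expected_tau_fastest: float = None


@dataclass(frozen=True)
class IdentificationResult:
    """Continuous transfer function and the models behind it."""

    G: RationalTF
    arx: ARXModel
    features: TFFeatures
    lambda_hat: float
    sim_loss: float = None
    disturbance: dict = field(default_factory=dict)

    @property
    def loss(self) -> float:
        """One-step prediction-error loss of the underlying ARX fit."""
        return self.arx.loss


def fit_arx(trace: SampledTrace, n_alpha: int, n_beta: int) -> ARXModel:
    """Ordinary-least-squares fit of an ARX(n_alpha, n_beta) model.

    The trace must already be baseline-subtracted (the model has no affine
    term).  Raises :class:`~kinfer.errors.IdentifiabilityError` when the
    regressor matrix is rank deficient, e.g. for an identically zero input.
    """
    if n_alpha < 1 or n_beta < 1:
        raise InvalidParameterError("ARX orders must be >= 1")
    y = trace.y
    u = trace.u
    m = max(n_alpha, n_beta)
    n_rows = len(y) - m
    k = n_alpha + n_beta
    if n_rows <= k:
        raise InvalidParameterError("trace too short for the requested orders")
    cols = [-y[m - j: len(y) - j] for j in range(1, n_alpha + 1)]
    cols += [u[m - i: len(u) - i] for i in range(1, n_beta + 1)]
    Phi = np.column_stack(cols)
    target = y[m:]
    theta, _, rank, _ = np.linalg.lstsq(Phi, target, rcond=None)
    if rank < k:
        raise IdentifiabilityError(
            f"rank-deficient regressor (rank {rank} < {k}); "
            "input carries no identifiable excitation")
    resid = target - Phi @ theta
    sse = float(resid @ resid)
    loss = sse / n_rows
    alpha = theta[:n_alpha]
    lam = sse / max(n_rows - k, 1) / (1.0 + float(alpha @ alpha))
    return ARXModel(n_alpha=n_alpha, n_beta=n_beta,
                    alpha=alpha, beta=theta[n_alpha:],
                    lambda_hat=lam, loss=loss)


def _aicc(loss: float, n: int, k: int, floor: float) -> float:
    # the floor keeps machine-precision losses of exact fits from swamping
    # the parsimony penalty: below it, models are judged on order alone
    loss = max(loss, floor, 1e-300)
    pen = 2.0 * k + 2.0 * k * (k + 1) / max(n - k - 1, 1)
    return n * np.log(loss) + pen


def _bic(loss: float, n: int, k: int, floor: float) -> float:
    # consistent structure selection: the log-n penalty keeps a spurious
    # extra pole-zero pair from winning on chance noise-fitting gains
    loss = max(loss, floor, 1e-300)
    return n * np.log(loss) + k * np.log(max(n, 2))


def _prune_discrete(num, den, rel_tol=1e-6):
    """Cancel structurally coincident pole-zero pairs of G(z).

    Only near-exact cancellations are removed here (origin pairs from
    over-ordering and machine-precision common factors); physically
    meaningful pruning happens in the continuous domain, where pole
    distances are not compressed against the unit circle.
    """
    poles = list(np.roots(den))
    zeros = list(np.roots(num)) if np.any(num) else []
    lead = num[np.argmax(np.abs(num) > 0)] if np.any(num) else 0.0
    for z in list(zeros):
        if not poles:
            break
        d = [abs(z - p) / max(abs(z), abs(p), 1e-2) for p in poles]
        j = int(np.argmin(d))
        if d[j] < rel_tol:
            poles.pop(j)
            zeros.remove(z)
    num_p = np.real(lead * np.poly(zeros)) if zeros or lead else np.array([lead])
    den_p = np.real(np.poly(poles))
    return np.atleast_1d(num_p), np.atleast_1d(den_p)


def _d2c_zoh(num, den, Ts) -> RationalTF:
    """Zero-order-hold inverse: G(z) -> G(s) via the matrix logarithm."""
    Ad, Bd, C, D = tf2ss(num, den)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Ac = logm(Ad) / Ts
    if np.max(np.abs(Ac.imag)) > 1e-8 * max(np.max(np.abs(Ac.real)), 1.0):
        raise UnsupportedDynamicsError(
            "discrete poles without a real continuous logarithm "
            "(negative-real or complex discrete dynamics)")
    Ac = Ac.real
    Bc = Ac @ np.linalg.solve(Ad - np.eye(Ad.shape[0]), Bd)
    num_s, den_s = ss2tf(Ac, Bc, C, D)
    return RationalTF(tuple(np.atleast_1d(np.squeeze(num_s))),
                      tuple(np.atleast_1d(np.squeeze(den_s))))


def _d2c_bilinear(num, den, Ts) -> RationalTF:
    """Inverse Tustin transform z = (1 + sT/2)/(1 - sT/2)."""
    nz = len(den) - 1
    p_num = np.zeros(nz + 1)
    p_den = np.zeros(nz + 1)
    up = np.asarray([Ts / 2.0, 1.0])     # (Ts/2) s + 1, descending powers
    dn = np.asarray([-Ts / 2.0, 1.0])    # -(Ts/2) s + 1
    num = np.concatenate([np.zeros(nz + 1 - len(num)), num])
    for i in range(nz + 1):
        term = np.array([1.0])
        for _ in range(nz - i):
            term = np.convolve(term, up)
        for _ in range(i):
            term = np.convolve(term, dn)
        term = np.pad(term, (nz + 1 - len(term), 0))
        p_num = p_num + num[i] * term
        p_den = p_den + den[i] * term
    return RationalTF(tuple(p_num), tuple(p_den))


# ----------------------------------------------------------------------
# simulation-focus refinement
# ----------------------------------------------------------------------

def _pack(poles, zeros, gain):
    return np.concatenate([np.log(-np.asarray(poles, dtype=float)),
                           np.asarray(zeros, dtype=float), [gain]])


def _unpack(x, n_p, n_z):
    # clip keeps exploratory optimizer steps from overflowing exp
    poles = -np.exp(np.clip(x[:n_p], -45.0, 45.0))
    zeros = x[n_p:n_p + n_z]
    gain = x[-1]
    return poles, zeros, gain


def _separate_poles(poles):
    poles = np.asarray(poles, dtype=float).copy()
    for i in range(1, len(poles)):
        while np.any(np.abs(poles[:i] - poles[i]) < 1e-9 * np.abs(poles[i])):
            poles[i] *= 1.0 + 1e-8
    return poles


def _step_parts(poles, zeros, gain, t):
    """Residue expansion of the unit-step response and its building blocks.

    Returns (y, G0, R, E) with y(t) = G0 + E @ R,  E[:, i] = exp(p_i t).
    Assumes distinct nonzero poles (coincident poles are nudged apart by a
    relative 1e-9, far below any tolerance of interest).
    """
    poles = _separate_poles(poles)
    zeros = np.asarray(zeros, dtype=float)
    numf = lambda s: gain * (np.prod(s - zeros) if zeros.size else 1.0)
    G0 = float(numf(0.0)) / np.prod(-poles)
    R = np.empty(len(poles))
    for i, p in enumerate(poles):
        others = np.prod(np.delete(poles * -1.0 + p, i)) if len(poles) > 1 else 1.0
        R[i] = numf(p) / (p * others)
    E = np.exp(np.clip(np.outer(t, poles), None, 50.0))
    return G0 + E @ R, G0, R, E


def _step_response(poles, zeros, gain, t):
    """Unit-step response of gain * prod(s - z)/prod(s - p) at times t >= 0."""
    y, _, _, _ = _step_parts(poles, zeros, gain, t)
    return y


def _step_jacobian(x, n_p, n_z, t, u_amp):
    """Analytic Jacobian of the step-response residual wrt the packed params.

    Parametrization: x = [log(rate_1..n_p), zero_1..n_z, gain], poles
    p_i = -exp(x_i).  Differentiates the residue expansion in closed form.
    """
    poles, zeros, gain = _unpack(x, n_p, n_z)
    poles = _separate_poles(poles)
    y, G0, R, E = _step_parts(poles, zeros, gain, t)
    J = np.empty((len(t), n_p + n_z + 1))
    numf = lambda s: gain * (np.prod(s - zeros) if n_z else 1.0)

    # gain column: y is linear in gain
    J[:, -1] = y / gain if gain != 0 else _step_response(poles, zeros, 1.0, t)

    # zero columns: d ln num(s)/dz_j = -1/(s - z_j)
    for j in range(n_z):
        z = zeros[j]
        dG0 = G0 / z if z != 0 else 0.0
        dR = -R / (poles - z)
        J[:, n_p + j] = dG0 + E @ dR
    # pole columns (chain rule dp/dq = p)
    for m in range(n_p):
        p_m = poles[m]
        dG0 = -G0 / p_m
        dR = np.empty(n_p)
        for i in range(n_p):
            if i == m:
                dnum = (np.sum(1.0 / (p_m - zeros)) if n_z else 0.0)
                cross = np.sum([1.0 / (p_m - q) for j, q in enumerate(poles) if j != m])
                dR[i] = R[m] * (dnum - 1.0 / p_m - cross)
            else:
                dR[i] = R[i] / (poles[i] - p_m)
        col = dG0 + E @ dR + R[m] * t * E[:, m]
        J[:, m] = col * p_m
    return u_amp * J


def _is_step_input(u, onset):
    if onset == 0 and u[0] != 0:
        return False
    pre = u[:onset]
    post = u[onset:]
    return (pre.size == 0 or np.ptp(pre) == 0) and np.ptp(post) == 0


def _refine_structure(n_p, n_z, inits, t_resp, y_resp, u_amp, t_full=None,
                      u_full=None, step_mode=True):
    """Best simulation-focus fit of a (n_p poles, n_z zeros) structure."""

    jac = None
    if step_mode:
        def residual(x):
            poles, zeros, gain = _unpack(x, n_p, n_z)
            return u_amp * _step_response(poles, zeros, gain, t_resp) - y_resp

        def jac(x):
            return _step_jacobian(x, n_p, n_z, t_resp, u_amp)
    else:
        def residual(x):
            poles, zeros, gain = _unpack(x, n_p, n_z)
            num = gain * np.atleast_1d(np.poly(zeros))
            den = np.atleast_1d(np.poly(poles))
            _, y_sim, _ = lsim((num, den), u_full, t_full)
            return y_sim[-len(y_resp):] - y_resp

    best = None
    for x0 in inits:
        try:
            sol = least_squares(residual, x0, method="lm", xtol=1e-11, ftol=1e-11,
                                gtol=1e-11, max_nfev=120,
                                jac=jac if jac is not None else "2-point")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None, np.inf
    loss = float(2.0 * best.cost / len(y_resp))
    return _unpack(best.x, n_p, n_z), loss


def _heuristic_inits(n_p, n_z, t_span, dc):
    """Generic starting points when no ARX-derived initialization matches."""
    inits = []
    for scale in (0.3, 1.0, 3.0):
        rates = np.geomspace(2.0 / t_span, 60.0 / t_span, n_p) * scale
        poles = -rates
        zeros = -np.full(n_z, np.sqrt(rates[0] * rates[-1]))
        denom = np.prod(-zeros) if n_z else 1.0
        gain = dc * np.prod(rates) / denom if denom != 0 else dc
        inits.append(_pack(poles, zeros, gain))
    return inits


def identify(trace: SampledTrace, options: IdentifyOptions = None) -> IdentificationResult:
    """Identify a continuous transfer function from a stimulus-response trace.

    Subtracts the pre-stimulus baseline of u and y (so the system starts at
    rest), fits ARX models over the order grid, converts the candidates to
    the continuous domain, and (by default) refines them by simulation
    focus, selecting the structure by corrected AIC on the simulation loss.
    Near-cancelling pole-zero pairs are pruned; unstable or oscillatory
    models are rejected.  The surviving pole count (1 or 2) labels candidate
    first- or second-order dynamics; three or more poles label a
    higher-order system.
    """
    opt = options or IdentifyOptions()

    onset = detect_onset(trace.u)
    base = opt.baseline or trace.baseline or (0, onset)
    b0, b1 = base
    if b1 > b0:
        u0 = float(np.mean(trace.u[b0:b1]))
        y0 = float(np.mean(trace.y[b0:b1]))
    else:
        u0 = y0 = 0.0
    work = SampledTrace(t=trace.t, u=trace.u - u0, y=trace.y - y0,
                        Ts=trace.Ts, baseline=base)

    # --- ARX stage ----------------------------------------------------
    candidates = []
    n_eff = len(work)
    floor = 1e-14 * max(float(np.var(work.y)), 1e-30)
    for na, nb in opt.order_grid:
        try:
            model = fit_arx(work, na, nb)
        except IdentifiabilityError:
            continue
        candidates.append((_aicc(model.loss, n_eff, na + nb, floor), na + nb, model))
    if not candidates:
        raise IdentifiabilityError("no ARX order on the grid could be fitted")
    candidates.sort(key=lambda c: (c[0], c[1]))

    # continuous conversions of the ranked candidates (used directly when
    # refine is off, and as refinement initializations otherwise)
    converted = []
    last_err = IdentifiabilityError("no convertible ARX candidate")
    for _, _, model in candidates:
        num_z, den_z = model.discrete_tf()
        num_z, den_z = _prune_discrete(num_z, den_z)
        poles_z = np.roots(den_z)
        try:
            if np.any(np.abs(poles_z) >= 1.0):
                raise InstabilityError(
                    f"unstable identified discrete poles {poles_z}; rejecting model")
            if opt.conversion == "zoh":
                Gc = _d2c_zoh(num_z, den_z, work.Ts)
            elif opt.conversion == "bilinear":
                Gc = _d2c_bilinear(num_z, den_z, work.Ts)
            else:
                raise InvalidParameterError(f"unknown conversion {opt.conversion!r}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Gc = Gc.prune(rel_tol=opt.prune_tol)
            tf_features(Gc)   # validates real, stable poles
        except (InstabilityError, UnsupportedDynamicsError) as err:
            last_err = err
            continue
        converted.append((Gc, model))

    if not opt.refine:
        if not converted:
            raise last_err
        G, best = converted[0]
        feats = tf_features(G)
        return _package(G, best, feats, work, opt, sim_loss=None,
                        lambda_hat=best.lambda_hat)

    # --- simulation-focus stage --------------------------------------
    y_resp = work.y[onset:]
    t_resp = work.t[onset:] - work.t[onset]
    u_amp = float(np.mean(work.u[onset:])) if onset < len(work) else 0.0
    step_mode = _is_step_input(work.u, onset) and u_amp != 0.0
    if y_resp.size < 10:
        raise IdentifiabilityError("response window too short for refinement")
    dc_est = float(np.mean(y_resp[-max(len(y_resp) // 20, 5):])) / (u_amp or 1.0)
    t_span = max(t_resp[-1], work.Ts * 10)

    best_fit = None
    best_score = np.inf
    best_struct = None
    best_loss = np.inf
    for n_p, n_z in opt.structures:
        inits = []
        for Gc, _ in converted:
            if Gc.order == n_p and max(len(Gc.num) - 1, 0) == n_z:
                lead = Gc.num[0] if any(Gc.num) else 0.0
                inits.append(_pack(Gc.poles.real, Gc.zeros.real, lead))
                break
        heur = _heuristic_inits(n_p, n_z, t_span, dc_est)
        inits.extend(heur[1:2] if inits else heur)
        fit, loss = _refine_structure(n_p, n_z, inits, t_resp, y_resp, u_amp,
                                      t_full=work.t, u_full=work.u,
                                      step_mode=step_mode)
        if fit is None:
            continue
        score = _bic(loss, len(y_resp), n_p + n_z + 1, floor)
        if score < best_score:
            best_score, best_fit, best_struct = score, fit, (n_p, n_z)
            best_loss = loss
        if best_loss <= floor:
            break   # already at machine precision; richer structures cannot help
    if best_fit is None:
        raise last_err

    poles, zeros, gain = best_fit
    G = RationalTF.from_zpk(zeros, poles, gain)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        G = G.prune(rel_tol=opt.prune_tol)
    feats = tf_features(G)
    n_fit = len(y_resp)
    k_fit = best_struct[0] + best_struct[1] + 1
    sim_loss = float(np.mean((u_amp * _step_response(poles, zeros, gain, t_resp)
                              - y_resp) ** 2)) if step_mode else None
    lam = (np.sum((u_amp * _step_response(poles, zeros, gain, t_resp) - y_resp) ** 2)
           / max(n_fit - k_fit, 1)) if step_mode else candidates[0][2].lambda_hat
    return _package(G, candidates[0][2], feats, work, opt,
                    sim_loss=sim_loss, lambda_hat=float(lam))


def _package(G, arx, feats, work, opt, sim_loss, lambda_hat):
    tau_fast = min(feats.tau_poles)
    ref_tau = opt.expected_tau_fastest or tau_fast
    if work.Ts > ref_tau / MIN_SAMPLES_PER_TAU:
        warnings.warn(
            f"sampling interval {work.Ts} ms gives fewer than "
            f"{MIN_SAMPLES_PER_TAU} samples per fastest time constant "
            f"({ref_tau:.3g} ms); identification may be unreliable",
            stacklevel=3)
    disturbance = {"model": "arx", "h_den": [1.0, *np.asarray(arx.alpha)],
                   "lambda": lambda_hat}
    return IdentificationResult(G=G, arx=arx, features=feats,
                                lambda_hat=lambda_hat, sim_loss=sim_loss,
                                disturbance=disturbance)
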