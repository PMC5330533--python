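"""Signal-to-noise computation and Monte-Carlo robustness sweeps.

The SNR of a trace is defined in band: the signal's average power
P_Y = (1/N) sum y[n]^2 over the response window, divided by the noise power
that falls inside the signal's bandwidth, P_N = 2 lambda BW, where lambda is
the per-sample white-noise variance (flat spectral density over the
normalized band [-1/2, 1/2]) and BW is the frequency (cycles/sample) at
which |G| has dropped 3 dB from its peak.  ``noise_sweep`` runs the full
identify -> classify -> convert pipeline on noisy replicates and reports the
misclassification probability and the relative errors of the recovered
transition rates per SNR level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError, KinferError
from .identify import SampledTrace, detect_onset, identify
from .transfer import RationalTF

__all__ = ["SweepResult", "snr_db", "noise_sweep", "bandwidth_3db", "signal_power"]


def signal_power(trace: SampledTrace, response_only: bool = True) -> float:
    """Average power (1/N) sum y^2, by default over the post-onset window."""
    y = trace.y
    if response_only:
        onset = detect_onset(trace.u)
        if onset < len(y) - 1:
            y = y[onset:]
    return float(np.mean(np.square(y)))


def bandwidth_3db(G: RationalTF, f_max: float = None) -> float:
    """3-dB bandwidth of |G| in cycles/ms.

    The bandwidth is the frequency at which the gain has dropped by 3 dB
    (a factor sqrt(2)) from its maximum over the band; the maximum is found
    on a log-spaced grid reaching well beyond the fastest pole or zero.
    """
    rates = np.abs(np.concatenate([G.poles, G.zeros])) if len(G.num) > 1 else np.abs(G.poles)
    fastest = np.max(rates.real) if rates.size else 1.0
    f_hi = f_max or 100.0 * max(fastest, 1e-6) / (2 * np.pi)
    grid = np.concatenate([[0.0], np.geomspace(f_hi * 1e-6, f_hi, 2000)])
    mag = G.freq_response(grid)
    i_pk = int(np.argmax(mag))
    target = mag[i_pk] / np.sqrt(2.0)
    for j in range(i_pk + 1, len(grid)):
        if mag[j] <= target:
            f = brentq(lambda x: G.freq_response(x) - target, grid[j - 1], grid[j])
            return float(f)
    raise InvalidParameterError("no 3-dB drop found below the search limit")


def snr_db(trace: SampledTrace, lambda_hat: float, G: RationalTF) -> float:
    """In-band SNR (dB) of a trace given its noise variance and dynamics.

    ``lambda_hat`` is the per-sample white-noise variance (identified, or
    the pre-stimulus sample variance); ``G`` supplies the bandwidth.
    Returns +inf for a noise-free trace; raises for a zero-power signal.
    """
    p_y = signal_power(trace)
    if p_y == 0:
        raise InvalidParameterError("zero-power signal: SNR undefined")
    if lambda_hat == 0:
        return np.inf
    if lambda_hat < 0:
        raise InvalidParameterError("negative noise variance")
    bw_n = bandwidth_3db(G) * trace.Ts          # cycles/sample
    p_n = 2.0 * lambda_hat * bw_n
    return float(10.0 * np.log10(p_y / p_n))


@dataclass(frozen=True)
class SweepResult:
    """Per-SNR-level misclassification probability and rate errors.

    ``p_e`` counts every run not returning the generating configuration
    (wrong label, wrong order, ambiguous outcome, or a stage failure) as an
    error.  ``rel_err`` holds mean +/- sd of |sigma_hat - sigma|/sigma per
    transition rate, over the correctly classified runs only.
    """

    config: str
    snr_levels: tuple
    p_e: tuple
    rel_err: dict
    n_sim: int
    seed: int
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "snr_levels": list(self.snr_levels),
            "p_e": list(self.p_e),
            "rel_err": {k: {"mean": list(v[0]), "sd": list(v[1])}
                        for k, v in self.rel_err.items()},
            "n_sim": self.n_sim,
            "seed": self.seed,
        }

    def to_table(self, path=None, delimiter=","):
        """Per-level sweep table (one row per SNR level); optionally written
        to delimited text."""
        import pandas as pd

        data = {"snr_db": list(self.snr_levels), "p_e": list(self.p_e)}
        for k, (mean, sd) in sorted(self.rel_err.items()):
            data[f"rel_err_{k}_mean"] = list(mean)
            data[f"rel_err_{k}_sd"] = list(sd)
        df = pd.DataFrame(data)
        if path is not None:
            df.to_csv(path, sep=delimiter, index=False)
        return df


def noise_sweep(config: str, params: dict, snr_levels, bounds, n_sim: int = 100,
                seed: int = 0, Ts: float = None, identify_options=None,
                classify_options=None) -> SweepResult:
    """Monte-Carlo noise-robustness sweep of the full pipeline.

    ``params`` carries k_a, k_b, tau_a, tau_b of the generating scheme;
    ``snr_levels`` the white-noise levels in dB (None = noise-free).  For
    each level, ``n_sim`` noisy replicates are generated, pushed through
    identify -> classify -> convert, and scored.
    """
    from .classify import classify
    from .kinetics import scheme_from_parameters
    from .simulate import DEFAULT_TS, NoiseSpec, add_noise, synth_trace

    if n_sim < 10:
        warnings.warn("n_sim < 10 gives unstable error estimates", stacklevel=2)
    Ts = Ts or DEFAULT_TS
    scheme_true = scheme_from_parameters(
        config, params["k_a"], params["tau_a"], params.get("k_b"), params.get("tau_b"))
    sigma_true = scheme_true.sigma
    clean = synth_trace(config, params["k_a"], params.get("k_b"),
                        params["tau_a"], params.get("tau_b"), Ts=Ts)
    from .kinetics import scheme_to_tf
    G_true = scheme_to_tf(scheme_true)

    p_e = []
    rel = {k: ([], []) for k in sigma_true}
    per_level_errs = {}
    for li, level in enumerate(snr_levels):
        errors = 0
        errs_here = {k: [] for k in sigma_true}
        for r in range(n_sim):
            rep_seed = int(np.random.SeedSequence([seed, li, r]).generate_state(1)[0]
                           % (2 ** 31))
            if level is None or np.isinf(level):
                noisy = clean
            else:
                noisy = add_noise(clean, NoiseSpec(kind="white_gaussian",
                                                   snr_db=float(level),
                                                   seed=rep_seed), G_true)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ident = identify(noisy, identify_options)
                    res = classify(ident.G, bounds, classify_options)
            except KinferError:
                errors += 1
                continue
            if res.configuration != config:
                errors += 1
                continue
            try:
                from .kinetics import convert_to_scheme
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scheme_hat = convert_to_scheme(ident.G, res)
            except KinferError:
                errors += 1
                continue
            for k, v in sigma_true.items():
                errs_here[k].append(abs(scheme_hat.sigma[k] - v) / abs(v))
        p_e.append(errors / n_sim)
        for k in sigma_true:
            vals = np.asarray(errs_here[k])
            rel[k][0].append(float(np.mean(vals)) if vals.size else np.nan)
            rel[k][1].append(float(np.std(vals)) if vals.size else np.nan)
        per_level_errs[str(level)] = errors
    rel_err = {k: (tuple(m), tuple(s)) for k, (m, s) in rel.items()}
    return SweepResult(config=config, snr_levels=tuple(snr_levels), p_e=tuple(p_e),
                       rel_err=rel_err, n_sim=n_sim, seed=seed,
                       detail={"errors": per_level_errs})
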