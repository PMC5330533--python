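"""End-to-end pipeline: identify -> classify -> convert -> simulate-check.

``run_pipeline`` chains the four stages on a stimulus-response trace and
returns a self-contained report: the identified transfer function and its
features, the classification costs and recovered process parameters, the
kinetic scheme with its transition rates, and the relative RMS misfit of
the scheme's simulated output against the observed response.  Reports
serialize to JSON and validate against the schema shipped in
``kinfer/schemas/report.schema.json``.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import __version__
from .classify import Bounds, ClassifyOptions, classify
from .errors import FormatError, KinferError
from .identify import IdentifyOptions, SampledTrace, identify
from .kinetics import convert_to_scheme, simulate_scheme
from .noise import snr_db

__all__ = ["PipelineReport", "run_pipeline", "validate_report", "report_schema"]


@dataclass(frozen=True)
class PipelineReport:
    """Self-contained result of a full pipeline run."""

    identification: dict
    classification: dict
    scheme: dict
    trajectory: dict
    provenance: dict
    trace_snr_db: float = None

    def to_dict(self) -> dict:
        return {
            "identification": self.identification,
            "classification": self.classification,
            "scheme": self.scheme,
            "trajectory": self.trajectory,
            "trace_snr_db": self.trace_snr_db,
            "provenance": self.provenance,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=_jsonable, **kw)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(bounds: Bounds, id_opt, cl_opt) -> str:
    blob = json.dumps({"bounds": bounds.to_dict(),
                       "identify": repr(id_opt), "classify": repr(cl_opt)},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(trace: SampledTrace, bounds: Bounds = None,
                 identify_options: IdentifyOptions = None,
                 classify_options: ClassifyOptions = None) -> PipelineReport:
    """Run identification, classification, conversion and the simulate-check.

    An ambiguous classification yields a report carrying both costs and no
    scheme.  Stage errors propagate as the stage's own exception type with
    its context.
    """
    bounds = bounds or Bounds()
    id_opt = identify_options or IdentifyOptions()
    cl_opt = classify_options or ClassifyOptions()

    ident = identify(trace, id_opt)
    identification = {
        "G": ident.G.to_dict(),
        "tau_poles": list(ident.features.tau_poles),
        "tau_zeros": list(ident.features.tau_zeros),
        "dc_gain": ident.features.dc_gain,
        "loss": ident.loss,
        "sim_loss": ident.sim_loss,
        "lambda_hat": ident.lambda_hat,
        "arx_orders": [ident.arx.n_alpha, ident.arx.n_beta],
    }
    try:
        snr = snr_db(trace, ident.lambda_hat, ident.G)
    except KinferError:
        snr = None

    result = classify(ident.G, bounds, cl_opt)
    classification = result.to_dict()

    scheme_dict = {}
    trajectory = {}
    if result.configuration in ("first_order", "cascade", "feedback",
                                "parallel_add", "parallel_sub"):
        scheme = convert_to_scheme(ident.G, result)
        scheme_dict = scheme.to_dict()
        # simulate-check: overlay the scheme's output on the observed trace
        onset = trace.baseline[1] if trace.baseline else 0
        u0 = float(np.mean(trace.u[:onset])) if onset else 0.0
        y0 = float(np.mean(trace.y[:onset])) if onset else 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = simulate_scheme(scheme, u=trace.u - u0, t=trace.t)
        resid = traj.y - (trace.y - y0)
        scale = np.sqrt(np.mean((trace.y - y0) ** 2)) or 1.0
        trajectory = {
            "relative_rms_misfit": float(np.sqrt(np.mean(resid ** 2)) / scale),
            "y_final": float(traj.y[-1]),
            "occupancy_final": {scheme.states[i]: float(traj.z[i, -1])
                                for i in range(scheme.n_states)},
        }

    provenance = {
        "package": "kinfer",
        "version": __version__,
        "config_hash": _config_hash(bounds, id_opt, cl_opt),
        "bounds": bounds.to_dict(),
        "classify_seed": cl_opt.seed,
        "n_samples": len(trace),
        "Ts": trace.Ts,
    }
    return PipelineReport(identification=identification,
                          classification=classification,
                          scheme=scheme_dict, trajectory=trajectory,
                          provenance=provenance, trace_snr_db=snr)


def report_schema() -> dict:
    """The published JSON schema for pipeline reports."""
    with resources.files("kinfer").joinpath("schemas/report.schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Validate a report dict against the published schema (subset check).

    Raises :class:`~kinfer.errors.FormatError` on the first violation.
    """
    schema = report_schema()

    def check(obj, sch, path):
        typ = sch.get("type")
        if typ == "object":
            if not isinstance(obj, dict):
                raise FormatError(f"{path}: expected object")
            for key in sch.get("required", []):
                if key not in obj:
                    raise FormatError(f"{path}: missing required key {key!r}")
            for key, sub in sch.get("properties", {}).items():
                if key in obj and obj[key] is not None:
                    check(obj[key], sub, f"{path}.{key}")
        elif typ == "array":
            if not isinstance(obj, list):
                raise FormatError(f"{path}: expected array")
            if "items" in sch:
                for i, item in enumerate(obj):
                    check(item, sch["items"], f"{path}[{i}]")
        elif typ == "number":
            if not isinstance(obj, (int, float)) or isinstance(obj, bool):
                raise FormatError(f"{path}: expected number, got {type(obj).__name__}")
        elif typ == "string":
            if not isinstance(obj, str):
                raise FormatError(f"{path}: expected string")

    check(report, schema, "$")
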