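"""Trace input/output: delimited text with time, stimulus and response columns."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError
from .identify import SampledTrace

__all__ = ["read_trace", "write_trace", "write_trajectory"]


def read_trace(path, *, time_col=0, input_col=1, output_col=2,
               delimiter=None, baseline=None) -> SampledTrace:
    """Read a sampled trace from delimited text.

    Columns may be addressed by position (default: time, input, output) or
    by header name.  Which physical channel is the stimulus is a property
    of the experiment (command voltage in voltage clamp, ligand
    concentration in a perfusion step) and must be stated explicitly when
    it is not the second column.  Non-uniform time grids (spacing deviating
    by more than 0.1%) are rejected, naming the first offending row.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python",
                         comment="#", skip_blank_lines=True)
    except Exception as err:
        raise FormatError(f"cannot parse {path}: {err}") from err
    # positional addressing falls back to a header-less read
    if isinstance(time_col, int):
        first = pd.read_csv(path, sep=delimiter, engine="python", comment="#",
                            nrows=1, header=None)
        if not np.issubdtype(np.asarray(first.iloc[0]).dtype, np.number):
            pass        # header present; df already parsed with it
        else:
            df = pd.read_csv(path, sep=delimiter, engine="python",
                             comment="#", header=None)

    def col(sel, name):
        try:
            series = df.iloc[:, sel] if isinstance(sel, int) else df[sel]
        except (IndexError, KeyError):
            raise FormatError(f"missing {name} column {sel!r} in {path}")
        vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            row = int(np.argmax(~np.isfinite(vals))) + 1
            raise FormatError(f"non-numeric or NaN {name} value at data row {row}")
        return vals

    t = col(time_col, "time")
    u = col(input_col, "input")
    y = col(output_col, "output")
    try:
        return SampledTrace(t=t, u=u, y=y, baseline=baseline)
    except SamplingError:
        raise
    except ValueError as err:
        raise FormatError(str(err)) from err


def write_trace(trace: SampledTrace, path, delimiter=",") -> None:
    """Write a trace as delimited text with a `time,input,output` header."""
    df = pd.DataFrame({"time": trace.t, "input": trace.u, "output": trace.y})
    df.to_csv(path, sep=delimiter, index=False)


def write_trajectory(traj, path, delimiter=",") -> None:
    """Write state occupancies and reconstructed output of a simulation."""
    data = {"time": traj.t}
    for i, label in enumerate(traj.scheme.states):
        data[f"z_{label}"] = traj.z[i]
    data["y"] = traj.y
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)
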