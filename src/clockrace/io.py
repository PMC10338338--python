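"""Trace-table I/O.

Traces are stored as long-format CSV with one row per (cell, frame):
``cell_id, time_h, cdk2, apc, ccna2, divided, treatment, treatment_time_h,
preset``.  ``divided`` is a 0/1 event flag at the frame of anaphase; a
channel a trace does not carry is written as empty fields and read back
as a missing channel.  Division times are snapped to the frame grid by
the generator, so a write -> read round trip is lossless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import CellTrace, TreatmentProgram

__all__ = ["SchemaError", "TRACE_COLUMNS", "write_traces", "read_traces",
           "traces_to_frame"]

TRACE_COLUMNS = (
    "cell_id", "time_h", "cdk2", "apc", "ccna2", "divided",
    "treatment", "treatment_time_h", "preset",
)


class SchemaError(ValueError):
    """A trace table does not conform to the expected schema."""


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-format table for a collection of traces."""
    parts = []
    for tr in traces:
        n = len(tr.times)
        divided = np.zeros(n, dtype=int)
        for d in tr.division_times:
            divided[int(np.argmin(np.abs(tr.times - d)))] = 1
        parts.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "time_h": tr.times,
            "cdk2": tr.cdk2 if tr.cdk2 is not None else np.nan,
            "apc": tr.apc if tr.apc is not None else np.nan,
            "ccna2": tr.ccna2 if tr.ccna2 is not None else np.nan,
            "divided": divided,
            "treatment": tr.treatment.encode(),
            "treatment_time_h": tr.treatment.treatment_time,
            "preset": tr.preset_name,
        }))
    return pd.concat(parts, ignore_index=True)


def write_traces(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.8g")


def read_traces(path) -> list[CellTrace]:
    """Read a trace CSV back into CellTrace objects.

    Validates the schema (missing columns are named in the error), the
    per-cell time grid (strictly increasing, constant step) and channel
    values.  All-empty channel columns become missing channels.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"trace table is missing column(s): {', '.join(missing)}"
        )
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        times = grp["time_h"].to_numpy(dtype=float)
        steps = np.diff(times)
        if len(times) < 2 or np.any(steps <= 0) or \
                not np.allclose(steps, steps[0]):
            raise SchemaError(
                f"cell {cell_id}: time_h must be strictly increasing with a "
                "constant step"
            )
        channels = {}
        for name in ("cdk2", "apc", "ccna2"):
            col = grp[name].to_numpy(dtype=float)
            if np.all(np.isnan(col)):
                channels[name] = None
            elif np.any(~np.isfinite(col)):
                raise SchemaError(
                    f"cell {cell_id}: column {name} mixes values and gaps"
                )
            else:
                channels[name] = col
        t_treat = float(grp["treatment_time_h"].iloc[0])
        treatment = TreatmentProgram.decode(str(grp["treatment"].iloc[0]),
                                            t_treat)
        division_times = [float(t) for t, flag
                          in zip(times, grp["divided"].to_numpy()) if flag]
        try:
            traces.append(CellTrace(
                cell_id=str(cell_id), times=times,
                cdk2=channels["cdk2"], apc=channels["apc"],
                ccna2=channels["ccna2"], division_times=division_times,
                treatment=treatment, preset_name=str(grp["preset"].iloc[0]),
            ))
        except ValueError as exc:
            raise SchemaError(f"cell {cell_id}: {exc}") from exc
    return traces
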