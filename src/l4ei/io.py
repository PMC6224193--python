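"""File I/O: columnar CSV dialects with metadata headers, JSON summaries, HDF5.

Traces are written as ``time_ms,current_pA`` CSV with a ``# key=value``
header block (or as HDF5 datasets with attributes); spike rasters as
two-column CSV plus a JSON rate summary.  Every result summary embeds the
seed and the decision-parameter values used, so a published file can be
regenerated exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import SimResult
from .scenarios import GridResult
from .traces import LTDExperiment, Trace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_h5",
    "read_trace_h5",
    "write_sim_result",
    "read_sim_result",
    "write_grid_csv",
    "read_grid_csv",
    "write_ltd_csv",
    "read_ltd_csv",
    "write_results",
]


def write_trace_csv(trace: Trace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_interval_ms={trace.sample_interval!r}\n")
        fh.write(f"# holding_mV={trace.holding_potential!r}\n")
        fh.write(f"# markers={json.dumps(trace.stimulus_markers)}\n")
        fh.write("time_ms,current_pA\n")
        for t, c in zip(trace.times, trace.samples):
            fh.write(f"{t:.6g},{c:.9g}\n")


def read_trace_csv(path) -> Trace:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    markers = [tuple(m) for m in json.loads(meta.get("markers", "[]"))]
    return Trace(
        samples=df["current_pA"].to_numpy(),
        sample_interval=float(meta["sample_interval_ms"]),
        holding_potential=float(meta.get("holding_mV", -70.0)),
        stimulus_markers=markers,
    )


def write_trace_h5(traces: dict, path) -> None:
    """Write named traces to one HDF5 container (one dataset per sweep)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, tr in traces.items():
            ds = fh.create_dataset(name, data=tr.samples)
            ds.attrs["sample_interval_ms"] = tr.sample_interval
            ds.attrs["holding_mV"] = tr.holding_potential
            ds.attrs["markers"] = json.dumps(tr.stimulus_markers)


def read_trace_h5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for name, ds in fh.items():
            out[name] = Trace(
                samples=ds[()],
                sample_interval=float(ds.attrs["sample_interval_ms"]),
                holding_potential=float(ds.attrs["holding_mV"]),
                stimulus_markers=[tuple(m) for m in json.loads(ds.attrs["markers"])],
            )
    return out


def write_sim_result(result: SimResult, out_dir, stem: str = "sim") -> None:
    """Spike raster as two-column CSV plus a JSON rate/provenance summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"neuron_id": result.spike_ids, "time_ms": result.spike_times}
    ).to_csv(out / f"{stem}_spikes.csv", index=False)
    meta = {k: v for k, v in result.meta.items() if k != "multipliers"}
    if "multipliers" in result.meta:
        meta["multipliers"] = vars(result.meta["multipliers"])
    summary = {
        "duration_ms": result.duration,
        "NE": result.NE,
        "NI": result.NI,
        "transient_discard_ms": result.transient_discard,
        "rate_e_hz": result.rate_e,
        "rate_i_hz": result.rate_i,
        "meta": meta,
    }
    (out / f"{stem}_rates.json").write_text(json.dumps(summary, indent=2))


def read_sim_result(out_dir, stem: str = "sim") -> SimResult:
    out = Path(out_dir)
    df = pd.read_csv(out / f"{stem}_spikes.csv")
    summary = json.loads((out / f"{stem}_rates.json").read_text())
    return SimResult(
        spike_ids=df["neuron_id"].to_numpy(dtype=np.int32),
        spike_times=df["time_ms"].to_numpy(dtype=float),
        duration=summary["duration_ms"],
        NE=summary["NE"],
        NI=summary["NI"],
        rate_e=summary["rate_e_hz"],
        rate_i=summary["rate_i_hz"],
        transient_discard=summary["transient_discard_ms"],
        meta=summary.get("meta", {}),
    )


def write_grid_csv(grid: GridResult, path, which: str = "percent_of_bl_e") -> None:
    """Grid matrix as CSV with rho as the row index and pi as columns."""
    mat = getattr(grid, which)
    df = pd.DataFrame(
        mat,
        index=pd.Index(grid.rho_values, name="rho_ei"),
        columns=[f"pi={p:g}" for p in grid.pi_values],
    )
    df.to_csv(path)


def read_grid_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_ltd_csv(exp: LTDExperiment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# induction_end={exp.induction_end}\n")
        fh.write("minute,amplitude_pA\n")
        for m, a in zip(exp.minutes, exp.amplitudes):
            fh.write(f"{m:g},{a:.9g}\n")


def read_ltd_csv(path) -> LTDExperiment:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return LTDExperiment(
        minutes=df["minute"].to_numpy(),
        amplitudes=df["amplitude_pA"].to_numpy(),
        induction_end=int(meta["induction_end"]),
    )


def write_results(result, path, format: str = "csv") -> None:
    """Dispatch writer: SimResult, GridResult, Trace, LTDExperiment, DataFrame, dict."""
    path = Path(path)
    if format not in ("csv", "json", "hdf5"):
        raise ValueError(f"unknown format {format!r}")
    if isinstance(result, SimResult):
        write_sim_result(result, path.parent if path.suffix else path, stem=path.stem or "sim")
    elif isinstance(result, GridResult):
        write_grid_csv(result, path)
    elif isinstance(result, Trace):
        if format == "hdf5":
            write_trace_h5({"trace": result}, path)
        else:
            write_trace_csv(result, path)
    elif isinstance(result, LTDExperiment):
        write_ltd_csv(result, path)
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
    elif isinstance(result, dict):
        path.write_text(json.dumps(result, indent=2, default=float))
    else:
        raise TypeError(f"no writer for {type(result).__name__}")
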