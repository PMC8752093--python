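"""Plain-text readers and writers for traces, curves, tables and calibrations.

Trace and curve files are tab-separated with '#'-prefixed header lines
carrying ``key=value`` metadata, so they stay greppable and diffable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import Calibration
from .correlate import CorrelationCurve
from .preprocess import BackgroundEstimate
from .synthetic import IntensityTrace

__all__ = ["write_trace", "read_trace", "write_curve", "read_curve",
           "write_calibrations", "read_calibrations",
           "write_background_table", "read_background_table"]


def _write_header(fh, fields: dict) -> None:
    for k, v in fields.items():
        fh.write(f"# {k}={v}\n")


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
    return meta


def write_trace(path, trace: IntensityTrace) -> None:
    path = Path(path)
    integral = (np.allclose(trace.counts_G, np.round(trace.counts_G))
                and np.allclose(trace.counts_R, np.round(trace.counts_R)))
    fmt = "%d" if integral else "%.6f"
    with open(path, "w") as fh:
        _write_header(fh, {"bin_width": repr(trace.bin_width),
                           "duration": repr(trace.duration),
                           **trace.metadata})
        fh.write("bin_index\tcounts_G\tcounts_R\n")
        idx = np.arange(trace.n_bins)
        np.savetxt(fh, np.column_stack([idx, trace.counts_G, trace.counts_R]),
                   fmt=["%d", fmt, fmt], delimiter="\t")


def read_trace(path) -> IntensityTrace:
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#", skiprows=len(meta) + 1, delimiter="\t")
    bin_width = float(meta.pop("bin_width"))
    meta.pop("duration", None)
    return IntensityTrace(counts_G=data[:, 1], counts_R=data[:, 2],
                          bin_width=bin_width, metadata=meta)


def write_curve(path, curve: CorrelationCurve) -> None:
    with open(Path(path), "w") as fh:
        _write_header(fh, {"pair": curve.pair,
                           "mean_rate_A": repr(curve.mean_rate_A),
                           "mean_rate_B": repr(curve.mean_rate_B),
                           "duration": repr(curve.duration)})
        fh.write("lag_s\tG\tG_err\n")
        np.savetxt(fh, np.column_stack([curve.lags, curve.G, curve.G_err]),
                   fmt="%.9e", delimiter="\t")


def read_curve(path) -> CorrelationCurve:
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#", skiprows=len(meta) + 1, delimiter="\t")
    data = np.atleast_2d(data)
    return CorrelationCurve(lags=data[:, 0], G=data[:, 1], G_err=data[:, 2],
                           pair=meta["pair"],
                           mean_rate_A=float(meta["mean_rate_A"]),
                           mean_rate_B=float(meta["mean_rate_B"]),
                           duration=float(meta["duration"]))


def write_calibrations(path, calibrations: dict[str, Calibration]) -> None:
    """YAML file with one calibration per channel."""
    doc = {}
    for channel, cal in calibrations.items():
        doc[channel] = {"dye_name": cal.dye_name, "D_ref": cal.D_ref,
                        "kappa": cal.kappa, "tau_D_ref": cal.tau_D_ref,
                        "omega_xy": cal.omega_xy, "v_eff": cal.v_eff}
    with open(Path(path), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_calibrations(path) -> dict[str, Calibration]:
    with open(Path(path)) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for channel, d in doc.items():
        out[channel] = Calibration(omega_xy=float(d["omega_xy"]),
                                   kappa=float(d["kappa"]),
                                   v_eff=float(d["v_eff"]),
                                   D_ref=float(d["D_ref"]),
                                   tau_D_ref=float(d["tau_D_ref"]),
                                   dye_name=str(d.get("dye_name", "")))
    return out


def write_background_table(path, estimates: dict[str, BackgroundEstimate]) -> None:
    """TSV of per-compartment background rates: compartment, channel, B_Hz, n_cells."""
    rows = []
    for compartment, est in estimates.items():
        rows.append({"compartment": compartment, "channel": "G",
                     "B_Hz": est.B_G, "n_cells": est.n_cells})
        rows.append({"compartment": compartment, "channel": "R",
                     "B_Hz": est.B_R, "n_cells": est.n_cells})
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_background_table(path) -> dict[str, BackgroundEstimate]:
    df = pd.read_csv(Path(path), sep="\t")
    out = {}
    for compartment, grp in df.groupby("compartment"):
        rates = {row["channel"]: float(row["B_Hz"]) for _, row in grp.iterrows()}
        out[str(compartment)] = BackgroundEstimate(
            B_G=rates.get("G", 0.0), B_R=rates.get("R", 0.0),
            source=str(compartment), n_cells=int(grp["n_cells"].iloc[0]))
    return out
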