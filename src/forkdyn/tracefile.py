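"""Plain-text file formats: traces, event sidecars, rate and step tables.

Traces are tab-separated text with ``# key = value`` header lines
carrying the generation metadata, then columns ``time_s``,
``extension_nm``, ``force_pN``.  A constant-force dialect without the
force column is accepted on read (the force then comes from a
``force_pN`` header key).  Result documents are flat YAML key/value maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .simulate import Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "write_steps",
    "write_rates",
    "read_rates",
    "write_result",
    "read_result",
]

_SCALARS = (int, float, str, bool)


def write_trace(path, trace: Trace) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# forkdyn trace v1\n")
        fh.write(f"# sample_rate_hz = {trace.sample_rate:g}\n")
        for k, v in trace.meta.items():
            if isinstance(v, _SCALARS):
                fh.write(f"# {k} = {v}\n")
        fh.write("time_s\textension_nm\tforce_pN\n")
        for t, x, F in zip(trace.t, trace.x, trace.F):
            fh.write(f"{t:.6f}\t{x:.4f}\t{F:.4f}\n")


def read_trace(path) -> Trace:
    path = Path(path)
    meta: dict = {}
    header = None
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = (s.strip() for s in body.split("=", 1))
                    try:
                        meta[k] = json.loads(v)
                    except (json.JSONDecodeError, ValueError):
                        meta[k] = v
                continue
            if header is None and any(c.isalpha() for c in line):
                header = line.split("\t")
                continue
            rows.append([float(v) for v in line.split("\t")])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    data = np.asarray(rows)
    if data.shape[1] >= 3:
        t, x, F = data[:, 0], data[:, 1], data[:, 2]
    elif data.shape[1] == 2:  # constant-force dialect
        t, x = data[:, 0], data[:, 1]
        if "force_pN" not in meta:
            raise ValueError("two-column trace requires a 'force_pN' header key")
        F = np.full_like(t, float(meta["force_pN"]))
    else:
        raise ValueError("trace needs at least time and extension columns")
    sr = float(meta.get("sample_rate_hz") or meta.get("sample_rate") or 0)
    if sr <= 0:
        dt = np.median(np.diff(t))
        sr = 1.0 / dt
    return Trace(t=t, x=x, F=F, sample_rate=sr, meta=meta)


def write_events(path, events) -> None:
    """Ground-truth sidecar: (time, opened_bp_after) per simulated event."""
    with Path(path).open("w") as fh:
        fh.write("time_s\topened_bp_after\n")
        for t, n in events:
            fh.write(f"{t:.6f}\t{n:.3f}\n")


def write_steps(path, fit, levels_time=None) -> None:
    """Step table: one row per accepted change point."""
    with Path(path).open("w") as fh:
        fh.write("t_s\tlevel_before_nm\tlevel_after_nm\tsize_nm\tsize_bp\tquality\n")
        for i in range(fit.n_steps):
            fh.write(
                f"{fit.times[i]:.6f}\t{fit.levels[i]:.4f}\t{fit.levels[i + 1]:.4f}\t"
                f"{fit.step_sizes_nm[i]:.4f}\t{fit.step_sizes_bp[i]:.4f}\t{fit.quality[i]:.4g}\n"
            )


def write_rates(path, measurements) -> None:
    with Path(path).open("w") as fh:
        fh.write("F_pN\tv_bp_s\tv_err\tbranch\tcondition\n")
        for mm in measurements:
            fh.write(f"{mm.F:.4f}\t{mm.v:.6g}\t{mm.v_err:.6g}\t{mm.branch}\t{mm.condition}\n")


def read_rates(path):
    from .ratefit import RateMeasurement

    out = []
    with Path(path).open() as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            out.append(
                RateMeasurement(
                    F=float(fields[0]), v=float(fields[1]),
                    v_err=float(fields[2]) if len(fields) > 2 and fields[2] else 0.0,
                    branch=fields[3] if len(fields) > 3 else "",
                    condition=fields[4] if len(fields) > 4 else "",
                )
            )
    return out


def write_result(path, result: dict) -> None:
    """Flat key/value result document (YAML)."""
    clean = {}
    for k, v in result.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        clean[k] = v
    with Path(path).open("w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=True)


def read_result(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
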