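"""Plain-text I/O: time series, profiles, surfaces, reports and configs.

All formats are whitespace-delimited text with ``#`` metadata headers
of the form ``# key = value`` (the dialect common to biasing-engine
colvar outputs: time in the first column).  Every writer stamps a
provenance header (package version, surface/config fingerprints, seed)
so a run can be traced back to its inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import ParseError
from .profiles import FreeEnergyProfile1D, FreeEnergySurface2D
from .sampler import TimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_profile",
    "read_profile",
    "write_surface",
    "read_surface",
    "write_offsets",
    "write_report",
    "read_config",
    "write_config",
]


def _meta_value(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def _write_header(fh, meta: dict, columns: str):
    fh.write(f"# generator = ambdimer {__version__}\n")
    for key in sorted(meta):
        fh.write(f"# {key} = {meta[key]}\n")
    fh.write(f"# columns = {columns}\n")


def write_timeseries(path, ts: TimeSeries):
    """Write a trajectory as `time xi [theta]` columns at full precision."""
    path = Path(path)
    cols = "time xi theta" if ts.theta is not None else "time xi"
    with path.open("w") as fh:
        _write_header(fh, ts.meta, cols)
        if ts.theta is not None:
            for t, x, th in zip(ts.time, ts.xi, ts.theta):
                fh.write(f"{float(t)!r} {float(x)!r} {float(th)!r}\n")
        else:
            for t, x in zip(ts.time, ts.xi):
                fh.write(f"{float(t)!r} {float(x)!r}\n")


def read_timeseries(path, required_keys: tuple = ()) -> TimeSeries:
    """Read a trajectory file; errors name the offending line or header key."""
    path = Path(path)
    meta = {}
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, raw = body.partition("=")
                    meta[key.strip()] = _meta_value(raw.strip())
                continue
            parts = line.split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as err:
                raise ParseError(
                    f"{path.name}: non-numeric token at line {lineno}: {line!r}"
                ) from err
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"{path.name}: expected 2 or 3 columns at line {lineno}, "
                    f"got {len(parts)}"
                )
    for key in required_keys:
        if key not in meta:
            raise ParseError(f"{path.name}: missing required header key {key!r}")
    if not rows:
        raise ParseError(f"{path.name}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ParseError(f"{path.name}: inconsistent column counts")
    arr = np.asarray(rows, dtype=float)
    meta.pop("columns", None)
    meta.pop("generator", None)
    return TimeSeries(
        time=arr[:, 0],
        xi=arr[:, 1],
        theta=arr[:, 2] if ncol == 3 else None,
        meta=meta,
    )


def write_profile(path, profile: FreeEnergyProfile1D, meta: dict | None = None):
    meta = {**profile.meta, **(meta or {}), "zero_convention": profile.zero_convention}
    with Path(path).open("w") as fh:
        _write_header(fh, meta, "xi g count")
        counts = (
            profile.counts
            if profile.counts is not None
            else np.full_like(profile.g, np.nan)
        )
        for x, g, c in zip(profile.xi, profile.g, counts):
            fh.write(f"{float(x)!r}\t{float(g)!r}\t{float(c)!r}\n")


def read_profile(path) -> FreeEnergyProfile1D:
    ts_like = np.loadtxt(path)
    meta = _read_meta(path)
    return FreeEnergyProfile1D(
        xi=ts_like[:, 0],
        g=ts_like[:, 1],
        counts=ts_like[:, 2] if ts_like.shape[1] > 2 else None,
        zero_convention=str(meta.get("zero_convention", "plateau-zero")),
        meta=meta,
    )


def _read_meta(path) -> dict:
    meta = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, raw = body.partition("=")
                meta[key.strip()] = _meta_value(raw.strip())
    meta.pop("columns", None)
    meta.pop("generator", None)
    return meta


def write_surface(path, surface: FreeEnergySurface2D, meta: dict | None = None):
    """Long-format TSV: xi angle g masked count."""
    meta = {**surface.meta, **(meta or {}), "angle_tag": surface.angle_tag}
    with Path(path).open("w") as fh:
        _write_header(fh, meta, "xi angle g masked count")
        counts = (
            surface.counts
            if surface.counts is not None
            else np.zeros_like(surface.g)
        )
        for i, x in enumerate(surface.xi):
            for j, a in enumerate(surface.angle):
                fh.write(
                    f"{float(x)!r}\t{float(a)!r}\t{float(surface.g[i, j])!r}\t"
                    f"{int(surface.mask[i, j])}\t{float(counts[i, j])!r}\n"
                )


def read_surface(path) -> FreeEnergySurface2D:
    meta = _read_meta(path)
    arr = np.loadtxt(path)
    xi = np.unique(arr[:, 0])
    angle = np.unique(arr[:, 1])
    shape = (len(xi), len(angle))
    g = arr[:, 2].reshape(shape)
    mask = arr[:, 3].reshape(shape).astype(bool)
    counts = arr[:, 4].reshape(shape)
    tag = str(meta.pop("angle_tag", "theta"))
    return FreeEnergySurface2D(
        xi=xi, angle=angle, g=g, mask=mask, angle_tag=tag, counts=counts, meta=meta
    )


def write_offsets(path, offsets, meta: dict | None = None):
    meta = dict(meta or {})
    meta.update(
        {
            "n_iterations": offsets.n_iterations,
            "residual": offsets.residual,
        }
    )
    with Path(path).open("w") as fh:
        _write_header(fh, meta, "window f_kcal_mol effective_count")
        neff = (
            offsets.effective_counts
            if offsets.effective_counts is not None
            else np.full_like(offsets.f, np.nan)
        )
        for i, (f, n) in enumerate(zip(offsets.f, neff)):
            fh.write(f"{i}\t{float(f)!r}\t{float(n)!r}\n")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(path, report: dict):
    with Path(path).open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_config(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh) or {}


def write_config(path, config: dict):
    with Path(path).open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
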