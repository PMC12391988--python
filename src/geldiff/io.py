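"""Tabular I/O, result serialisation and run manifests.

CSV schemas (UTF-8, comma-delimited; CRLF and LF both accepted):

==============  =====================================================
dataset         header
==============  =====================================================
release curve   ``time_s,replicate,value``
calibration     ``amount,signal``
probe panel     ``name,r_h_nm,d_gel_um2_s[,d_free_um2_s]``
FRAP curve      ``time_s,intensity_norm``
tracks          ``track_id,frame,time_s,x,y`` (optionally ``x_px,y_px``
                instead of ``x,y``, converted with ``pixel_size_um``)
==============  =====================================================

Results are written as JSON with a deterministic key order and floats
rendered at 10 significant digits, so identical inputs give byte-identical
outputs.  Every CLI run also emits a :class:`RunManifest` recording the
command, resolved parameters, SHA-256 digests of all inputs, the seed and
the package version — enough to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .frap import FrapCurve
from .gel_network import ProbeSpec
from .release import ReleaseCurve
from .tracking import Track
from . import __version__ as _pkg_version

__all__ = [
    "RunManifest",
    "read_release_csv",
    "write_release_csv",
    "read_calibration_csv",
    "read_probes_csv",
    "write_probes_csv",
    "read_frap_csv",
    "write_frap_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "write_results",
    "sha256_of_file",
]


def _read_csv(path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if path.stat().st_size == 0:
        raise SchemaError(f"empty input file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: header mismatch — missing column(s) {missing}; "
            f"found {list(df.columns)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in list(required) + [c for c in optional if c in df.columns]:
        if col in ("name", "track_id", "replicate"):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), col].iloc[0]
            raise SchemaError(f"{path}: non-numeric cell {bad!r} in column {col!r}")
        df[col] = vals
    return df


def read_release_csv(path, time_unit: str = "s") -> ReleaseCurve:
    """Read a release curve; ``time_unit='days'`` converts on read."""
    df = _read_csv(path, ["time_s", "replicate", "value"])
    if df.duplicated(subset=["time_s", "replicate"]).any():
        raise SchemaError(f"{path}: duplicate (time, replicate) keys")
    factor = 86_400.0 if time_unit == "days" else 1.0
    if time_unit not in ("s", "days"):
        raise ValidationError(f"unknown time unit {time_unit!r}")
    df = df.sort_values(["replicate", "time_s"], kind="stable")
    try:
        return ReleaseCurve(times_s=df["time_s"].to_numpy(dtype=float) * factor,
                            values=df["value"].to_numpy(dtype=float),
                            replicate_ids=df["replicate"].to_numpy())
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_release_csv(path, curve: ReleaseCurve) -> None:
    df = pd.DataFrame({"time_s": curve.times_s, "replicate": curve.replicate_ids,
                       "value": curve.values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_calibration_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, ["amount", "signal"])
    return df["amount"].to_numpy(dtype=float), df["signal"].to_numpy(dtype=float)


def read_probes_csv(path) -> list[ProbeSpec]:
    df = _read_csv(path, ["name", "r_h_nm", "d_gel_um2_s"], optional=["d_free_um2_s"])
    probes = []
    for _, row in df.iterrows():
        d_free = float(row["d_free_um2_s"]) if "d_free_um2_s" in df.columns and pd.notna(row.get("d_free_um2_s")) else None
        try:
            probes.append(ProbeSpec(name=str(row["name"]), r_h_nm=float(row["r_h_nm"]),
                                    d_gel_um2_s=float(row["d_gel_um2_s"]),
                                    d_free_um2_s=d_free))
        except ValidationError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    return probes


def write_probes_csv(path, probes: list[ProbeSpec]) -> None:
    df = pd.DataFrame({
        "name": [p.name for p in probes],
        "r_h_nm": [p.r_h_nm for p in probes],
        "d_gel_um2_s": [p.d_gel_um2_s for p in probes],
        "d_free_um2_s": [p.d_free_um2_s for p in probes],
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_frap_csv(path) -> FrapCurve:
    df = _read_csv(path, ["time_s", "intensity_norm"])
    try:
        return FrapCurve(times_s=df["time_s"].to_numpy(dtype=float),
                         intensities=df["intensity_norm"].to_numpy(dtype=float))
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_frap_csv(path, curve: FrapCurve) -> None:
    pd.DataFrame({"time_s": curve.times_s, "intensity_norm": curve.intensities}
                 ).to_csv(path, index=False, float_format="%.10g")


def read_tracks_csv(path, pixel_size_um: float | None = None) -> list[Track]:
    """Read an MTrackJ-export-like track table.

    With ``x,y`` columns positions are taken as μm; with ``x_px,y_px`` a
    ``pixel_size_um`` is required and applied.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise SchemaError(f"missing or empty input file: {path}")
    head = pd.read_csv(path, nrows=0)
    if {"x", "y"}.issubset(head.columns):
        df = _read_csv(path, ["track_id", "frame", "time_s", "x", "y"])
        xcol, ycol, scale = "x", "y", 1.0
    elif {"x_px", "y_px"}.issubset(head.columns):
        if pixel_size_um is None or not pixel_size_um > 0:
            raise ValidationError("pixel coordinates require a positive pixel_size_um")
        df = _read_csv(path, ["track_id", "frame", "time_s", "x_px", "y_px"])
        xcol, ycol, scale = "x_px", "y_px", float(pixel_size_um)
    else:
        raise SchemaError(f"{path}: header must contain x,y or x_px,y_px; found {list(head.columns)}")
    if df.duplicated(subset=["track_id", "frame"]).any():
        raise SchemaError(f"{path}: duplicate (track_id, frame) keys")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame", kind="stable")
        try:
            tracks.append(Track(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                times_s=grp["time_s"].to_numpy(dtype=float),
                positions_um=np.column_stack([grp[xcol].to_numpy(dtype=float) * scale,
                                              grp[ycol].to_numpy(dtype=float) * scale]),
            ))
        except ValidationError as exc:
            raise SchemaError(f"{path}: track {tid!r}: {exc}") from exc
    return tracks


def write_tracks_csv(path, tracks: list[Track]) -> None:
    rows = []
    for tr in tracks:
        rows.append(pd.DataFrame({
            "track_id": tr.track_id, "frame": tr.frames, "time_s": tr.times_s,
            "x": tr.positions_um[:, 0], "y": tr.positions_um[:, 1]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Result serialisation & manifests
# ---------------------------------------------------------------------------


def _jsonify(obj):
    """Render nested results deterministically; floats at 10 sig. digits."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if not np.isfinite(x) else float(f"{x:.10g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(path, payload: dict) -> None:
    """Write a result JSON with fixed key order and numeric formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_jsonify(payload), fh, indent=2, allow_nan=True)
        fh.write("\n")


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one CLI run; reproduces the run exactly."""

    command: str
    parameters: dict
    input_digests: dict = field(default_factory=dict)
    seed: int | None = None
    tool_version: str = _pkg_version
    timestamp_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds"))

    def add_input(self, path) -> None:
        self.input_digests[str(path)] = sha256_of_file(path)

    def write(self, path) -> None:
        write_results(path, {
            "command": self.command,
            "parameters": _jsonify(self.parameters),
            "input_digests": self.input_digests,
            "seed": self.seed,
            "tool_version": self.tool_version,
            "timestamp_utc": self.timestamp_utc,
        })
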