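"""Readers and writers shared by all modules.

Formats (see docs/FORMATS.md): ThT traces as 2-column CSV with ``#``
comment headers, FDF frames as long-format CSV, wavefront tracks as CSV,
fits and stats as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .fdf_biofilm import CellState, SimFrame
from .traces import ThTTrace
from .wavefront_analysis import PowerLawFit, WavefrontTrack

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_frames_csv",
    "write_frames_csv",
    "write_track_csv",
    "read_track_csv",
    "write_fits_json",
]

_FLOAT_FMT = "%.17g"  # full double precision for byte-stable round trips


def write_trace_csv(trace: ThTTrace, path: str | Path,
                    extra_header: dict | None = None) -> None:
    """Write a trace as CSV: ``#`` comment header lines, then
    time_min,intensity rows at full float precision."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# label: {trace.label}\n")
        fh.write(f"# normalized: {trace.normalized}\n")
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("time_min,intensity\n")
        for t, y in zip(trace.times, trace.intensity):
            fh.write(f"{_FLOAT_FMT % t},{_FLOAT_FMT % y}\n")


def read_trace_csv(path: str | Path) -> ThTTrace:
    """Read a trace CSV written by :func:`write_trace_csv`.

    write-then-read is the identity to full float precision; ``#`` header
    comments carrying the label and normalization flag are honoured.

    Raises
    ------
    ValueError
        For a missing column (named in the message) or a non-increasing
        time column.
    """
    path = Path(path)
    label = ""
    normalized = False
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key, value = key.strip(), value.strip()
                    if key == "label":
                        label = value
                    elif key == "normalized":
                        normalized = value.lower() == "true"
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                for required in ("time_min", "intensity"):
                    if required not in cols:
                        raise ValueError(
                            f"trace CSV {path} is missing column '{required}'"
                        )
                t_i, y_i = cols.index("time_min"), cols.index("intensity")
                header_seen = True
                continue
            parts = line.split(",")
            rows.append((float(parts[t_i]), float(parts[y_i])))
    if not header_seen:
        raise ValueError(f"trace CSV {path} has no header row")
    if not rows:
        raise ValueError(f"trace CSV {path} contains no samples")
    times = np.array([r[0] for r in rows])
    intensity = np.array([r[1] for r in rows])
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"trace CSV {path}: time column is not strictly increasing")
    return ThTTrace(times=times, intensity=intensity, label=label,
                    normalized=normalized)


def write_frames_csv(frames: Sequence[SimFrame], positions: np.ndarray,
                     path: str | Path, header: dict | None = None) -> None:
    """Write FDF frames in long format: t, cell_id, x, y, z, state, tht."""
    path = Path(path)
    positions = np.atleast_2d(positions)
    with path.open("w", newline="") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(["t_min", "cell_id", "x_um", "y_um", "z_um",
                         "state", "tht"])
        for frame in frames:
            for i in range(positions.shape[0]):
                writer.writerow([
                    _FLOAT_FMT % frame.t, i,
                    _FLOAT_FMT % positions[i, 0],
                    _FLOAT_FMT % positions[i, 1],
                    _FLOAT_FMT % positions[i, 2],
                    CellState.NAMES[int(frame.states[i])],
                    _FLOAT_FMT % frame.tht[i],
                ])


def read_frames_csv(path: str | Path) -> tuple[list[SimFrame], np.ndarray]:
    """Read long-format frames CSV; returns (frames, cell positions)."""
    path = Path(path)
    state_codes = {v: k for k, v in CellState.NAMES.items()}
    by_time: dict[float, list[tuple[int, str, float]]] = {}
    pos: dict[int, tuple[float, float, float]] = {}
    with path.open() as fh:
        reader = csv.reader(
            row for row in fh if row.strip() and not row.startswith("#")
        )
        header = next(reader, None)
        if header is None:
            raise ValueError(f"frames CSV {path} is empty")
        required = ["t_min", "cell_id", "x_um", "y_um", "z_um", "state", "tht"]
        for col in required:
            if col not in header:
                raise ValueError(f"frames CSV {path} is missing column '{col}'")
        ix = {c: header.index(c) for c in required}
        for row in reader:
            t = float(row[ix["t_min"]])
            cid = int(row[ix["cell_id"]])
            pos[cid] = (float(row[ix["x_um"]]), float(row[ix["y_um"]]),
                        float(row[ix["z_um"]]))
            by_time.setdefault(t, []).append(
                (cid, row[ix["state"]], float(row[ix["tht"]]))
            )
    n = max(pos) + 1
    positions = np.zeros((n, 3))
    for cid, xyz in pos.items():
        positions[cid] = xyz
    frames = []
    for t in sorted(by_time):
        states = np.zeros(n, dtype=np.int8)
        tht = np.zeros(n)
        for cid, state, value in by_time[t]:
            states[cid] = state_codes[state]
            tht[cid] = value
        frames.append(SimFrame(
            t=t, states=states, tht=tht, global_tht=float(tht.mean()),
            released_mass=0.0, field_mass=0.0,
        ))
    return frames, positions


def write_track_csv(tracks: Sequence[WavefrontTrack], path: str | Path) -> None:
    """Write wavefront tracks as CSV: phase, time_min, R_um."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phase", "time_min", "R_um"])
        for track in tracks:
            for t, r in zip(track.times, track.R):
                writer.writerow([track.phase, _FLOAT_FMT % t, _FLOAT_FMT % r])


def read_track_csv(path: str | Path) -> list[WavefrontTrack]:
    """Read tracks written by :func:`write_track_csv`."""
    path = Path(path)
    groups: dict[str, list[tuple[float, float]]] = {}
    with path.open() as fh:
        reader = csv.reader(row for row in fh if row.strip())
        header = next(reader)
        for col in ("phase", "time_min", "R_um"):
            if col not in header:
                raise ValueError(f"track CSV {path} is missing column '{col}'")
        ix = {c: header.index(c) for c in header}
        for row in reader:
            groups.setdefault(row[ix["phase"]], []).append(
                (float(row[ix["time_min"]]), float(row[ix["R_um"]]))
            )
    tracks = []
    for phase, rows in groups.items():
        rows.sort()
        tracks.append(WavefrontTrack(
            times=np.array([r[0] for r in rows]),
            R=np.array([r[1] for r in rows]),
            phase=phase, source=str(path),
        ))
    return tracks


def write_fits_json(fits: Sequence[PowerLawFit], path: str | Path,
                    extra: dict | None = None) -> None:
    """Write power-law fits as JSON records
    {phase, Rc, b, gamma, sds, n_points}."""
    records = [
        {
            "phase": fit.phase,
            "Rc": fit.Rc,
            "b": fit.b,
            "gamma": fit.gamma,
            "sds": {"Rc": fit.Rc_sd, "b": fit.b_sd, "gamma": fit.gamma_sd},
            "residual_norm": fit.residual_norm,
            "n_points": fit.n_points,
        }
        for fit in fits
    ]
    payload: dict = {"fits": records}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
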