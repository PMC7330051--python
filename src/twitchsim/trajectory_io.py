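"""Readers and writers for trajectories, events, observables and config.

The canonical trajectory format is a text extended-XYZ dialect, one
block per frame::

    <n_spheres>
    time=<t> box=<L> columns=x,y,x_unwrapped,y_unwrapped,twitcher_id,sphere_idx,phase,anchor_x,anchor_y
    <x> <y> <xu> <yu> <tid> <sidx> <R|E|T> [<ax> <ay>]

Positions are written with 17 significant digits so a write/read
round-trip is lossless for float64.  The anchor columns are present only
on rows of retracting twitchers (anchors are stored wrapped).
Observables are emitted as CSV with ``# key=value`` comment headers;
configurations are YAML mappings mirroring the parameter field names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .kinematics import com_positions, polar_vectors
from .params import Phase, SPHERES_PER_TWITCHER, SimulationParams, twitcher_area
from .trajectory import Trajectory

__all__ = [
    "TrajectoryWriter",
    "TrajectoryParseError",
    "read_trajectory",
    "iter_frames",
    "write_events",
    "read_events",
    "load_config",
    "save_config",
    "write_observable",
    "read_observable",
]

_COLUMNS = (
    "x,y,x_unwrapped,y_unwrapped,twitcher_id,sphere_idx,phase,anchor_x,anchor_y"
)


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""


class TrajectoryWriter:
    """Streaming frame writer for the text trajectory format."""

    def __init__(self, path):
        self._fh = open(path, "w")
        self._n_frames = 0

    def write_frame_arrays(self, t, pos, posu, phase, anchor, params):
        fh = self._fh
        n = pos.shape[0]
        fh.write(f"{n}\n")
        fh.write(f"time={t!r} box={params.box_L!r} columns={_COLUMNS}\n")
        for i in range(n):
            g = i // SPHERES_PER_TWITCHER
            ph = Phase(int(phase[g])).letter
            row = (
                f"{pos[i, 0]:.17g} {pos[i, 1]:.17g} "
                f"{posu[i, 0]:.17g} {posu[i, 1]:.17g} "
                f"{g} {i % SPHERES_PER_TWITCHER} {ph}"
            )
            if ph == "T":
                row += f" {anchor[g, 0]:.17g} {anchor[g, 1]:.17g}"
            fh.write(row + "\n")
        self._n_frames += 1

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


@dataclass
class RawFrame:
    """One parsed frame at sphere resolution."""

    time: float
    box_L: float
    pos: np.ndarray
    pos_unwrapped: np.ndarray
    twitcher_id: np.ndarray
    sphere_idx: np.ndarray
    phase: np.ndarray  # per twitcher, int8
    anchor: np.ndarray  # per twitcher, NaN when absent


def iter_frames(path):
    """Yield :class:`RawFrame` objects from a trajectory file.

    Raises :class:`TrajectoryParseError` naming the frame index and
    line number on malformed or truncated input.
    """
    with open(path) as fh:
        lineno = 0
        frame_idx = 0
        while True:
            header = fh.readline()
            lineno += 1
            if header == "":
                return
            header = header.strip()
            if not header:
                continue
            try:
                n = int(header)
            except ValueError:
                raise TrajectoryParseError(
                    f"line {lineno}: expected sphere count, got {header!r}"
                ) from None
            comment = fh.readline()
            lineno += 1
            if comment == "":
                raise TrajectoryParseError(
                    f"frame {frame_idx}: truncated at line {lineno} (missing comment)"
                )
            kv = {}
            for tok in comment.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    kv[k] = v
            try:
                t = float(kv["time"])
                box = float(kv["box"])
            except (KeyError, ValueError):
                raise TrajectoryParseError(
                    f"frame {frame_idx}: bad comment line at line {lineno}"
                ) from None
            n_tw = n // SPHERES_PER_TWITCHER
            pos = np.empty((n, 2))
            posu = np.empty((n, 2))
            tid = np.empty(n, dtype=np.int64)
            sidx = np.empty(n, dtype=np.int64)
            phase = np.zeros(n_tw, dtype=np.int8)
            anchor = np.full((n_tw, 2), np.nan)
            for i in range(n):
                line = fh.readline()
                lineno += 1
                if line == "":
                    raise TrajectoryParseError(
                        f"frame {frame_idx}: truncated at line {lineno} "
                        f"(expected {n} rows, got {i})"
                    )
                parts = line.split()
                if len(parts) not in (7, 9):
                    raise TrajectoryParseError(
                        f"frame {frame_idx}: line {lineno} has {len(parts)} fields"
                    )
                try:
                    pos[i] = float(parts[0]), float(parts[1])
                    posu[i] = float(parts[2]), float(parts[3])
                    tid[i] = int(parts[4])
                    sidx[i] = int(parts[5])
                    ph = Phase.from_letter(parts[6])
                except ValueError as e:
                    raise TrajectoryParseError(
                        f"frame {frame_idx}: line {lineno}: {e}"
                    ) from None
                g = tid[i]
                phase[g] = int(ph)
                if len(parts) == 9:
                    anchor[g] = float(parts[7]), float(parts[8])
            yield RawFrame(t, box, pos, posu, tid, sidx, phase, anchor)
            frame_idx += 1


def read_trajectory(path, params: SimulationParams | None = None) -> Trajectory:
    """Read a trajectory file into the per-twitcher container.

    An empty file yields an empty trajectory.  The centre of mass and
    polar orientation are recomputed from the stored unwrapped sphere
    positions, so analysis from file matches analysis in memory exactly.
    """
    times, coms, pols, phases = [], [], [], []
    box = None
    for fr in iter_frames(path):
        box = fr.box_L
        times.append(fr.time)
        coms.append(com_positions(fr.pos_unwrapped))
        pols.append(polar_vectors(fr.pos_unwrapped))
        phases.append(fr.phase)
    if not times:
        return Trajectory(
            times=np.zeros(0), com=np.zeros((0, 0, 2)),
            polar=np.zeros((0, 0, 2)), phase=np.zeros((0, 0), dtype=np.int8),
            box_L=params.box_L if params else 100.0,
            a_twitch=twitcher_area(params),
        )
    return Trajectory(
        times=np.asarray(times),
        com=np.stack(coms),
        polar=np.stack(pols),
        phase=np.stack(phases),
        box_L=box,
        a_twitch=twitcher_area(params),
    )


# ----------------------------------------------------------------------
# Event ledger
# ----------------------------------------------------------------------

def write_events(path, events) -> None:
    df = pd.DataFrame(
        [(e.twitcher, e.kind, e.time) for e in (events or [])],
        columns=["twitcher", "kind", "time"],
    )
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------

def load_config(path) -> SimulationParams:
    """Read a YAML mapping of parameter names into SimulationParams."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of parameter names")
    return SimulationParams.from_dict(data)


def save_config(path, params: SimulationParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# ----------------------------------------------------------------------
# Observable tables
# ----------------------------------------------------------------------

def write_observable(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a statistic as CSV with ``# key=value`` header comments."""
    buf = io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}={v}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_observable(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    return df, meta
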