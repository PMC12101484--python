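"""Readers and writers for the package's file dialects.

* TrackMate-style spot tables (CSV with TRACK_ID, FRAME, POSITION_X,
  POSITION_Y, optional POSITION_T and AREA; TrackMate's extra sub-header
  rows are tolerated, frame indexing is normalized to 0-based);
* extended-XYZ trajectories and a columnar dump dialect
  (id chain active x y z vx vy vz) for simulation snapshots;
* flat key=value configuration files mirroring SimulationParameters;
* JSON run-metadata sidecars.

Numeric round-trips are lossless: floats are written with 17 significant
digits (%.17g), which reproduces float64 exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .motility import DEFAULT_FRAME_INTERVAL, Track
from .sim import SimulationParameters, SystemState, TrajectoryDump

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_xyz",
    "write_xyz",
    "read_dump",
    "write_dump",
    "read_config",
    "write_config",
    "write_metadata",
]

REQUIRED_TRACK_COLUMNS = ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y")


# ---------------------------------------------------------------------------
# TrackMate-style tables


def read_tracks(path, frame_interval: float | None = None,
                return_report: bool = False):
    """Read a TrackMate-style CSV into Track objects.

    Non-numeric sub-header rows (TrackMate exports carry up to three) and
    rows with missing or non-finite coordinates are dropped and counted.
    1-based frame numbering is auto-detected (minimum frame over the file is
    1 and no track repeats a frame) and shifted to 0-based.  When
    POSITION_T is absent, times come from ``frame_interval`` (default
    1/2.3 s).  With return_report=True, returns (tracks, report dict).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    n_raw = len(df)
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    core = list(REQUIRED_TRACK_COLUMNS)
    ok = np.isfinite(df[core].to_numpy(dtype=float)).all(axis=1)
    dropped = int((~ok).sum())
    df = df[ok]
    if len(df) == 0:
        return ([], {"rows": n_raw, "dropped": dropped, "frame_offset": 0}) \
            if return_report else []
    frame_offset = 1 if df["FRAME"].min() == 1 else 0
    fi = DEFAULT_FRAME_INTERVAL if frame_interval is None else float(frame_interval)
    tracks = []
    for tid, g in df.groupby("TRACK_ID"):
        g = g.sort_values("FRAME")
        if len(g) < 2:
            dropped += len(g)
            continue
        frames = g["FRAME"].to_numpy(dtype=int) - frame_offset
        times = None
        if "POSITION_T" in g.columns and np.isfinite(g["POSITION_T"]).all():
            times = g["POSITION_T"].to_numpy(dtype=float)
        areas = None
        if "AREA" in g.columns and np.isfinite(g["AREA"]).all():
            areas = g["AREA"].to_numpy(dtype=float)
        tracks.append(Track(int(tid), frames,
                            g["POSITION_X"].to_numpy(dtype=float),
                            g["POSITION_Y"].to_numpy(dtype=float),
                            times=times, areas=areas, frame_interval=fi))
    report = {"rows": n_raw, "dropped": dropped, "frame_offset": frame_offset}
    return (tracks, report) if return_report else tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks as a TrackMate-style CSV (0-based frames)."""
    rows = []
    for t in tracks:
        for i in range(len(t)):
            row = {"TRACK_ID": t.track_id, "FRAME": int(t.frames[i]),
                   "POSITION_X": "%.17g" % t.x[i],
                   "POSITION_Y": "%.17g" % t.y[i],
                   "POSITION_T": "%.17g" % t.times[i]}
            if t.areas is not None:
                row["AREA"] = "%.17g" % t.areas[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trajectory dialects


def _state_arrays(state: SystemState):
    act = state.active_chain[state.chain_id].astype(int)
    return state.positions, state.velocities, state.chain_id, act


def write_xyz(dump: TrajectoryDump, path) -> None:
    """Extended-XYZ trajectory: lattice, per-bead pos/velo/chain/active."""
    b = dump.params.box
    lattice = ("%.17g 0.0 0.0 0.0 %.17g 0.0 0.0 0.0 %.17g" % tuple(b))
    props = "species:S:1:pos:R:3:velo:R:3:id:I:1:chain:I:1:active:I:1"
    with open(path, "w") as fh:
        for state in dump.snapshots:
            pos, vel, cid, act = _state_arrays(state)
            fh.write(f"{state.n_beads}\n")
            fh.write(f'Lattice="{lattice}" Properties={props} '
                     f"step={state.step}\n")
            for i in range(state.n_beads):
                fh.write(
                    "B %.17g %.17g %.17g %.17g %.17g %.17g %d %d %d\n"
                    % (pos[i, 0], pos[i, 1], pos[i, 2],
                       vel[i, 0], vel[i, 1], vel[i, 2], i, cid[i], act[i]))


def read_xyz(path, params: SimulationParameters | None = None) -> TrajectoryDump:
    """Read an extended-XYZ trajectory written by write_xyz."""
    lines = Path(path).read_text().splitlines()
    snapshots, steps = [], []
    box = None
    k, frame = 0, 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as e:
            raise FormatError(f"frame {frame}: bad atom count line") from e
        if k + 1 + n >= len(lines) + 1 and n > 0 and k + 1 + n > len(lines):
            raise FormatError(f"frame {frame}: truncated ({n} atoms expected)")
        header = lines[k + 1]
        step = 0
        for tok in header.split():
            if tok.startswith("step="):
                step = int(tok.split("=")[1])
        if 'Lattice="' in header:
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box = (float(lat[0]), float(lat[4]), float(lat[8]))
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        cid = np.empty(n, dtype=int)
        act = np.empty(n, dtype=int)
        for i in range(n):
            try:
                f = lines[k + 2 + i].split()
                pos[i] = [float(f[1]), float(f[2]), float(f[3])]
                vel[i] = [float(f[4]), float(f[5]), float(f[6])]
                cid[i], act[i] = int(f[8]), int(f[9])
            except (IndexError, ValueError) as e:
                raise FormatError(f"frame {frame}: malformed atom line {i}") from e
        snapshots.append(_assemble_state(pos, vel, cid, act, step))
        steps.append(step)
        k += 2 + n
        frame += 1
    return _assemble_dump(snapshots, steps, box, params)


def write_dump(dump: TrajectoryDump, path) -> None:
    """Columnar dump dialect: '# step N' header then id chain active x y z vx vy vz."""
    b = dump.params.box
    with open(path, "w") as fh:
        fh.write("# box %.17g %.17g %.17g\n" % tuple(b))
        for state in dump.snapshots:
            pos, vel, cid, act = _state_arrays(state)
            fh.write(f"# step {state.step} beads {state.n_beads}\n")
            for i in range(state.n_beads):
                fh.write("%d %d %d %.17g %.17g %.17g %.17g %.17g %.17g\n"
                         % (i, cid[i], act[i], pos[i, 0], pos[i, 1], pos[i, 2],
                            vel[i, 0], vel[i, 1], vel[i, 2]))


def read_dump(path, params: SimulationParameters | None = None) -> TrajectoryDump:
    """Read a columnar dump written by write_dump."""
    lines = Path(path).read_text().splitlines()
    box = None
    snapshots, steps = [], []
    k, frame = 0, 0
    while k < len(lines):
        line = lines[k].strip()
        if not line:
            k += 1
            continue
        if line.startswith("# box"):
            f = line.split()
            box = (float(f[2]), float(f[3]), float(f[4]))
            k += 1
            continue
        if not line.startswith("# step"):
            raise FormatError(f"frame {frame}: expected '# step' header")
        f = line.split()
        step, n = int(f[2]), int(f[4])
        if k + 1 + n > len(lines):
            raise FormatError(f"frame {frame}: truncated ({n} beads expected)")
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        cid = np.empty(n, dtype=int)
        act = np.empty(n, dtype=int)
        for i in range(n):
            try:
                g = lines[k + 1 + i].split()
                cid[i], act[i] = int(g[1]), int(g[2])
                pos[i] = [float(g[3]), float(g[4]), float(g[5])]
                vel[i] = [float(g[6]), float(g[7]), float(g[8])]
            except (IndexError, ValueError) as e:
                raise FormatError(f"frame {frame}: malformed bead line {i}") from e
        snapshots.append(_assemble_state(pos, vel, cid, act, step))
        steps.append(step)
        k += 1 + n
        frame += 1
    return _assemble_dump(snapshots, steps, box, params)


def _assemble_state(pos, vel, cid, act, step) -> SystemState:
    chains, first = np.unique(cid, return_index=True)
    head = np.zeros(len(cid), dtype=bool)
    boundaries = np.flatnonzero(np.diff(cid, prepend=cid[0] - 1) != 0) \
        if len(cid) else np.array([], int)
    head[boundaries] = True
    active_chain = np.zeros(len(chains), dtype=bool)
    active_chain[np.searchsorted(chains, cid[first])] = act[first].astype(bool)
    return SystemState(pos, vel, cid, head, active_chain, step)


def _assemble_dump(snapshots, steps, box, params) -> TrajectoryDump:
    if params is None:
        if snapshots:
            n_chains = snapshots[0].n_chains
            bpc = snapshots[0].n_beads // max(n_chains, 1)
        else:
            n_chains, bpc = 1, 1
        params = SimulationParameters(
            n_chains=max(n_chains, 1), beads_per_chain=max(bpc, 1),
            box=box if box else (64.0, 64.0, 100.0),
            total_steps=max(steps[-1], 1) if steps else 1,
            dump_every=max(steps[1] - steps[0], 1) if len(steps) > 1 else 1)
    dump = TrajectoryDump(params=params)
    for s in snapshots:
        dump.append(s)
    return dump


# ---------------------------------------------------------------------------
# config and metadata


def read_config(path) -> SimulationParameters:
    """Flat key = value file mirroring SimulationParameters field names."""
    d = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        if key == "box":
            d[key] = tuple(float(x) for x in val.replace(",", " ").split())
        elif key in ("lj_shift",):
            d[key] = val.lower() in ("1", "true", "yes")
        elif key in ("n_chains", "beads_per_chain", "bias_steps", "total_steps",
                     "dump_every", "analysis_start", "seed"):
            d[key] = int(float(val))
        else:
            d[key] = float(val)
    return SimulationParameters.from_dict(d)


def write_config(params: SimulationParameters, path) -> None:
    with open(path, "w") as fh:
        for key, val in params.to_dict().items():
            if isinstance(val, list):
                val = " ".join("%.17g" % float(v) for v in val)
            fh.write(f"{key} = {val}\n")


def write_metadata(params: SimulationParameters, path, **extra) -> None:
    from . import __version__
    meta = {"package": "actophase", "version": __version__,
            "params": params.to_dict()}
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
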