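"""File interfaces: trajectory tables, event tables, profile configs, manifests.

On disk everything is plain text: comma-separated tables with a header row
('.' decimal), flat key-value config files for profile parameters, and
JSON run manifests.  Units are normalised at this boundary: lengths in um,
times in s, rates in 1/s.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import Geometry, ProfileParams
from .trajectory import Trajectory

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]

_CONFIG_KEYS = [
    "L_wall",
    "L_bulk",
    "l_plus",
    "l_minus",
    "lambda_wall",
    "lambda_bulk",
    "l_lambda",
    "y_col",
    "W",
    "a",
]


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory table (track_id, frame, t_s, x_um, y_um).

    Rows are sorted per track by frame; duplicate (track, frame) pairs,
    non-monotone times and missing columns raise ValueError.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        dup = frames[:-1][np.diff(frames) == 0]
        if dup.size:
            raise ValueError(f"duplicate frame {int(dup[0])} in track {tid}")
        t = grp["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone time in track {tid}")
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        out.append(Trajectory(track_id=int(tid), t=t, xy=xy))
    return out


def write_trajectories(path, trajectories) -> None:
    rows = []
    for traj in trajectories:
        n = len(traj)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": np.full(n, traj.track_id, dtype=int),
                    "frame": np.arange(n),
                    "t_s": traj.t,
                    "x_um": traj.xy[:, 0],
                    "y_um": traj.xy[:, 1],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_events(path, events) -> None:
    """Write detected jump events (one row per event, all fields)."""
    pd.DataFrame([vars(e) for e in events]).to_csv(path, index=False)


def write_true_events(path, trajectories) -> None:
    """Sidecar table of ground-truth jumps from labelled trajectories."""
    rows = []
    for traj in trajectories:
        for ev in traj.events:
            rows.append(
                {
                    "track_id": traj.track_id,
                    "frame_start": ev.frame_start,
                    "frame_end": ev.frame_end,
                    "x0_um": ev.x0,
                    "y0_um": ev.y0,
                    "dx_um": ev.dx,
                    "dy_um": ev.dy,
                    "censored": ev.censored,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def parse_profile_config(text: str) -> tuple[ProfileParams, Geometry]:
    """Parse a flat key-value profile config (``key = value`` lines)."""
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        values[key] = float(raw)
    missing = [k for k in _CONFIG_KEYS if k not in values]
    if missing:
        raise ValueError(f"profile config missing keys: {missing}")
    params = ProfileParams(
        L_wall=values["L_wall"],
        L_bulk=values["L_bulk"],
        l_plus=values["l_plus"],
        l_minus=values["l_minus"],
        lambda_wall=values["lambda_wall"],
        lambda_bulk=values["lambda_bulk"],
        l_lambda=values["l_lambda"],
        y_col=values["y_col"],
    )
    geometry = Geometry(half_width=values["W"], colloid_radius=values["a"], wall_offset=values["y_col"])
    return params, geometry


def read_profile_config(path) -> tuple[ProfileParams, Geometry]:
    return parse_profile_config(Path(path).read_text())


def write_profile_config(path, params: ProfileParams, geometry: Geometry) -> None:
    lines = [
        f"L_wall = {params.L_wall!r}",
        f"L_bulk = {params.L_bulk!r}",
        f"l_plus = {params.l_plus!r}",
        f"l_minus = {params.l_minus!r}",
        f"lambda_wall = {params.lambda_wall!r}",
        f"lambda_bulk = {params.lambda_bulk!r}",
        f"l_lambda = {params.l_lambda!r}",
        f"y_col = {params.y_col!r}",
        f"W = {geometry.half_width!r}",
        f"a = {geometry.colloid_radius!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_tabulated_field(path, y_centres, lam, L_plus, L_minus) -> None:
    pd.DataFrame(
        {
            "y_bin_centre_um": y_centres,
            "lambda_per_s": lam,
            "L_plus_um": L_plus,
            "L_minus_um": L_minus,
        }
    ).to_csv(path, index=False)


def read_tabulated_field(path, geometry: Geometry):
    from .profiles import TabulatedField

    df = pd.read_csv(path)
    return TabulatedField(
        df["y_bin_centre_um"], df["lambda_per_s"], df["L_plus_um"], df["L_minus_um"], geometry
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, subcommand: str, config: dict, seed, inputs=(), outputs=()) -> None:
    """Record what a run did: config snapshot, seed, file digests, version."""
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "config": config,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): _digest(p) for p in inputs},
        "outputs": {str(p): _digest(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
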