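"""File formats: tracking tables, point clouds, AGETs, parameters, chains.

Dialects
--------
* tracks CSV — header ``track_id,frame,x,y,z``; frames 1-based, positions µm.
* cloud CSV — header ``x,y,z,tbxta,tbx16,tbx6,wnt,fgf`` (position-only
  clouds omit the channel columns); also ASCII PLY with the same scalar
  vertex properties.
* AGET CSV — header ``track_id,frame,tbxta,tbx16,tbx6,wnt,fgf``, one row per
  cell per frame.
* parameters — JSON with named blocks W (3x3, regulator-major), E (2x3),
  R, lam, h; exactly 24 scalars.
* chains — HDF5 with samples, log-probabilities, acceptance fractions and a
  config snapshot.

Values round-trip at full float precision (written via ``repr``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .agets import AGETSet
from .cloud import ExpressionPointCloud
from .inference import PosteriorEnsemble
from .model import GRNParameters
from .schema import CHANNELS, SchemaError
from .tracks import CellTrackSet, TrackError

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tracks


def read_tracks(path: str | Path, frame_interval_min: float = 2.0) -> CellTrackSet:
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:
        raise ParseError(f"{path}: {e}") from e
    required = ["track_id", "frame", "x", "y", "z"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    try:
        return CellTrackSet(table, frame_interval_min=frame_interval_min)
    except TrackError as e:
        raise ParseError(f"{path}: {e}") from e


def write_tracks(tracks: CellTrackSet, path: str | Path) -> None:
    t = tracks.table.copy()
    t.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# clouds


def read_cloud(path: str | Path) -> ExpressionPointCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_cloud_ply(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:
        raise ParseError(f"{path}: {e}") from e
    for c in ("x", "y", "z"):
        if c not in table.columns:
            raise ParseError(f"{path}: missing position column {c!r}")
    channels = {
        c: table[c].to_numpy(float) for c in table.columns if c not in ("x", "y", "z")
    }
    unknown = [c for c in channels if c.lower() not in CHANNELS]
    if unknown:
        raise ParseError(f"{path}: unknown channel columns {unknown}")
    return ExpressionPointCloud(
        table[["x", "y", "z"]].to_numpy(float),
        channels,
        metadata={"path": str(path)},
    )


def write_cloud(cloud: ExpressionPointCloud, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _write_cloud_ply(cloud, path)
        return
    cols = {"x": cloud.positions[:, 0], "y": cloud.positions[:, 1],
            "z": cloud.positions[:, 2]}
    for name in CHANNELS:
        if name in cloud.channels:
            cols[name] = cloud.channels[name]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_cloud_ply(cloud: ExpressionPointCloud, path: Path) -> None:
    names = [c for c in CHANNELS if c in cloud.channels]
    cols = [cloud.positions[:, i] for i in range(3)] + [
        cloud.channels[c] for c in names
    ]
    props = ["x", "y", "z"] + names
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        for p in props:
            fh.write(f"property double {p}\n")
        fh.write("end_header\n")
        for row in zip(*cols):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_cloud_ply(path: Path) -> ExpressionPointCloud:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ParseError(f"{path}: not a PLY file")
        n_vertex, props = 0, []
        fmt = None
        for line in fh:
            line = line.strip()
            if line.startswith("format"):
                fmt = line.split()[1]
            elif line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        if fmt != "ascii":
            raise ParseError(f"{path}: only ASCII PLY is supported")
        data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    if data.shape != (n_vertex, len(props)):
        raise ParseError(f"{path}: vertex data does not match header")
    cols = dict(zip(props, data.T))
    for c in ("x", "y", "z"):
        if c not in cols:
            raise ParseError(f"{path}: missing vertex property {c!r}")
    channels = {k: v for k, v in cols.items() if k not in ("x", "y", "z")}
    return ExpressionPointCloud(
        np.column_stack([cols["x"], cols["y"], cols["z"]]),
        channels,
        metadata={"path": str(path)},
    )


# ---------------------------------------------------------------------------
# AGETs


def write_agets(agets: AGETSet, path: str | Path) -> None:
    n_cells, n_frames, _ = agets.values.shape
    rows = {
        "track_id": np.repeat(agets.track_ids, n_frames),
        "frame": np.tile(np.arange(1, n_frames + 1), n_cells),
    }
    flat = agets.values.reshape(-1, len(CHANNELS))
    for i, c in enumerate(CHANNELS):
        rows[c] = flat[:, i]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_agets(path: str | Path) -> AGETSet:
    """Load an AGET table; cells missing any frame are dropped with a warning
    (they are ineligible for fitting)."""
    import logging

    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    required = ["track_id", "frame", *CHANNELS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    n_frames = int(table["frame"].max())
    counts = table.groupby("track_id")["frame"].agg(["size", "min", "max"])
    complete = counts[
        (counts["size"] == n_frames) & (counts["min"] == 1) & (counts["max"] == n_frames)
    ].index.to_numpy()
    dropped = set(counts.index) - set(complete)
    if dropped:
        logging.getLogger(__name__).warning(
            "%s: dropping %d incomplete cells (fitting-ineligible)",
            path, len(dropped),
        )
    table = table[table["track_id"].isin(complete)].sort_values(["track_id", "frame"])
    values = table[list(CHANNELS)].to_numpy(float).reshape(
        len(complete), n_frames, len(CHANNELS)
    )
    return AGETSet(np.sort(complete).astype(int), values, provenance={"path": str(path)})


# ---------------------------------------------------------------------------
# parameters and chains


def read_params(path: str | Path) -> GRNParameters:
    try:
        return GRNParameters.from_json(Path(path).read_text())
    except (json.JSONDecodeError, SchemaError, ValueError) as e:
        raise ParseError(f"{path}: {e}") from e


def write_params(params: GRNParameters, path: str | Path) -> None:
    Path(path).write_text(params.to_json() + "\n")


def write_chain(ensemble: PosteriorEnsemble, path: str | Path, config: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("chain", data=ensemble.chain)
        fh.create_dataset("log_prob", data=ensemble.log_prob)
        fh.create_dataset("acceptance_fraction", data=ensemble.acceptance_fraction)
        fh.attrs["converged"] = bool(ensemble.converged)
        fh.attrs["metadata"] = json.dumps(ensemble.metadata)
        if config is not None:
            fh.attrs["config"] = json.dumps(config)


def read_chain(path: str | Path) -> PosteriorEnsemble:
    with h5py.File(path, "r") as fh:
        return PosteriorEnsemble(
            chain=fh["chain"][()],
            log_prob=fh["log_prob"][()],
            acceptance_fraction=fh["acceptance_fraction"][()],
            converged=bool(fh.attrs.get("converged", False)),
            metadata=json.loads(fh.attrs.get("metadata", "{}")),
        )
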