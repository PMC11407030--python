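"""Building AGETs: project fixed-sample expression onto tracked cells.

For every frame of the lapse, each aligned source cloud is moved into the
frame's coordinate system with that frame's registration transform; each
tracked cell is then assigned, per channel, a statistic (median by default)
of its n nearest source nuclei, and the per-source statistics are combined
across sources with the same statistic (median of medians).  Repeating this
over all frames yields one approximated trajectory per cell.

Distances are Euclidean in the target frame's coordinates.  Ties at the
n-th neighbour are broken deterministically by lowest source-point index.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .agets import AGETSet
from .cloud import ExpressionPointCloud
from .processing import ap_profile
from .registration import AlignmentResult, rescale_ap
from .schema import CHANNELS, N_CHANNELS, channel_index
from .tracks import CellTrackSet

logger = logging.getLogger(__name__)

METHODS = ("median", "mean", "nearest")


class AssignmentError(ValueError):
    pass


class BuildError(RuntimeError):
    pass


@dataclass
class NeighborAssignment:
    """Per-source and combined channel statistics for the cells of one frame."""

    cell_ids: np.ndarray  # (n_cells,)
    per_source: np.ndarray  # (n_sources, n_cells, n_channels) M_ijk
    combined: np.ndarray  # (n_cells, n_channels) M_ik
    nearest_distance: np.ndarray  # (n_sources, n_cells) distance to 1st neighbour
    n_neighbors: int
    method: str


def _neighbor_stat(
    cells: np.ndarray,
    source: ExpressionPointCloud,
    n_neighbors: int,
    method: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(stat (n_cells, n_channels), nearest distance (n_cells,)) for one source."""
    if len(source) < n_neighbors:
        raise AssignmentError(
            f"source has {len(source)} points, fewer than n_neighbors={n_neighbors}"
        )
    d = cdist(cells, source.positions)
    # stable argsort: equal distances keep ascending source-point index
    order = np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]
    vals = np.stack([source.channel(c) for c in CHANNELS], axis=1)  # (n_src, 5)
    nbr_vals = vals[order]  # (n_cells, n_neighbors, 5)
    if method == "median":
        stat = np.median(nbr_vals, axis=1)
    elif method == "mean":
        stat = nbr_vals.mean(axis=1)
    elif method == "nearest":
        stat = nbr_vals[:, 0, :]
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    nearest = np.take_along_axis(d, order[:, :1], axis=1)[:, 0]
    return stat, nearest


def assign_frame_expression(
    target_frame: ExpressionPointCloud,
    aligned_sources: list[ExpressionPointCloud],
    n_neighbors: int = 5,
    method: str = "median",
) -> NeighborAssignment:
    """Assign every cell of one frame a combined per-channel statistic.

    Sources must already be in the target frame's coordinate system.  The
    across-source combination uses the same statistic family as the
    per-source one; for ``nearest`` the value comes from the source whose
    first neighbour is globally closest.
    """
    if not aligned_sources:
        raise AssignmentError("empty source list")
    if n_neighbors < 1:
        raise AssignmentError("n_neighbors must be >= 1")
    cells = target_frame.positions
    per_source = np.empty((len(aligned_sources), len(cells), N_CHANNELS))
    nearest = np.empty((len(aligned_sources), len(cells)))
    for j, src in enumerate(aligned_sources):
        per_source[j], nearest[j] = _neighbor_stat(cells, src, n_neighbors, method)
    if method == "median":
        combined = np.median(per_source, axis=0)
    elif method == "mean":
        combined = per_source.mean(axis=0)
    else:  # nearest: the source holding the globally closest point wins
        best = np.argmin(nearest, axis=0)
        combined = per_source[best, np.arange(len(cells))]
    ids = target_frame.metadata.get("track_ids", np.arange(len(cells)))
    return NeighborAssignment(
        cell_ids=np.asarray(ids),
        per_source=per_source,
        combined=combined,
        nearest_distance=nearest,
        n_neighbors=n_neighbors,
        method=method,
    )


def build_agets(
    tracks: CellTrackSet,
    sources: list[ExpressionPointCloud],
    alignments: dict[tuple[int, int], AlignmentResult],
    n_neighbors: int = 5,
    method: str = "median",
    min_sources: int = 3,
    track_ids: np.ndarray | None = None,
) -> AGETSet:
    """Assemble per-cell trajectories over every frame of the lapse.

    ``alignments`` maps (source index, frame) to that pair's AlignmentResult;
    only accepted alignments are used, and a frame must retain at least
    ``min_sources`` accepted sources (clamped to the number of sources).
    Each source is A-P-rescaled to the frame's extent before its transform
    is applied, matching how the transforms were fitted.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if track_ids is None:
        track_ids = tracks.eligible_track_ids()
    track_ids = np.asarray(track_ids, int)
    n_frames = tracks.n_frames
    min_sources = min(min_sources, len(sources))
    values = np.full((len(track_ids), n_frames, N_CHANNELS), np.nan)
    used_sources: set[int] = set()

    for frame in range(1, n_frames + 1):
        frame_cloud = tracks.frame_cloud(frame)
        moved = []
        for j, src in enumerate(sources):
            res = alignments.get((j, frame))
            if res is None or not res.accepted:
                continue
            # transforms are fitted on the A-P-rescaled source (see
            # registration.align); apply the same rescale before moving
            rescaled = rescale_ap(src, frame_cloud)
            moved.append(
                rescaled.with_positions(res.transform.apply(rescaled.positions))
            )
            used_sources.add(j)
        if len(moved) < min_sources:
            raise BuildError(
                f"frame {frame}: only {len(moved)} accepted sources "
                f"(minimum {min_sources})"
            )
        assignment = assign_frame_expression(frame_cloud, moved, n_neighbors, method)
        frame_ids = assignment.cell_ids
        pos = {tid: i for i, tid in enumerate(frame_ids)}
        for i, tid in enumerate(track_ids):
            if tid in pos:
                values[i, frame - 1] = assignment.combined[pos[tid]]

    if np.isnan(values).any():
        bad = track_ids[np.isnan(values).any(axis=(1, 2))]
        raise BuildError(f"incomplete trajectories for tracks {bad[:5].tolist()}")
    return AGETSet(
        track_ids,
        values,
        provenance={
            "n_neighbors": n_neighbors,
            "method": method,
            "source_ids": sorted(used_sources),
        },
    )


def tissue_pattern_profiles(
    agets: AGETSet,
    tracks: CellTrackSet,
    frame: int,
    window: int = 11,
    polyorder: int = 3,
    n_bins: int = 50,
) -> dict[str, np.ndarray]:
    """Per-channel smoothed A-P profiles of the AGET pattern at one frame.

    Cells are placed at their normalized A-P position for that frame and the
    channel values are profiled exactly as for a fixed sample, so tissue-level
    patterns are directly comparable with source-cloud profiles.
    """
    ids, p = tracks.normalized_ap_position(frame)
    keep = [i for i, tid in enumerate(ids) if tid in set(agets.track_ids)]
    if not keep:
        raise ValueError(f"no AGET cells present at frame {frame}")
    ids = ids[keep]
    p = p[np.asarray(keep)]
    row = {tid: i for i, tid in enumerate(agets.track_ids)}
    vals = agets.values[[row[tid] for tid in ids], frame - 1, :]
    positions = np.column_stack([p, np.zeros_like(p), np.zeros_like(p)])
    cloud = ExpressionPointCloud(
        positions,
        {c: vals[:, channel_index(c)] for c in CHANNELS},
        ap_normalized=True,
    )
    return {
        c: ap_profile(cloud, c, window=window, polyorder=polyorder, n_bins=n_bins)
        for c in CHANNELS
    }


def export_insilico_reporter(
    agets: AGETSet,
    tracks: CellTrackSet,
    channel: str,
    out_dir: str | Path,
) -> list[Path]:
    """Write one CSV (x,y,z,value) per frame: the in-silico reporter series."""
    ci = channel_index(channel)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row = {tid: i for i, tid in enumerate(agets.track_ids)}
    paths = []
    for frame in range(1, agets.n_frames + 1):
        ids, pos = tracks.frame_positions(frame)
        path = out_dir / f"{channel.lower()}_frame{frame:03d}.csv"
        try:
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["x", "y", "z", "value"])
                for tid, p in zip(ids, pos):
                    if tid in row:
                        v = agets.values[row[tid], frame - 1, ci]
                        writer.writerow(
                            [repr(float(p[0])), repr(float(p[1])),
                             repr(float(p[2])), repr(float(v))]
                        )
        except OSError as e:
            raise OSError(f"failed writing reporter frame to {path}: {e}") from e
        paths.append(path)
    return paths
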