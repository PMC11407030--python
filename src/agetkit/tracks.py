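"""Cell tracks: per-cell positions over consecutive time-lapse frames.

Tracks are the spatial skeleton that approximated gene expression
trajectories (AGETs) are painted onto.  Frames are 1-based.  A track is
*fitting-eligible* only if it spans every frame of the lapse with no gaps;
cells lost or gained mid-lapse are kept for visualization but excluded from
model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloud import ExpressionPointCloud


class TrackError(ValueError):
    pass


@dataclass
class CellTrackSet:
    """Tracking table with one row per (track, frame).

    ``table`` columns: track_id (int), frame (int, 1-based), x, y, z (µm).
    """

    table: pd.DataFrame
    frame_interval_min: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["track_id", "frame", "x", "y", "z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise TrackError(f"tracking table missing columns {missing}")
        t = self.table[required].copy()
        t["track_id"] = t["track_id"].astype(int)
        t["frame"] = t["frame"].astype(int)
        for c in ("x", "y", "z"):
            t[c] = pd.to_numeric(t[c], errors="raise").astype(float)
        if not np.all(np.isfinite(t[["x", "y", "z"]].to_numpy())):
            raise TrackError("tracking table contains non-finite positions")
        dup = t.duplicated(subset=["track_id", "frame"])
        if dup.any():
            rows = (t.index[dup] + 1).tolist()[:5]
            raise TrackError(f"duplicate (track, frame) pairs at rows {rows}")
        self.table = t.sort_values(["track_id", "frame"]).reset_index(drop=True)

    @property
    def track_ids(self) -> np.ndarray:
        return self.table["track_id"].unique()

    @property
    def n_frames(self) -> int:
        return int(self.table["frame"].max())

    @property
    def frames(self) -> np.ndarray:
        return np.arange(1, self.n_frames + 1)

    def eligible_track_ids(self) -> np.ndarray:
        """Tracks present at every frame 1..n_frames with no gaps."""
        n = self.n_frames
        counts = self.table.groupby("track_id")["frame"].agg(["min", "max", "size"])
        ok = (counts["min"] == 1) & (counts["max"] == n) & (counts["size"] == n)
        return counts.index[ok].to_numpy()

    def frame_positions(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(track_ids, positions) of all cells present at ``frame``."""
        sub = self.table[self.table["frame"] == frame]
        if sub.empty:
            raise TrackError(f"no cells at frame {frame}")
        return sub["track_id"].to_numpy(), sub[["x", "y", "z"]].to_numpy()

    def frame_cloud(self, frame: int) -> ExpressionPointCloud:
        """The frame's positions as a channel-free target point cloud."""
        ids, pos = self.frame_positions(frame)
        return ExpressionPointCloud(pos, metadata={"frame": frame, "track_ids": ids})

    def positions_for(self, track_ids: np.ndarray) -> np.ndarray:
        """(n_tracks, n_frames, 3) positions for eligible tracks only."""
        n = self.n_frames
        out = np.empty((len(track_ids), n, 3))
        grouped = self.table.set_index("track_id")
        for i, tid in enumerate(track_ids):
            sub = grouped.loc[[tid]].sort_values("frame")
            if len(sub) != n or sub["frame"].iloc[0] != 1:
                raise TrackError(f"track {tid} does not span all {n} frames")
            out[i] = sub[["x", "y", "z"]].to_numpy()
        return out

    def normalized_ap_position(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(track_ids, x / max x) for cells at ``frame``; 0 = posterior tip."""
        ids, pos = self.frame_positions(frame)
        xmax = pos[:, 0].max()
        if xmax <= 0:
            raise TrackError(f"degenerate frame {frame}: max x <= 0")
        return ids, pos[:, 0] / xmax
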