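"""The AGET container: per-cell, per-frame approximated channel values.

An approximated gene expression trajectory (AGET) assigns each tracked cell,
at each frame, a value for every channel (three T-box genes + Wnt and FGF),
obtained by projecting fixed-sample expression measurements onto the cell's
position.  AGETs serve double duty: they are the fitting target for the GRN
model and the source of its initial and signal boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import CHANNELS, N_CHANNELS, N_GENES, channel_index


@dataclass
class AGETSet:
    """Dense per-cell trajectories.

    values has shape (n_cells, n_frames, 5) with channel order
    (tbxta, tbx16, tbx6, wnt, fgf); frames are 1-based and contiguous.
    """

    track_ids: np.ndarray  # (n_cells,)
    values: np.ndarray  # (n_cells, n_frames, 5)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.track_ids = np.asarray(self.track_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != N_CHANNELS:
            raise ValueError(
                f"values must be (n_cells, n_frames, {N_CHANNELS}), "
                f"got {self.values.shape}"
            )
        if self.values.shape[0] != len(self.track_ids):
            raise ValueError("track_ids and values disagree on cell count")
        if np.isnan(self.values).any():
            raise ValueError("AGET values contain missing entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def genes(self) -> np.ndarray:
        """(n_cells, n_frames, 3) view of the gene channels."""
        return self.values[:, :, :N_GENES]

    @property
    def signals(self) -> np.ndarray:
        """(n_cells, n_frames, 2) view of the Wnt/FGF channels."""
        return self.values[:, :, N_GENES:]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, :, channel_index(name)]

    def cell(self, track_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.track_ids == track_id)
        if len(idx) == 0:
            raise KeyError(f"no AGET for track {track_id}")
        return self.values[idx[0]]

    def subset(self, track_ids: np.ndarray) -> "AGETSet":
        order = {tid: i for i, tid in enumerate(self.track_ids)}
        try:
            rows = [order[int(t)] for t in track_ids]
        except KeyError as e:
            raise KeyError(f"no AGET for track {e.args[0]}") from None
        return AGETSet(
            np.asarray(track_ids, int),
            self.values[rows].copy(),
            provenance=dict(self.provenance),
        )

    def copy(self) -> "AGETSet":
        return AGETSet(
            self.track_ids.copy(), self.values.copy(), dict(self.provenance)
        )


CHANNEL_ORDER = CHANNELS  # re-export for file headers
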