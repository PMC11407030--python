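"""Expression point clouds: nuclear positions plus per-nucleus channel values.

A cloud represents either one processed fixed sample (a *source*, carrying
measured expression channels) or one time-lapse frame (a *target*, often
position-only).  Positions are in micrometres with the posterior tip of the
tissue at the origin and x increasing toward the anterior, so the
anteroposterior (A-P) axis is the x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .schema import SchemaError


@dataclass
class ExpressionPointCloud:
    positions: np.ndarray  # (n, 3) float, micrometres
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    ap_normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions must be (n, 3), got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        n = len(self.positions)
        clean = {}
        for name, vals in self.channels.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n,):
                raise SchemaError(
                    f"channel {name!r} has {vals.shape[0] if vals.ndim else '?'}"
                    f" values for {n} points"
                )
            clean[name.lower()] = vals
        self.channels = clean

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def ap_length(self) -> float:
        """Extent along the A-P (x) axis, in the cloud's current units."""
        return float(self.x.max() - self.x.min())

    def channel(self, name: str) -> np.ndarray:
        key = name.lower()
        if key not in self.channels:
            raise SchemaError(
                f"cloud has no channel {name!r}; available: {sorted(self.channels)}"
            )
        return self.channels[key]

    def with_positions(self, positions: np.ndarray) -> "ExpressionPointCloud":
        return replace(
            self,
            positions=np.asarray(positions, dtype=float),
            channels={k: v.copy() for k, v in self.channels.items()},
            metadata={
                k: list(v) if isinstance(v, list) else v
                for k, v in self.metadata.items()
            },
        )

    def with_channels(self, channels: dict[str, np.ndarray]) -> "ExpressionPointCloud":
        return replace(
            self,
            positions=self.positions.copy(),
            channels={k.lower(): np.asarray(v, float) for k, v in channels.items()},
            metadata={
                k: list(v) if isinstance(v, list) else v
                for k, v in self.metadata.items()
            },
        )

    def copy(self) -> "ExpressionPointCloud":
        return replace(
            self,
            positions=self.positions.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            metadata=dict(self.metadata),
        )
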