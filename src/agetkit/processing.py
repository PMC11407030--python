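"""Numeric post-processing of expression point clouds.

Mirrors the image-analysis steps applied to segmented fixed samples once
per-nucleus intensities have been extracted: background thresholding per
channel, normalization of each channel by its Savitzky-Golay-smoothed
spatial maximum (so plateau height is 1 without being dragged up by bright
outlier nuclei), and normalization of the anteroposterior axis to [0, 1] by
dividing x by its maximum.  Normalization is always per sample, never pooled
across samples.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .cloud import ExpressionPointCloud
from .schema import SchemaError


class ProfileError(ValueError):
    pass


def apply_thresholds(
    cloud: ExpressionPointCloud, thresholds: dict[str, float]
) -> ExpressionPointCloud:
    """Zero out channel values strictly below each channel's lower bound."""
    channels = {k: v.copy() for k, v in cloud.channels.items()}
    for name, thr in thresholds.items():
        key = name.lower()
        if key not in channels:
            raise SchemaError(f"threshold for unknown channel {name!r}")
        if thr < 0:
            raise ValueError(f"threshold for {name!r} must be >= 0")
        vals = channels[key]
        channels[key] = np.where(vals < thr, 0.0, vals)
    out = cloud.with_channels(channels)
    out.metadata.setdefault("processing", []).append(
        {"step": "threshold", "thresholds": {k: float(v) for k, v in thresholds.items()}}
    )
    return out


def percentile_thresholds(
    cloud: ExpressionPointCloud, q: float = 20.0
) -> dict[str, float]:
    """Heuristic auto-thresholds: the q-th percentile of each channel.

    A stand-in for the visual threshold choice of the original pipeline;
    flag in provenance whenever used.
    """
    return {name: float(np.percentile(v, q)) for name, v in cloud.channels.items()}


def normalize_ap_axis(cloud: ExpressionPointCloud) -> ExpressionPointCloud:
    """Divide x by its maximum so A-P position lies in [0, 1]."""
    x = cloud.x
    xmax = x.max()
    if xmax <= 0:
        raise ValueError("cannot normalize A-P axis: max x <= 0")
    positions = cloud.positions.copy()
    positions[:, 0] = x / xmax
    out = cloud.with_positions(positions)
    out.ap_normalized = True
    out.metadata.setdefault("processing", []).append(
        {"step": "ap_normalize", "ap_length_um": float(xmax)}
    )
    return out


def ap_profile(
    cloud: ExpressionPointCloud,
    channel: str,
    window: int = 11,
    polyorder: int = 3,
    n_bins: int = 50,
    max_gap_bins: int = 5,
) -> np.ndarray:
    """Smoothed A-P expression profile of one channel.

    Values are binned by normalized A-P position into ``n_bins`` equal-width
    bins; bin means are Savitzky-Golay smoothed (window in bins).  Interior
    runs of empty bins up to ``max_gap_bins`` are linearly interpolated,
    longer gaps raise ProfileError.  Returns an (n_bins, 2) array of
    (bin-center position, smoothed value).
    """
    if not cloud.ap_normalized:
        raise ValueError("ap_profile requires an A-P-normalized cloud")
    if window % 2 != 1 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if n_bins < window:
        raise ValueError("n_bins must be >= window")
    vals = cloud.channel(channel)
    x = np.clip(cloud.x, 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=vals, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]

    if not nz.all():
        empty = ~nz
        runs = _run_lengths(empty)
        if runs and max(runs) > max_gap_bins:
            raise ProfileError(
                f"profile of {channel!r} has an empty-bin run of {max(runs)} "
                f"bins (limit {max_gap_bins})"
            )
        idx = np.arange(n_bins)
        means[empty] = np.interp(idx[empty], idx[nz], means[nz])

    smoothed = savgol_filter(means, window_length=window, polyorder=polyorder)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return np.column_stack([centers, smoothed])


def _run_lengths(mask: np.ndarray) -> list[int]:
    runs, current = [], 0
    for m in mask:
        if m:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def normalize_channels(
    cloud: ExpressionPointCloud,
    window: int = 11,
    polyorder: int = 3,
    n_bins: int = 50,
) -> ExpressionPointCloud:
    """Set each channel's smoothed spatial maximum to one.

    Each channel is divided by the maximum of its smoothed A-P profile, then
    capped at 1 (raw nuclei can exceed the smoothed plateau; the cap keeps
    the [0, 1] invariant).
    """
    channels = {}
    for name, vals in cloud.channels.items():
        prof = ap_profile(cloud, name, window=window, polyorder=polyorder, n_bins=n_bins)
        m = prof[:, 1].max()
        if m <= 0:
            raise ValueError(f"channel {name!r} has non-positive smoothed maximum")
        channels[name] = np.minimum(vals / m, 1.0)
    out = cloud.with_channels(channels)
    out.metadata.setdefault("processing", []).append(
        {"step": "normalize_channels", "window": window, "polyorder": polyorder}
    )
    return out
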