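"""Rigid registration of source clouds onto time-lapse frames.

Each fixed-sample source cloud is first rescaled so its anteroposterior
length matches the target frame's, then aligned by point-to-plane iterative
closest point (ICP): alternate (i) nearest-neighbour correspondence search
against the target and (ii) a linearized least-squares update of the rigid
transform that minimizes the residual component along the target's surface
normals.  Normals are estimated per target point from a local PCA plane fit
of its k nearest neighbours.

Alignment quality is gated numerically (inlier RMS distance and inlier
fraction) rather than by eye; sources that fail the gate for a frame are
excluded from that frame's expression assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .cloud import ExpressionPointCloud

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """4x4 homogeneous rigid-body transform (rotation + translation, µm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (4, 4):
            raise ValueError(f"transform must be 4x4, got {m.shape}")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation block determinant is not +1 (not a rotation)")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, float)
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rotation_translation(R, -R @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class AlignmentResult:
    transform: RigidTransform
    rms_residual: float  # inlier point-to-point RMS, µm
    inlier_fraction: float
    n_iterations: int
    accepted: bool = True
    history: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")
        if not 0.0 <= self.inlier_fraction <= 1.0:
            raise ValueError("inlier_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------


def rescale_ap(
    source: ExpressionPointCloud, target: ExpressionPointCloud
) -> ExpressionPointCloud:
    """Isotropically rescale the source so its A-P extent matches the target's.

    Scaling is about the origin (the posterior tip); applying the operation
    twice is a no-op because the first call already matches extents.
    """
    src_len = source.ap_length
    tgt_len = target.ap_length
    if src_len <= 0 or tgt_len <= 0:
        raise ValueError("cannot rescale: a cloud has zero A-P extent")
    factor = tgt_len / src_len
    out = source.with_positions(source.positions * factor)
    out.metadata["ap_rescale_factor"] = factor * source.metadata.get(
        "ap_rescale_factor", 1.0
    )
    return out


def estimate_normals(points: np.ndarray, k: int = 20) -> np.ndarray:
    """Unit normals from a local PCA plane fit of each point's k neighbours."""
    points = np.asarray(points, float)
    n = len(points)
    if n < k:
        raise RegistrationError(f"need at least {k} points to estimate normals")
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k)
    nbrs = points[idx]  # (n, k, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / k
    # smallest-eigenvalue eigenvector of each 3x3 covariance = plane normal
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]
    return normals / np.linalg.norm(normals, axis=1, keepdims=True)


def initial_alignment(
    source: ExpressionPointCloud, target: ExpressionPointCloud
) -> RigidTransform:
    """Coarse pre-alignment: match centroids and co-orient principal axes.

    Principal axes carry a sign ambiguity, so every proper-rotation sign
    combination (four candidates) plus a centroid-only translation is
    scored by mean nearest-neighbour distance and the cheapest wins.
    """
    sp, tp = source.positions, target.positions
    sc, tc = sp.mean(axis=0), tp.mean(axis=0)

    def axes(p, c):
        _, _, vt = np.linalg.svd(p - c, full_matrices=False)
        return vt.T  # columns = principal axes, descending variance

    A, B = axes(sp, sc), axes(tp, tc)
    if np.linalg.det(A) < 0:
        A[:, 2] *= -1.0
    if np.linalg.det(B) < 0:
        B[:, 2] *= -1.0
    tree = cKDTree(tp)
    candidates = [RigidTransform.from_rotation_translation(np.eye(3), tc - sc)]
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = B @ np.diag(signs) @ A.T
        candidates.append(
            RigidTransform.from_rotation_translation(R, tc - R @ sc)
        )
    costs = [tree.query(T.apply(sp))[0].mean() for T in candidates]
    return candidates[int(np.argmin(costs))]


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(R)
    out = u @ vt
    if np.linalg.det(out) < 0:
        u[:, -1] *= -1.0
        out = u @ vt
    return out


def icp_point_to_plane(
    source: ExpressionPointCloud,
    target: ExpressionPointCloud,
    init: RigidTransform | None = None,
    max_iterations: int = 50,
    max_correspondence_distance: float | None = None,
    normal_k: int = 20,
    tol: float = 1e-8,
) -> AlignmentResult:
    """Point-to-plane ICP of ``source`` onto ``target``.

    ``max_correspondence_distance`` defaults to 10% of the target's A-P
    length.  The per-iteration inlier RMS history is non-increasing: the
    iteration stops (keeping the previous transform) as soon as an update
    fails to improve it.
    """
    sp = source.positions
    tp = target.positions
    if not (np.all(np.isfinite(sp)) and np.all(np.isfinite(tp))):
        raise ValueError("non-finite positions in input clouds")
    if len(sp) < normal_k or len(tp) < normal_k:
        raise RegistrationError(
            f"clouds must have at least normal_k={normal_k} points "
            f"(got {len(sp)} source, {len(tp)} target)"
        )
    if max_correspondence_distance is None:
        max_correspondence_distance = 0.1 * target.ap_length

    normals = estimate_normals(tp, k=normal_k)
    tree = cKDTree(tp)
    T = init if init is not None else RigidTransform.identity()

    def residuals(transform: RigidTransform):
        moved = transform.apply(sp)
        d, j = tree.query(moved)
        mask = d <= max_correspondence_distance
        return moved, d, j, mask

    history: list[float] = []
    moved, d, j, mask = residuals(T)
    if mask.sum() < 6:
        raise RegistrationError("fewer than 6 correspondences at initialization")
    rms = float(np.sqrt(np.mean(d[mask] ** 2)))
    history.append(rms)

    best = T
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        p = moved[mask]
        q = tp[j[mask]]
        n = normals[j[mask]]
        # linearized point-to-plane: solve for rotation vector w and shift t
        # minimizing sum ((p - q + w x p + t) . n)^2
        A = np.hstack([np.cross(p, n), n])
        b = -np.einsum("ij,ij->i", p - q, n)
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        w, t = x[:3], x[3:]
        angle = np.linalg.norm(w)
        if angle < 1e-15:
            R_delta = np.eye(3)
        else:
            k = w / angle
            Kx = np.array(
                [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
            )
            R_delta = np.eye(3) + np.sin(angle) * Kx + (1 - np.cos(angle)) * Kx @ Kx
        T_new = RigidTransform.from_rotation_translation(
            _orthonormalize(R_delta), t
        ).compose(T)

        moved_new, d_new, j_new, mask_new = residuals(T_new)
        if mask_new.sum() < 6:
            break
        rms_new = float(np.sqrt(np.mean(d_new[mask_new] ** 2)))
        if rms_new > rms - tol:
            if rms_new < rms:  # tiny improvement below tol: keep, then stop
                T, rms = T_new, rms_new
                history.append(rms_new)
            break
        T, rms = T_new, rms_new
        moved, d, j, mask = moved_new, d_new, j_new, mask_new
        history.append(rms)
        best = T

    _, d, _, mask = residuals(T)
    inlier_fraction = float(mask.mean())
    rms = float(np.sqrt(np.mean(d[mask] ** 2))) if mask.any() else np.inf
    return AlignmentResult(
        transform=T if T is not None else best,
        rms_residual=rms,
        inlier_fraction=inlier_fraction,
        n_iterations=n_iter,
        history=np.asarray(history),
    )


def alignment_qc(
    result: AlignmentResult,
    rms_threshold: float,
    min_inlier_fraction: float = 0.5,
) -> AlignmentResult:
    """Accept an alignment iff inlier RMS and inlier fraction pass the gate."""
    accepted = (
        result.rms_residual <= rms_threshold
        and result.inlier_fraction >= min_inlier_fraction
    )
    if not accepted:
        logger.info(
            "alignment rejected: rms=%.3f (thr %.3f), inliers=%.2f (min %.2f)",
            result.rms_residual, rms_threshold,
            result.inlier_fraction, min_inlier_fraction,
        )
    return replace(result, accepted=accepted)


def align(
    source: ExpressionPointCloud,
    target: ExpressionPointCloud,
    rms_threshold: float | None = None,
    min_inlier_fraction: float = 0.5,
    **icp_kwargs,
) -> tuple[ExpressionPointCloud, AlignmentResult]:
    """Full per-pair pipeline: A-P rescale, coarse init, ICP, QC gate.

    Returns the rescaled source (transform not yet applied) and the gated
    AlignmentResult whose transform maps the rescaled source onto the target.
    """
    rescaled = rescale_ap(source, target)
    init = initial_alignment(rescaled, target)
    result = icp_point_to_plane(rescaled, target, init=init, **icp_kwargs)
    if rms_threshold is None:
        rms_threshold = 0.05 * target.ap_length
    return rescaled, alignment_qc(result, rms_threshold, min_inlier_fraction)
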