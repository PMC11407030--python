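"""Posterior post-processing: filtering, topology clustering, consensus,
and in-silico perturbation summaries.

Retained samples are filtered on three gates (run converged, overall
likelihood >= -15000, every interaction weight within +/-100), z-scaled per
parameter and k-means clustered; clusters holding fewer than 5% of samples
are pruned.  Interaction-sign consensus reports, for each of the 15
interaction weights (9 gene->gene + 6 signal->gene), the fraction of
retained samples in which it is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .agets import AGETSet
from .model import N_PARAMS, PARAM_NAMES
from .schema import GENES, N_GENES

logger = logging.getLogger(__name__)

INTERACTION_INDICES = tuple(range(15))  # 9 W entries then 6 E entries
INTERACTION_NAMES = PARAM_NAMES[:15]


@dataclass
class FilterSpec:
    min_overall_likelihood: float = -15_000.0
    max_abs_weight: float = 100.0
    require_converged: bool = True

    def __post_init__(self) -> None:
        if self.max_abs_weight <= 0:
            raise ValueError("max_abs_weight must be > 0")


@dataclass
class RetainedSamples:
    """Filtered samples with provenance indices into the original array."""

    samples: np.ndarray  # (n, 24)
    scores: np.ndarray  # (n,)
    indices: np.ndarray  # (n,) positions in the pre-filter sample array

    def __len__(self) -> int:
        return len(self.samples)


def filter_parameter_sets(
    samples: np.ndarray,
    overall_scores: np.ndarray,
    spec: FilterSpec,
    converged: bool = True,
) -> RetainedSamples:
    """Apply the likelihood and weight-magnitude gates.

    An empty result is legal (a warning is logged, not raised).
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    overall_scores = np.asarray(overall_scores, float)
    if len(samples) != len(overall_scores):
        raise ValueError("samples and scores are not aligned")
    if spec.require_converged and not converged:
        keep = np.zeros(len(samples), dtype=bool)
    else:
        weights = samples[:, list(INTERACTION_INDICES)]
        keep = (overall_scores >= spec.min_overall_likelihood) & np.all(
            np.abs(weights) <= spec.max_abs_weight, axis=1
        )
    if not keep.any():
        logger.warning("filter retained no parameter sets")
    idx = np.flatnonzero(keep)
    return RetainedSamples(samples[idx], overall_scores[idx], idx)


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray  # (n,) in [1, k]
    centroids: np.ndarray  # (k, 24) in scaled space
    sizes: np.ndarray  # (k,)
    center: np.ndarray  # (24,) per-parameter scaling center
    scale: np.ndarray  # (24,) per-parameter scaling scale
    retained_mask: np.ndarray = field(default=None)  # (k,) clusters kept
    inertia: float = 0.0

    def __post_init__(self) -> None:
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.k, dtype=bool)

    def assign(self, samples: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(samples) - self.center) / self.scale
        d = ((z[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return d.argmin(axis=1) + 1


def scale_and_cluster(
    retained: RetainedSamples | np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """Z-scale parameters on the retained set, then k-means with restarts.

    Zero-variance parameters get scale 1 (logged) so they do not blow up
    the standardization.
    """
    samples = retained.samples if isinstance(retained, RetainedSamples) else retained
    samples = np.atleast_2d(np.asarray(samples, float))
    if len(samples) < k:
        raise ValueError(f"cannot form {k} clusters from {len(samples)} samples")
    center = samples.mean(axis=0)
    scale = samples.std(axis=0)
    degenerate = scale == 0
    if degenerate.any():
        logger.info(
            "zero-variance parameters %s: scale set to 1",
            [PARAM_NAMES[i] for i in np.flatnonzero(degenerate)],
        )
        scale = np.where(degenerate, 1.0, scale)
    z = (samples - center) / scale
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**31))
    labels = km.fit_predict(z) + 1
    sizes = np.bincount(labels - 1, minlength=k)
    return ClusterModel(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_,
        sizes=sizes,
        center=center,
        scale=scale,
        inertia=float(km.inertia_),
    )


def wss_curve(
    retained: RetainedSamples | np.ndarray,
    k_range: range = range(1, 16),
    seed: int = 0,
) -> dict[int, float]:
    """Within-cluster sum of squares over a k sweep (elbow-plot support)."""
    return {
        k: scale_and_cluster(retained, k, seed=seed).inertia
        for k in k_range
    }


def suggest_k(wss: dict[int, float]) -> int:
    """Elbow of the WSS curve: the k whose point lies farthest below the
    chord joining the curve's endpoints (kneedle-style)."""
    ks = np.array(sorted(wss))
    vals = np.array([wss[k] for k in ks], float)
    if len(ks) < 3:
        return int(ks[-1])
    span = vals[0] - vals[-1]
    if span <= 0:
        return int(ks[0])
    v = (vals - vals[-1]) / span
    t = (ks - ks[0]) / (ks[-1] - ks[0])
    return int(ks[np.argmax((1.0 - t) - v)])


def prune_small_clusters(model: ClusterModel, min_fraction: float = 0.05) -> ClusterModel:
    """Mask out clusters holding fewer than ``min_fraction`` of all samples.

    Members keep their labels; nothing is relabelled, so sample counts are
    conserved between masked and retained clusters.
    """
    total = model.sizes.sum()
    mask = model.sizes / total >= min_fraction
    return replace(model, retained_mask=mask)


def interaction_sign_consensus(
    retained: RetainedSamples | np.ndarray,
) -> dict[str, float]:
    """Fraction of samples with a positive value for each interaction weight.

    Exact zeros count as non-positive.
    """
    samples = retained.samples if isinstance(retained, RetainedSamples) else retained
    samples = np.atleast_2d(np.asarray(samples, float))
    if len(samples) == 0:
        raise ValueError("no samples for consensus")
    fractions = (samples[:, list(INTERACTION_INDICES)] > 0).mean(axis=0)
    return dict(zip(INTERACTION_NAMES, fractions.tolist()))


@dataclass
class PerturbationSummary:
    track_ids: np.ndarray
    per_cell_delta: np.ndarray  # (n_cells, 3) perturbed - unperturbed, final frame
    mean_delta: np.ndarray  # (3,)

    def gene_delta(self, gene: str) -> float:
        return float(self.mean_delta[GENES.index(gene.lower())])


def summarize_perturbation(sim_wt: AGETSet, sim_pert: AGETSet) -> PerturbationSummary:
    """Final-frame per-cell gene differences between perturbed and unperturbed
    simulations, plus their mean over cells."""
    if not np.array_equal(sim_wt.track_ids, sim_pert.track_ids):
        raise ValueError("perturbed and unperturbed simulations pair different cells")
    if sim_wt.n_frames != sim_pert.n_frames:
        raise ValueError("perturbed and unperturbed simulations differ in frames")
    delta = sim_pert.genes[:, -1, :] - sim_wt.genes[:, -1, :]
    return PerturbationSummary(
        track_ids=sim_wt.track_ids.copy(),
        per_cell_delta=delta,
        mean_delta=delta.mean(axis=0),
    )
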