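"""Ensemble-MCMC estimation of the 24 GRN parameters against AGETs.

The posterior combines a boxcar prior (uniform on [-200, 200] per parameter,
restricted to non-negative values for the production and decay rates) with a
Gaussian likelihood over the residuals between target AGETs and the
live-model simulation:

    log L = -0.5 * sum_a sum_c sum_t (T_atc - S_atc)^2 / sigma_a^2

with per-gene standard deviations sigma = (0.2, 0.2, 0.1) for
(tbxta, tbx16, tbx6).  Sampling uses the affine-invariant ensemble sampler
(emcee); convergence is declared when, for at least 20 of the 24 parameters,
a two-sample Kolmogorov-Smirnov test finds no distributional shift (p >
0.001) between an early and a late window of the chain.  Scores are then
recomputed on the *full* AGET set for the final retained samples so runs
fitted to different cell subsets are comparable, and the maximum a
posteriori (MAP) sample is the retained sample with the highest score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.stats import ks_2samp

from .agets import AGETSet
from .model import (
    N_PARAMS,
    POSITIVE_PARAM_INDICES,
    GRNParameters,
    SimulationError,
    TimeGrid,
    simulate_batch,
)
from .schema import N_GENES
from .tracks import CellTrackSet

logger = logging.getLogger(__name__)


class InferenceError(RuntimeError):
    pass


@dataclass
class LikelihoodSpec:
    """Gaussian-residual likelihood settings.

    sigmas are per-gene residual scales in AGET expression units for
    (tbxta, tbx16, tbx6); anterior_exclusion is the maximum first-frame
    normalized A-P position of cells eligible for fitting.
    """

    sigmas: tuple[float, float, float] = (0.2, 0.2, 0.1)
    anterior_exclusion: float = 0.85

    def __post_init__(self) -> None:
        if len(self.sigmas) != N_GENES or any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be three positive values")


@dataclass
class PriorSpec:
    """Independent uniform priors with optional positivity restrictions."""

    lower: float = -200.0
    upper: float = 200.0
    positive_indices: tuple[int, ...] = POSITIVE_PARAM_INDICES

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("prior lower bound must be below upper bound")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(N_PARAMS, self.lower)
        lo[list(self.positive_indices)] = 0.0
        return lo, np.full(N_PARAMS, self.upper)


@dataclass
class MCMCConfig:
    n_walkers: int = 96
    n_steps: int = 10_000
    extension_block: int = 10_000
    max_extensions: int = 1
    n_fitting_agets: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walkers % 2 or self.n_walkers < 2 * (N_PARAMS + 1):
            raise ValueError(
                f"n_walkers must be even and >= {2 * (N_PARAMS + 1)} "
                "(ensemble sampler needs more than twice the dimension)"
            )
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class PosteriorEnsemble:
    chain: np.ndarray  # (n_steps, n_walkers, 24)
    log_prob: np.ndarray  # (n_steps, n_walkers)
    acceptance_fraction: np.ndarray  # (n_walkers,)
    converged: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.chain.shape[0]

    @property
    def n_walkers(self) -> int:
        return self.chain.shape[1]

    def flat(self, discard: int = 0) -> np.ndarray:
        """Flatten to (n_samples, 24), step-major (walkers of a step adjacent)."""
        return self.chain[discard:].reshape(-1, N_PARAMS)

    def flat_log_prob(self, discard: int = 0) -> np.ndarray:
        return self.log_prob[discard:].reshape(-1)

    def final_samples(self, n_final: int) -> np.ndarray:
        flat = self.flat()
        if n_final > len(flat):
            raise ValueError(f"chain holds {len(flat)} samples < n_final={n_final}")
        return flat[-n_final:]


# ---------------------------------------------------------------------------
# posterior pieces


def log_prior(params: GRNParameters | np.ndarray, prior: PriorSpec) -> float:
    theta = (
        params.to_vector() if isinstance(params, GRNParameters) else np.asarray(params)
    )
    lo, hi = prior.bounds()
    return 0.0 if np.all((theta >= lo) & (theta <= hi)) else -np.inf


def _batch_log_likelihood(
    thetas: np.ndarray,
    targets: AGETSet,
    spec: LikelihoodSpec,
    grid: TimeGrid,
) -> np.ndarray:
    """Vectorized likelihood of (K, 24) parameter rows; -inf on failure."""
    thetas = np.atleast_2d(thetas)
    out = np.full(len(thetas), -np.inf)
    valid = np.flatnonzero(np.all(thetas[:, 18:21] > 0, axis=1))
    if len(valid) == 0:
        return out
    g0 = targets.genes[:, 0, :]
    try:
        sim = simulate_batch(thetas[valid], g0, targets.signals, grid)
    except SimulationError as e:
        logger.debug("batch simulation failed: %s", e)
        # fall back to per-row evaluation so one bad row cannot void a batch
        for i in valid:
            try:
                s = simulate_batch(thetas[i : i + 1], g0, targets.signals, grid)
            except SimulationError:
                continue
            out[i] = _residual_score(s[0], targets, spec)
        return out
    for pos, i in enumerate(valid):
        out[i] = _residual_score(sim[pos], targets, spec)
    return out


def _residual_score(sim_genes: np.ndarray, targets: AGETSet, spec: LikelihoodSpec) -> float:
    resid = targets.genes - sim_genes  # (C, T, 3)
    sig2 = np.asarray(spec.sigmas) ** 2
    return float(-0.5 * np.sum(resid**2 / sig2))


def log_likelihood(
    params: GRNParameters,
    targets: AGETSet,
    spec: LikelihoodSpec,
    grid: TimeGrid,
) -> float:
    """Gaussian log-likelihood of one parameter set against target AGETs.

    Returns -inf when any decay rate is non-positive or the simulation
    fails; exactly 0.0 for a perfect fit.
    """
    if np.any(params.lam <= 0):
        return -np.inf
    return float(_batch_log_likelihood(params.to_vector(), targets, spec, grid)[0])


def select_fitting_agets(
    agets: AGETSet,
    tracks: CellTrackSet,
    n: int,
    anterior_exclusion: float = 0.85,
    seed: int = 0,
) -> AGETSet:
    """Uniform random subset of fitting-eligible cells, excluding cells that
    start in the anterior-most region of the tissue."""
    ids, p = tracks.normalized_ap_position(1)
    posmap = dict(zip(ids.tolist(), p.tolist()))
    eligible = np.array(
        [t for t in agets.track_ids if posmap.get(int(t), np.inf) <= anterior_exclusion]
    )
    if n > len(eligible):
        raise InferenceError(
            f"requested {n} fitting AGETs but only {len(eligible)} eligible cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=False)
    return agets.subset(np.sort(chosen))


# ---------------------------------------------------------------------------
# sampling


def sample_ensemble(
    log_prob_fn,
    ndim: int,
    n_walkers: int,
    n_steps: int,
    initial: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin wrapper around the affine-invariant sampler.

    ``log_prob_fn`` must accept a (n_walkers, ndim) array and return a
    vector of log-probabilities.  Returns (chain, log_prob, acceptance).
    """
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob_fn, vectorize=True)
    sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    sampler.run_mcmc(initial, n_steps, progress=False, skip_initial_state_check=True)
    return sampler.get_chain(), sampler.get_log_prob(), sampler.acceptance_fraction


def _initial_walkers(
    prior: PriorSpec, n_walkers: int, rng: np.random.Generator
) -> np.ndarray:
    """Walkers start in a small region of prior support: weights and
    thresholds in [-1, 1], rates in [0.1, 2] (keeping lambda away from 0)."""
    init = rng.uniform(-1.0, 1.0, size=(n_walkers, N_PARAMS))
    init[:, list(prior.positive_indices)] = rng.uniform(
        0.1, 2.0, size=(n_walkers, len(prior.positive_indices))
    )
    lo, hi = prior.bounds()
    return np.clip(init, lo + 1e-6, hi - 1e-6)


def run_mcmc(
    targets: AGETSet,
    spec: LikelihoodSpec,
    prior: PriorSpec,
    config: MCMCConfig,
    grid: TimeGrid | None = None,
) -> PosteriorEnsemble:
    """Affine-invariant ensemble sampling of the GRN posterior.

    The chain is extended by ``extension_block`` steps (up to
    ``max_extensions`` times) while the K-S convergence rule fails.
    """
    if grid is None:
        grid = TimeGrid(n_frames=targets.n_frames)
    lo, hi = prior.bounds()

    def log_prob(thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        in_support = np.all((thetas >= lo) & (thetas <= hi), axis=1)
        out = np.full(len(thetas), -np.inf)
        if in_support.any():
            out[in_support] = _batch_log_likelihood(
                thetas[in_support], targets, spec, grid
            )
        return out

    rng = np.random.default_rng(config.seed)
    initial = _initial_walkers(prior, config.n_walkers, rng)
    sampler = emcee.EnsembleSampler(
        config.n_walkers, N_PARAMS, log_prob, vectorize=True
    )
    sampler.random_state = np.random.RandomState(config.seed % (2**31)).get_state()
    state = sampler.run_mcmc(
        initial, config.n_steps, progress=False, skip_initial_state_check=True
    )

    def current() -> PosteriorEnsemble:
        return PosteriorEnsemble(
            chain=sampler.get_chain(),
            log_prob=sampler.get_log_prob(),
            acceptance_fraction=sampler.acceptance_fraction,
            metadata={"seed": config.seed, "n_fitting_agets": targets.n_cells},
        )

    ensemble = current()
    if np.all(ensemble.acceptance_fraction == 0.0):
        raise InferenceError("all walkers stuck: zero acceptance over the run")
    converged = ks_convergence(ensemble)
    extensions = 0
    while not converged and extensions < config.max_extensions:
        state = sampler.run_mcmc(state, config.extension_block, progress=False)
        extensions += 1
        ensemble = current()
        converged = ks_convergence(ensemble)
    ensemble.converged = converged
    ensemble.metadata["extensions"] = extensions
    return ensemble


# ---------------------------------------------------------------------------
# convergence and scoring


def ks_statistics(
    ensemble: PosteriorEnsemble,
    early_window: tuple[int, int] | None = None,
    late_window: tuple[int, int | None] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample K-S statistic and p-value per parameter between an early
    and a late chain window (step ranges, negative indices allowed).

    Defaults follow the 10,000-step protocol — early = steps [-10000, -8000),
    late = final 5000 — rescaled proportionally for shorter chains.
    """
    n = ensemble.n_steps
    if early_window is None:
        early_window = (-10_000, -8_000) if n >= 10_000 else (-n, -int(0.8 * n))
    if late_window is None:
        late_window = (-5_000, None) if n >= 10_000 else (-n // 2, None)

    def resolve(w):
        start, stop = w
        start = start % n if start is not None else 0
        stop = n if stop is None else stop % n or n
        if not 0 <= start < stop <= n:
            raise ValueError(f"window {w} does not fit a {n}-step chain")
        return start, stop

    e0, e1 = resolve(early_window)
    l0, l1 = resolve(late_window)
    if max(e0, l0) < min(e1, l1):
        raise ValueError(
            f"convergence windows overlap: steps [{e0},{e1}) and [{l0},{l1})"
        )
    early = ensemble.chain[e0:e1].reshape(-1, N_PARAMS)
    late = ensemble.chain[l0:l1].reshape(-1, N_PARAMS)
    stats = np.empty(N_PARAMS)
    pvals = np.empty(N_PARAMS)
    for i in range(N_PARAMS):
        res = ks_2samp(early[:, i], late[:, i])
        stats[i], pvals[i] = res.statistic, res.pvalue
    return stats, pvals


def ks_convergence(
    ensemble: PosteriorEnsemble,
    early_window: tuple[int, int] | None = None,
    late_window: tuple[int, int | None] | None = None,
    alpha: float = 0.001,
    min_params: int = 20,
) -> bool:
    """Converged when >= min_params of the 24 parameters show no
    distributional shift between the two windows (K-S p > alpha)."""
    _, pvals = ks_statistics(ensemble, early_window, late_window)
    return int(np.sum(pvals > alpha)) >= min_params


def recompute_overall_likelihood(
    ensemble: PosteriorEnsemble,
    all_agets: AGETSet,
    spec: LikelihoodSpec,
    grid: TimeGrid,
    n_final: int = 2000,
    chunk: int = 64,
) -> np.ndarray:
    """Likelihood of the final ``n_final`` samples against the full AGET set,
    making runs fitted to different cell subsets comparable."""
    samples = ensemble.final_samples(n_final)
    scores = np.empty(len(samples))
    for i in range(0, len(samples), chunk):
        scores[i : i + chunk] = _batch_log_likelihood(
            samples[i : i + chunk], all_agets, spec, grid
        )
    return scores


def select_map(
    ensemble: PosteriorEnsemble,
    overall_scores: np.ndarray | None = None,
) -> GRNParameters:
    """The maximum a posteriori sample.

    With ``overall_scores`` (from recompute_overall_likelihood) the argmax is
    taken over the corresponding final samples; otherwise over the full
    chain's stored log-probabilities.  Ties break to the earliest sample.
    """
    if overall_scores is not None:
        samples = ensemble.final_samples(len(overall_scores))
        best = int(np.argmax(overall_scores))
    else:
        samples = ensemble.flat()
        if samples.size == 0:
            raise ValueError("empty ensemble")
        best = int(np.argmax(ensemble.flat_log_prob()))
    return GRNParameters.from_vector(samples[best])
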