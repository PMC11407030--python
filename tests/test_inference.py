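"""Likelihood, priors, sampling machinery, and convergence diagnostics."""

import numpy as np
import pytest

from agetkit.agets import AGETSet
from agetkit.inference import (
    InferenceError,
    LikelihoodSpec,
    MCMCConfig,
    PosteriorEnsemble,
    PriorSpec,
    ks_convergence,
    ks_statistics,
    log_likelihood,
    log_prior,
    recompute_overall_likelihood,
    sample_ensemble,
    select_fitting_agets,
    select_map,
)
from agetkit.model import N_PARAMS, GRNParameters, TimeGrid, live_model


def make_params(**kw):
    base = dict(W=np.zeros((3, 3)), E=np.zeros((2, 3)),
                R=np.ones(3), lam=np.ones(3), h=np.zeros(3))
    base.update(kw)
    return GRNParameters(**base)


class TestLogLikelihood:
    def test_perfect_fit_scores_zero(self, truth_agets, truth, grid):
        spec = LikelihoodSpec()
        L = log_likelihood(truth.params, truth_agets, spec, grid)
        assert L == pytest.approx(0.0, abs=1e-6)

    def test_unit_residual_contributes_half(self, grid):
        # build a target differing from the simulation by exactly sigma on
        # one gene at one frame of one cell
        params = make_params(R=np.zeros(3), lam=np.ones(3))
        vals = np.zeros((1, grid.n_frames, 5))
        agets = AGETSet([0], vals)
        sim = live_model(agets, params, grid)  # all-zero genes
        spec = LikelihoodSpec(sigmas=(0.2, 0.2, 0.1))
        target_vals = np.concatenate([sim.genes, agets.signals], axis=2).copy()
        target_vals[0, 5, 0] += 0.2  # one residual of exactly sigma_tbxta
        # note: frame 5 is not the initial frame, so g0 is unchanged
        target = AGETSet([0], target_vals)
        L = log_likelihood(params, target, spec, grid)
        assert L == pytest.approx(-0.5, abs=1e-9)

    def test_matches_triple_loop_oracle(self, rng, grid):
        spec = LikelihoodSpec()
        cells, frames = 2, grid.n_frames
        vals = rng.uniform(0, 1, (cells, frames, 5))
        targets = AGETSet(np.arange(cells), vals)
        params = make_params(W=rng.normal(0, 1, (3, 3)), h=rng.normal(0, 1, 3))
        sim = live_model(targets, params, grid)
        expected = 0.0
        for a in range(3):
            for c in range(cells):
                for t in range(frames):
                    r = targets.genes[c, t, a] - sim.genes[c, t, a]
                    expected += -0.5 * r**2 / spec.sigmas[a] ** 2
        L = log_likelihood(params, targets, spec, grid)
        assert L == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_decay_gives_minus_inf(self, truth_agets, grid):
        bad = make_params(lam=np.array([1.0, -1.0, 1.0]))
        assert log_likelihood(bad, truth_agets, LikelihoodSpec(), grid) == -np.inf

    def test_never_positive(self, rng, grid):
        vals = rng.uniform(0, 1, (2, grid.n_frames, 5))
        targets = AGETSet(np.arange(2), vals)
        for _ in range(5):
            params = make_params(W=rng.normal(0, 3, (3, 3)))
            assert log_likelihood(params, targets, LikelihoodSpec(), grid) <= 0.0


class TestLogPrior:
    def test_interior_point(self):
        assert log_prior(make_params(), PriorSpec()) == 0.0

    def test_bound_violation(self):
        W = np.zeros((3, 3))
        W[0, 0] = 250.0
        assert log_prior(make_params(W=W), PriorSpec()) == -np.inf

    def test_positivity_violation(self):
        assert log_prior(
            make_params(R=np.array([-0.1, 1.0, 1.0])), PriorSpec()
        ) == -np.inf

    def test_restricted_set_is_rates_only(self):
        # negative weights and thresholds are allowed
        W = np.full((3, 3), -50.0)
        assert log_prior(make_params(W=W, h=np.full(3, -100.0)), PriorSpec()) == 0.0


class TestSelectFittingAgets:
    def test_exhaustive_selection(self, truth_agets, tracks):
        out = select_fitting_agets(
            truth_agets, tracks, n=truth_agets.n_cells, anterior_exclusion=1.0
        )
        assert set(out.track_ids) == set(truth_agets.track_ids)

    def test_deterministic(self, truth_agets, tracks):
        a = select_fitting_agets(truth_agets, tracks, 10, seed=3)
        b = select_fitting_agets(truth_agets, tracks, 10, seed=3)
        assert np.array_equal(a.track_ids, b.track_ids)

    def test_anterior_exclusion_respected(self, truth_agets, tracks):
        ids, p = tracks.normalized_ap_position(1)
        posmap = dict(zip(ids.tolist(), p.tolist()))
        n_eligible = sum(1 for t in truth_agets.track_ids if posmap[int(t)] <= 0.9)
        out = select_fitting_agets(
            truth_agets, tracks, n=n_eligible, anterior_exclusion=0.9
        )
        assert all(posmap[int(t)] <= 0.9 for t in out.track_ids)

    def test_oversized_request_rejected(self, truth_agets, tracks):
        with pytest.raises(InferenceError):
            select_fitting_agets(truth_agets, tracks, truth_agets.n_cells + 1)


class TestSampler:
    def test_uniform_prior_moments(self):
        """Sampling a plain box recovers uniform moments."""
        lo, hi = -1.0, 1.0

        def logp(x):
            ok = np.all((x >= lo) & (x <= hi), axis=-1)
            return np.where(ok, 0.0, -np.inf)

        rng = np.random.default_rng(0)
        init = rng.uniform(-0.1, 0.1, (32, 3))
        chain, _, acc = sample_ensemble(logp, 3, 32, 800, init, seed=1)
        samples = chain[200:].reshape(-1, 3)
        # uniform(-1,1): mean 0, sd 0.577; generous 3-sigma-ish band given
        # walker autocorrelation
        assert np.abs(samples.mean(axis=0)).max() < 0.1
        assert np.abs(samples.std(axis=0) - 0.5774).max() < 0.06
        assert acc.mean() > 0.1

    def test_gaussian_posterior_mean(self):
        mu = np.array([1.5, -0.5])

        def logp(x):
            return -0.5 * np.sum((x - mu) ** 2 / 0.25, axis=-1)

        rng = np.random.default_rng(2)
        init = rng.normal(0, 0.5, (24, 2))
        chain, _, _ = sample_ensemble(logp, 2, 24, 600, init, seed=2)
        samples = chain[150:].reshape(-1, 2)
        assert np.abs(samples.mean(axis=0) - mu).max() < 0.05

    def test_seed_determinism(self):
        def logp(x):
            return -0.5 * np.sum(x**2, axis=-1)

        init = np.random.default_rng(5).normal(0, 0.1, (16, 2))
        a, _, _ = sample_ensemble(logp, 2, 16, 100, init, seed=9)
        b, _, _ = sample_ensemble(logp, 2, 16, 100, init, seed=9)
        assert np.array_equal(a, b)


def _ensemble_from(chain):
    chain = np.asarray(chain, float)
    return PosteriorEnsemble(
        chain=chain,
        log_prob=np.zeros(chain.shape[:2]),
        acceptance_fraction=np.full(chain.shape[1], 0.3),
    )


class TestKsConvergence:
    def _chain(self, rng, n_steps=400, shift=None):
        chain = rng.normal(0, 1, (n_steps, 4, N_PARAMS))
        if shift is not None:
            for param, size in shift.items():
                chain[-n_steps // 2 :, :, param] += size
        return _ensemble_from(chain)

    def test_identical_windows_converge(self, rng):
        block = rng.normal(0, 1, (100, 4, N_PARAMS))
        ens = _ensemble_from(np.concatenate([block, block, block, block]))
        assert ks_convergence(
            ens, early_window=(0, 100), late_window=(300, None)
        )

    def test_single_shifted_parameter_still_converges(self, rng):
        # prior width 400; one parameter jumps 10 prior-widths: 23 >= 20 stable
        ens = self._chain(rng, shift={0: 4000.0})
        assert ks_convergence(ens, early_window=(0, 100), late_window=(200, None))

    def test_five_shifted_parameters_fail(self, rng):
        ens = self._chain(rng, shift={i: 4000.0 for i in range(5)})
        assert not ks_convergence(ens, early_window=(0, 100), late_window=(200, None))

    def test_statistic_matches_bruteforce_cdf_oracle(self, rng):
        ens = self._chain(rng, n_steps=100, shift={2: 1.0})
        stats, _ = ks_statistics(ens, early_window=(0, 40), late_window=(60, None))
        early = ens.chain[0:40].reshape(-1, N_PARAMS)
        late = ens.chain[60:].reshape(-1, N_PARAMS)
        for i in (0, 2, 17):
            a, b = np.sort(early[:, i]), np.sort(late[:, i])
            grid_pts = np.concatenate([a, b])
            cdf_a = np.searchsorted(a, grid_pts, side="right") / len(a)
            cdf_b = np.searchsorted(b, grid_pts, side="right") / len(b)
            brute = np.abs(cdf_a - cdf_b).max()
            assert stats[i] == pytest.approx(brute, abs=1e-12)

    def test_overlapping_windows_rejected(self, rng):
        ens = self._chain(rng)
        with pytest.raises(ValueError, match="overlap"):
            ks_convergence(ens, early_window=(0, 300), late_window=(200, None))


class TestScoringAndMap:
    def test_full_set_equals_fitting_set(self, truth_agets, truth, grid):
        spec = LikelihoodSpec()
        chain = np.tile(truth.params.to_vector(), (5, 2, 1))
        ens = _ensemble_from(chain)
        scores = recompute_overall_likelihood(ens, truth_agets, spec, grid, n_final=4)
        direct = log_likelihood(truth.params, truth_agets, spec, grid)
        assert np.allclose(scores, direct, atol=1e-9)

    def test_cell_order_invariance(self, truth_agets, truth, grid):
        spec = LikelihoodSpec()
        perm = np.random.default_rng(0).permutation(truth_agets.n_cells)
        shuffled = AGETSet(truth_agets.track_ids[perm], truth_agets.values[perm])
        a = log_likelihood(truth.params, truth_agets, spec, grid)
        b = log_likelihood(truth.params, shuffled, spec, grid)
        assert a == pytest.approx(b, abs=1e-9)

    def test_truth_beats_sign_flip(self, truth_agets, truth, grid):
        spec = LikelihoodSpec()
        flipped = GRNParameters.from_vector(truth.params.to_vector())
        flipped.E[0, 1] *= -1  # flip the wnt->tbx16 activation
        L_true = log_likelihood(truth.params, truth_agets, spec, grid)
        L_flip = log_likelihood(flipped, truth_agets, spec, grid)
        assert L_true > L_flip

    def test_map_is_argmax_with_earliest_tie(self):
        chain = np.zeros((3, 2, N_PARAMS))
        chain[1, 0, 0] = 7.0  # flat index 2
        chain[2, 1, 0] = 7.0  # flat index 5 (tied score, later)
        ens = _ensemble_from(chain)
        ens.log_prob = np.array([[0.0, -1.0], [5.0, -2.0], [-3.0, 5.0]])
        best = select_map(ens)
        assert best.W[0, 0] == 7.0
        assert np.argmax(ens.flat_log_prob()) == 2

    def test_singleton(self):
        chain = np.full((1, 1, N_PARAMS), 2.0)
        ens = _ensemble_from(chain)
        params = select_map(ens)
        assert np.all(params.to_vector() == 2.0)


class TestMCMCConfigValidation:
    def test_walker_floor(self):
        with pytest.raises(ValueError, match="n_walkers"):
            MCMCConfig(n_walkers=16)

    def test_even_requirement(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_walkers=51)
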