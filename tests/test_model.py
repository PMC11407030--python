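"""GRN dynamics: the sigmoid, the right-hand side, and per-cell simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agetkit.agets import AGETSet
from agetkit.model import (
    GRNParameters,
    PerturbationSpec,
    TimeGrid,
    live_model,
    perturb_signals,
    phi,
    regulatory_input,
    rhs,
    simulate_batch,
    simulate_cell,
)
from agetkit.schema import SchemaError


def make_params(W=None, E=None, R=None, lam=None, h=None):
    return GRNParameters(
        W=np.zeros((3, 3)) if W is None else W,
        E=np.zeros((2, 3)) if E is None else E,
        R=np.ones(3) if R is None else R,
        lam=np.ones(3) if lam is None else lam,
        h=np.zeros(3) if h is None else h,
    )


class TestPhi:
    def test_zero_maps_to_half(self):
        assert phi(0.0) == 0.5

    def test_value_at_one(self):
        # (1/sqrt(2) + 1)/2
        assert phi(1.0) == pytest.approx(0.8535533906, abs=1e-10)

    @given(st.floats(min_value=-1e6, max_value=1e6))
    @settings(max_examples=100, deadline=None)
    def test_odd_symmetry(self, u):
        assert phi(u) + phi(-u) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_and_bounded(self):
        u = np.linspace(-50, 50, 1001)
        v = phi(u)
        assert np.all(np.diff(v) > 0)
        assert v.min() > 0.0 and v.max() < 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            phi(np.nan)


class TestRegulatoryInput:
    def test_zero_network(self):
        u = regulatory_input(np.zeros(3), np.zeros(2), make_params())
        assert np.array_equal(u, np.zeros(3))

    def test_bias_only(self):
        h = np.array([1.0, -2.0, 0.5])
        u = regulatory_input(np.zeros(3), np.zeros(2), make_params(h=h))
        assert np.array_equal(u, h)

    def test_hand_sum(self):
        params = make_params(W=np.ones((3, 3)))
        u = regulatory_input(np.array([0.1, 0.2, 0.3]), np.zeros(2), params)
        assert np.allclose(u, 0.6)

    def test_dimension_mismatch(self):
        with pytest.raises(SchemaError):
            regulatory_input(np.zeros(4), np.zeros(2), make_params())


class TestRhs:
    def test_decay_only(self):
        g = np.array([1.0, 2.0, 3.0])
        lam = np.array([1.0, 0.5, 2.0])
        out = rhs(g, np.zeros(2), make_params(R=np.zeros(3), lam=lam))
        assert np.allclose(out, -lam * g)

    def test_fixed_point_is_stationary(self):
        params = make_params(R=np.array([1.0, 2.0, 3.0]), lam=np.array([2.0, 1.0, 4.0]))
        s = np.array([0.3, 0.7])
        g_star = params.R * phi(params.h) / params.lam  # u = h when W=E=0
        assert np.allclose(rhs(g_star, s, params), 0.0, atol=1e-14)

    def test_zero_state_production(self):
        out = rhs(np.zeros(3), np.zeros(2), make_params())
        assert np.allclose(out, 0.5)  # R * phi(0)


class TestSimulateCell:
    def _aget(self, n_frames, g0=(1.0, 1.0, 1.0), signals=0.0):
        vals = np.zeros((n_frames, 5))
        vals[0, :3] = g0
        vals[:, 3:] = signals
        return vals

    def test_pure_decay_closed_form(self):
        params = make_params(R=np.zeros(3))
        grid = TimeGrid(n_frames=11, total_span=1.0, substeps=50)
        sim = simulate_cell(self._aget(11), params, grid)
        assert np.allclose(sim.genes[-1], np.exp(-1.0), atol=1e-6)
        # intermediate frames too
        assert np.allclose(sim.genes[:, 0], np.exp(-grid.frame_times), atol=1e-6)

    def test_initial_condition_read_from_first_frame(self):
        aget = self._aget(5, g0=(0.2, 0.4, 0.6))
        sim = simulate_cell(aget, make_params(), TimeGrid(5, 1.0, 10))
        assert np.array_equal(sim.genes[0], [0.2, 0.4, 0.6])

    def test_equilibrium_stays_constant(self):
        params = make_params(R=np.array([2.0, 2.0, 2.0]), lam=np.array([2.0, 2.0, 2.0]))
        g_star = params.R * phi(params.h) / params.lam
        aget = self._aget(21, g0=tuple(g_star), signals=0.0)
        sim = simulate_cell(aget, params, TimeGrid(21, 1.0, 10))
        assert np.abs(sim.genes - g_star).max() < 1e-6

    def test_grid_self_convergence(self, rng):
        params = make_params(
            W=rng.normal(0, 2, (3, 3)), E=rng.normal(0, 2, (2, 3)),
            R=rng.uniform(0.5, 2, 3), lam=rng.uniform(0.5, 2, 3),
            h=rng.normal(0, 1, 3),
        )
        aget = np.zeros((11, 5))
        aget[0, :3] = rng.uniform(0, 1, 3)
        aget[:, 3:] = rng.uniform(0, 1, (11, 2))
        g_coarse = simulate_cell(aget, params, TimeGrid(11, 1.0, 10)).genes
        g_fine = simulate_cell(aget, params, TimeGrid(11, 1.0, 20)).genes
        assert np.abs(g_coarse - g_fine).max() < 1e-6

    def test_euler_oracle_agreement(self, rng):
        """RK4 frame samples match a fine-step explicit-Euler integration."""

        def euler(aget, params, grid, steps_per_frame=1000):
            g = aget[0, :3].copy()
            out = [g.copy()]
            dt = grid.frame_dt / steps_per_frame
            for t in range(grid.n_frames - 1):
                s0, s1 = aget[t, 3:], aget[t + 1, 3:]
                for j in range(steps_per_frame):
                    s = s0 + (s1 - s0) * (j / steps_per_frame)
                    g = g + dt * rhs(g, s, params)
                out.append(g.copy())
            return np.array(out)

        for _ in range(5):
            params = make_params(
                W=rng.normal(0, 3, (3, 3)), E=rng.normal(0, 3, (2, 3)),
                R=rng.uniform(0.1, 3, 3), lam=rng.uniform(0.1, 3, 3),
                h=rng.normal(0, 2, 3),
            )
            aget = np.zeros((6, 5))
            aget[0, :3] = rng.uniform(0, 1, 3)
            aget[:, 3:] = rng.uniform(0, 1, (6, 2))
            rk = simulate_cell(aget, params, TimeGrid(6, 0.1, 10)).genes
            eu = euler(aget, params, TimeGrid(6, 0.1, 10))
            assert np.abs(rk - eu).max() < 1e-4

    def test_boundedness(self, rng):
        for _ in range(10):
            params = make_params(
                W=rng.normal(0, 5, (3, 3)), E=rng.normal(0, 5, (2, 3)),
                R=rng.uniform(0, 3, 3), lam=rng.uniform(0.2, 3, 3),
                h=rng.normal(0, 3, 3),
            )
            aget = np.zeros((21, 5))
            g0 = rng.uniform(0, 1, 3)
            aget[0, :3] = g0
            aget[:, 3:] = rng.uniform(0, 1, (21, 2))
            genes = simulate_cell(aget, params, TimeGrid(21, 1.0, 20)).genes
            upper = np.maximum(g0, params.R / params.lam) + 1e-9
            assert np.all(genes >= -1e-9)
            assert np.all(genes <= upper)


class TestLiveModel:
    def _agets(self, n_cells, n_frames, rng):
        vals = rng.uniform(0, 1, (n_cells, n_frames, 5))
        return AGETSet(np.arange(n_cells), vals)

    def test_consistent_with_simulate_cell(self, rng):
        agets = self._agets(4, 11, rng)
        params = make_params(W=rng.normal(0, 1, (3, 3)))
        grid = TimeGrid(11, 1.0, 10)
        sim = live_model(agets, params, grid)
        single = simulate_cell(agets.values[2], params, grid)
        assert np.allclose(sim.genes[2], single.genes, atol=1e-12)

    def test_identical_cells_identical_output(self, rng):
        vals = rng.uniform(0, 1, (1, 11, 5))
        agets = AGETSet(np.arange(3), np.repeat(vals, 3, axis=0))
        sim = live_model(agets, make_params(), TimeGrid(11, 1.0, 10))
        assert np.array_equal(sim.genes[0], sim.genes[1])
        assert np.array_equal(sim.genes[1], sim.genes[2])

    def test_forward_inverse_consistency(self, truth_agets, truth, grid):
        """Simulating ground-truth AGETs with the generator's own parameters
        reproduces the targets."""
        sim = live_model(truth_agets, truth.params, grid)
        rms = np.sqrt(((sim.genes - truth_agets.genes) ** 2).mean())
        assert rms < 1e-4

    def test_signals_copied_unchanged(self, rng):
        agets = self._agets(3, 7, rng)
        sim = live_model(agets, make_params(), TimeGrid(7, 1.0, 5))
        assert np.array_equal(sim.signals, agets.signals)


class TestPerturbation:
    def test_wnt_clamp_sets_every_frame(self, truth_agets):
        out = perturb_signals(truth_agets, PerturbationSpec("wnt", 1.5))
        assert np.all(out.channel("wnt") == 1.5)
        assert np.array_equal(out.channel("fgf"), truth_agets.channel("fgf"))

    def test_fgf_clamp(self, truth_agets):
        out = perturb_signals(truth_agets, PerturbationSpec("fgf", 0.01))
        assert np.all(out.channel("fgf") == 0.01)

    def test_noop_clamp_preserves_dynamics(self, rng):
        vals = rng.uniform(0, 1, (3, 11, 5))
        vals[:, :, 3] = 0.7  # wnt already constant
        agets = AGETSet(np.arange(3), vals)
        params = make_params(E=rng.normal(0, 2, (2, 3)))
        grid = TimeGrid(11, 1.0, 10)
        clamped = perturb_signals(agets, PerturbationSpec("wnt", 0.7))
        a = live_model(agets, params, grid)
        b = live_model(clamped, params, grid)
        assert np.array_equal(a.genes, b.genes)

    def test_partial_interval(self, truth_agets):
        out = perturb_signals(
            truth_agets, PerturbationSpec("wnt", 1.5, frame_range=(5, 10))
        )
        assert np.all(out.channel("wnt")[:, 4:10] == 1.5)
        assert np.array_equal(
            out.channel("wnt")[:, :4], truth_agets.channel("wnt")[:, :4]
        )

    def test_unknown_signal_rejected(self, truth_agets):
        with pytest.raises(SchemaError):
            perturb_signals(truth_agets, PerturbationSpec("tbxta", 1.0))

    def test_monotone_response_to_single_input(self, rng):
        """A gene fed only by one positive signal weight never decreases its
        endpoint when that signal is clamped higher."""
        E = np.zeros((2, 3))
        E[0, 1] = 6.0  # wnt -> tbx16 only
        params = make_params(E=E, R=np.full(3, 2.0), lam=np.full(3, 2.0))
        vals = rng.uniform(0, 1, (5, 21, 5))
        agets = AGETSet(np.arange(5), vals)
        grid = TimeGrid(21, 1.0, 10)
        prev = None
        for clamp in (0.0, 0.5, 1.0, 1.5):
            sim = live_model(
                perturb_signals(agets, PerturbationSpec("wnt", clamp)), params, grid
            )
            end = sim.genes[:, -1, 1]
            if prev is not None:
                assert np.all(end >= prev - 1e-12)
            prev = end


class TestParameterSerialization:
    def test_round_trip_has_24_scalars(self, rng):
        params = make_params(
            W=rng.normal(0, 5, (3, 3)), E=rng.normal(0, 5, (2, 3)),
            R=rng.uniform(0, 2, 3), lam=rng.uniform(0.1, 2, 3),
            h=rng.normal(0, 2, 3),
        )
        vec = params.to_vector()
        assert vec.shape == (24,)
        back = GRNParameters.from_vector(vec)
        assert np.array_equal(back.to_vector(), vec)
        json_back = GRNParameters.from_json(params.to_json())
        assert np.array_equal(json_back.to_vector(), vec)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            GRNParameters.from_vector(np.zeros(23))
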