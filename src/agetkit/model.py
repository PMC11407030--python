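"""Connectionist GRN dynamics simulated independently in every tracked cell.

The mRNA concentration g_a(t) of each T-box gene obeys

    dg_a/dt = R_a * phi(u_a) - lambda_a * g_a,
    u_a     = sum_b W_ba g_b + sum_s E_sa g_s + h_a,
    phi(u)  = (u / sqrt(u^2 + 1) + 1) / 2,

where b ranges over the three genes and s over the two signalling inputs
(Wnt, FGF).  Signal concentrations g_s(t) are read from the cell's AGET and
interpolated linearly between frames, which makes the system non-autonomous:
the same 24 parameters are shared by all cells, but each cell sees its own
signalling history and starts from its own first-frame gene levels
("live-modelling").

Parameters (24 scalars): W is 3x3 (regulator-major: W[b, a] is the action of
gene b on gene a), E is 2x3 (E[s, a]: signal s on gene a), R (production
rates), lambda (first-order decay rates, must be positive) and h (basal
regulatory bias) are length-3.  Weights are dimensionless; R and lambda are
in concentration/time and 1/time on the model's dimensionless time scale, in
which 1.0 spans the whole lapse (the transit time of the fastest cell).

The integrator is fixed-step classical fourth-order Runge-Kutta with a
configurable number of sub-steps per frame interval; dynamics on these time
scales are smooth and non-stiff, and a fixed grid keeps likelihood
evaluations bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .agets import AGETSet
from .schema import GENES, N_GENES, N_SIGNALS, SIGNALS, SchemaError, signal_index

N_PARAMS = 24  # 9 W + 6 E + 3 R + 3 lambda + 3 h


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameters


@dataclass
class GRNParameters:
    W: np.ndarray  # (3, 3) gene -> gene, regulator-major
    E: np.ndarray  # (2, 3) signal -> gene
    R: np.ndarray  # (3,) production rates
    lam: np.ndarray  # (3,) decay rates
    h: np.ndarray  # (3,) basal thresholds

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float).reshape(N_GENES, N_GENES)
        self.E = np.asarray(self.E, float).reshape(N_SIGNALS, N_GENES)
        self.R = np.asarray(self.R, float).reshape(N_GENES)
        self.lam = np.asarray(self.lam, float).reshape(N_GENES)
        self.h = np.asarray(self.h, float).reshape(N_GENES)

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 24-vector (W row-major, E, R, lam, h)."""
        return np.concatenate(
            [self.W.ravel(), self.E.ravel(), self.R, self.lam, self.h]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "GRNParameters":
        theta = np.asarray(theta, float).ravel()
        if theta.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got {theta.shape}")
        return cls(
            W=theta[:9].reshape(3, 3),
            E=theta[9:15].reshape(2, 3),
            R=theta[15:18],
            lam=theta[18:21],
            h=theta[21:24],
        )

    def to_json(self) -> str:
        doc = {
            "schema": {"genes": list(GENES), "signals": list(SIGNALS)},
            "W": self.W.tolist(),
            "E": self.E.tolist(),
            "R": self.R.tolist(),
            "lam": self.lam.tolist(),
            "h": self.h.tolist(),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GRNParameters":
        doc = json.loads(text)
        missing = [k for k in ("W", "E", "R", "lam", "h") if k not in doc]
        if missing:
            raise SchemaError(f"parameter JSON missing blocks {missing}")
        p = cls(
            W=np.array(doc["W"]), E=np.array(doc["E"]),
            R=np.array(doc["R"]), lam=np.array(doc["lam"]), h=np.array(doc["h"]),
        )
        if p.to_vector().size != N_PARAMS:
            raise SchemaError("parameter JSON does not contain 24 scalars")
        return p


PARAM_NAMES: tuple[str, ...] = tuple(
    [f"W[{b}->{a}]" for b in GENES for a in GENES]
    + [f"E[{s}->{a}]" for s in SIGNALS for a in GENES]
    + [f"R[{a}]" for a in GENES]
    + [f"lam[{a}]" for a in GENES]
    + [f"h[{a}]" for a in GENES]
)

# R and lambda carry positivity-restricted priors (rates cannot be negative).
POSITIVE_PARAM_INDICES: tuple[int, ...] = tuple(range(15, 21))


@dataclass
class TimeGrid:
    """Frame-aligned simulation grid on dimensionless model time."""

    n_frames: int = 61
    total_span: float = 1.0
    substeps: int = 10

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.total_span <= 0 or self.substeps < 1:
            raise ValueError("total_span must be > 0 and substeps >= 1")

    @property
    def frame_dt(self) -> float:
        return self.total_span / (self.n_frames - 1)

    @property
    def frame_times(self) -> np.ndarray:
        return np.linspace(0.0, self.total_span, self.n_frames)


@dataclass
class PerturbationSpec:
    """Clamp one signalling channel to a fixed value over an interval."""

    signal: str
    value: float
    frame_range: tuple[int, int] | None = None  # 1-based inclusive; None = all

    def __post_init__(self) -> None:
        signal_index(self.signal)  # raises SchemaError on unknown signal
        if self.value < 0:
            raise ValueError("clamp value must be >= 0")


# ---------------------------------------------------------------------------
# model right-hand side


def phi(u):
    """Sigmoid regulation-expression function; maps R -> (0, 1), phi(0)=1/2."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("phi: non-finite regulatory input")
    return 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)


def regulatory_input(g, s, params: GRNParameters) -> np.ndarray:
    """u_a = sum_b W_ba g_b + sum_s E_sa g_s + h_a."""
    g = np.asarray(g, float)
    s = np.asarray(s, float)
    if g.shape[-1] != N_GENES or s.shape[-1] != N_SIGNALS:
        raise SchemaError(
            f"expected gene vector of {N_GENES} and signal vector of "
            f"{N_SIGNALS}, got {g.shape} and {s.shape}"
        )
    return g @ params.W + s @ params.E + params.h


def rhs(g, s, params: GRNParameters) -> np.ndarray:
    """dg_a/dt = R_a phi(u_a) - lambda_a g_a."""
    u = regulatory_input(g, s, params)
    return params.R * phi(u) - params.lam * np.asarray(g, float)


# ---------------------------------------------------------------------------
# batched integrator
#
# The MCMC evaluates many parameter sets against many cells; everything is
# vectorized over a leading parameter-set axis K and a cell axis C.


def _phi_raw(u):
    return 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)


def simulate_batch(
    theta: np.ndarray,
    g0: np.ndarray,
    signals: np.ndarray,
    grid: TimeGrid,
) -> np.ndarray:
    """Integrate the GRN for K parameter sets x C cells simultaneously.

    theta: (K, 24) canonical parameter vectors; g0: (C, 3) initial gene
    levels; signals: (C, n_frames, 2) per-frame Wnt/FGF values, linearly
    interpolated inside each frame interval.  Returns (K, C, n_frames, 3)
    gene trajectories sampled at frame times.
    """
    theta = np.atleast_2d(np.asarray(theta, float))
    K = theta.shape[0]
    C, T, _ = signals.shape
    if T != grid.n_frames:
        raise ValueError("signals and grid disagree on frame count")
    W = theta[:, :9].reshape(K, 3, 3)
    E = theta[:, 9:15].reshape(K, 2, 3)
    R = theta[:, 15:18][:, None, :]
    lam = theta[:, 18:21][:, None, :]
    h = theta[:, 21:24][:, None, :]
    if np.any(lam <= 0):
        raise SimulationError("decay rates must be strictly positive")

    g = np.broadcast_to(np.asarray(g0, float), (K, C, 3)).copy()
    out = np.empty((K, C, T, 3))
    out[:, :, 0] = g
    dt = grid.frame_dt / grid.substeps
    m = grid.substeps

    def f(g, s):
        # s: (C, 2) shared across parameter sets at a given time;
        # batched matmul broadcasts (K,C,3)@(K,3,3) and (C,2)@(K,2,3)
        u = g @ W + s @ E + h
        return R * _phi_raw(u) - lam * g

    for t in range(T - 1):
        s0 = signals[:, t]
        ds = signals[:, t + 1] - s0
        for j in range(m):
            sa = s0 + ds * (j / m)
            sm = s0 + ds * ((j + 0.5) / m)
            sb = s0 + ds * ((j + 1.0) / m)
            k1 = f(g, sa)
            k2 = f(g + 0.5 * dt * k1, sm)
            k3 = f(g + 0.5 * dt * k2, sm)
            k4 = f(g + dt * k3, sb)
            g = g + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(g)):
            raise SimulationError(f"non-finite state after frame {t + 2}")
        out[:, :, t + 1] = g
    return out


# ---------------------------------------------------------------------------
# public simulation surface


@dataclass
class CellSimulation:
    track_id: int
    times: np.ndarray  # (n_frames,)
    genes: np.ndarray  # (n_frames, 3) simulated
    signals: np.ndarray  # (n_frames, 2) inputs as used
    metadata: dict = field(default_factory=dict)


def simulate_cell(
    aget: np.ndarray,
    params: GRNParameters,
    grid: TimeGrid,
    track_id: int = -1,
) -> CellSimulation:
    """Integrate one cell's GRN from its AGET.

    ``aget`` is the (n_frames, 5) channel matrix of a single cell; initial
    gene levels are its first-frame gene values, Wnt/FGF are read per frame.
    """
    aget = np.asarray(aget, float)
    if aget.ndim != 2 or aget.shape[1] != 5:
        raise ValueError(f"cell AGET must be (n_frames, 5), got {aget.shape}")
    if aget.shape[0] != grid.n_frames:
        raise ValueError("cell AGET and grid disagree on frame count")
    g0 = aget[0, :N_GENES][None, :]
    sig = aget[None, :, N_GENES:]
    try:
        traj = simulate_batch(params.to_vector()[None, :], g0, sig, grid)
    except SimulationError as e:
        raise SimulationError(f"cell {track_id}: {e}") from e
    return CellSimulation(
        track_id=track_id,
        times=grid.frame_times,
        genes=traj[0, 0],
        signals=aget[:, N_GENES:].copy(),
    )


def live_model(agets: AGETSet, params: GRNParameters, grid: TimeGrid) -> AGETSet:
    """Simulate every cell independently; return simulated genes + the input
    signal channels, frame-aligned with the input for likelihood computation
    and reporter export."""
    if agets.n_frames != grid.n_frames:
        raise ValueError("AGET set and grid disagree on frame count")
    g0 = agets.genes[:, 0, :]
    traj = simulate_batch(params.to_vector()[None, :], g0, agets.signals, grid)
    values = np.concatenate([traj[0], agets.signals], axis=2)
    prov = dict(agets.provenance)
    prov["simulated"] = True
    return AGETSet(agets.track_ids.copy(), values, provenance=prov)


def perturb_signals(agets: AGETSet, spec: PerturbationSpec) -> AGETSet:
    """Clamp one signal channel in every cell over the active interval."""
    out = agets.copy()
    si = N_GENES + signal_index(spec.signal)
    if spec.frame_range is None:
        out.values[:, :, si] = spec.value
    else:
        lo, hi = spec.frame_range
        if not (1 <= lo <= hi <= agets.n_frames):
            raise ValueError(f"frame range {spec.frame_range} outside lapse")
        out.values[:, lo - 1 : hi, si] = spec.value
    prov = dict(out.provenance)
    prov.setdefault("perturbations", []).append(
        {"signal": spec.signal, "value": spec.value, "frame_range": spec.frame_range}
    )
    out.provenance = prov
    return out
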