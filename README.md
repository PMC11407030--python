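# agetkit

Reverse-engineering gene regulatory networks from hybrid live/fixed imaging
data of the zebrafish presomitic mesoderm (PSM).

Live imaging tells you where every cell goes but not what it expresses;
quantitative in-situ imaging (HCR) tells you what fixed cells express but
not where they came from. `agetkit` fuses the two: it registers fixed-sample
3D expression point clouds onto live-imaging cell tracks and assigns each
tracked cell, at each frame, the expression of its nearest fixed-sample
neighbours. The result is an **Approximated Gene Expression Trajectory
(AGET)** per cell — a per-cell time series for the T-box genes *tbxta*,
*tbx16*, *tbx6* and the Wnt and FGF signalling environments.

AGETs then power "live-modelling": a connectionist GRN ODE is simulated
independently in every cell,

$$\frac{dg_a}{dt} = R_a\,\phi(u_a) - \lambda_a g_a,\qquad
\phi(u) = \tfrac12\Big(\tfrac{u}{\sqrt{u^2+1}}+1\Big),\qquad
u_a = \sum_{b\in G} W_{ba} g_b + \sum_{s\in S} E_{sa} g_s + h_a,$$

with $G=\{tbxta, tbx16, tbx6\}$, $S=\{Wnt, FGF\}$. Initial gene levels and
the time-varying signal inputs are read from each cell's AGET (the system is
non-autonomous). The 24 free parameters ($W$ 3×3, $E$ 2×3, $R$, $\lambda$,
$h$) are fitted by affine-invariant ensemble MCMC against a random subset of
AGETs, with a Gaussian likelihood ($\sigma$ = 0.2, 0.2, 0.1 per gene) and
uniform priors on $[-200, 200]$ (rates restricted to positive values).
Converged posteriors are filtered (overall log-likelihood ≥ −15000, weights
within ±100), z-scaled and k-means clustered into network topologies, and
interrogated with in-silico perturbations (e.g. clamping Wnt to 1.5 or FGF
to 0.01 in every cell).

A synthetic-embryo generator produces PSM-like tapered point clouds,
61-frame cell tracks with posterior mixing, and exact forward-simulated
AGETs under a known sparse network, so the whole pipeline is testable
without any imaging data.

## Worked example

```python
import numpy as np
from agetkit import (SyntheticConfig, TimeGrid, default_ground_truth,
                     forward_simulate_agets, generate_tracks, live_model)
from agetkit.inference import (LikelihoodSpec, MCMCConfig, PriorSpec,
                               run_mcmc, select_fitting_agets, select_map)

cfg = SyntheticConfig(n_tracks=60, n_frames=61, seed=11)
tracks = generate_tracks(cfg)
truth = default_ground_truth()          # sparse network, 4 strong weights
grid = TimeGrid(61, 1.0, substeps=4)
all_agets = forward_simulate_agets(tracks, truth, grid)
# fit posterior-starting cells: they transit the Wnt/FGF gradient and
# therefore constrain the network
targets = select_fitting_agets(all_agets, tracks, n=25,
                               anterior_exclusion=0.5, seed=101)

mcmc = MCMCConfig(n_walkers=64, n_steps=3500, max_extensions=0, seed=7)
ensemble = run_mcmc(targets, LikelihoodSpec(), PriorSpec(), mcmc, grid)
map_params = select_map(ensemble)
sim = live_model(targets, map_params, grid)
rms = np.sqrt(((sim.genes - targets.genes) ** 2).mean(axis=(0, 1)))
print("per-gene live-model RMS:", rms.round(4))
print("Wnt->tbx16 weight (truth +8):", round(map_params.E[0, 1], 2))
```

This run (a few minutes on one CPU) prints

```
per-gene live-model RMS: [0.0153 0.014  0.0094]
Wnt->tbx16 weight (truth +8): 30.97
```

The MAP network reproduces every fitted trajectory to within ~0.015
expression units, and all four strong ground-truth interactions
(Wnt→*tbx16* +, FGF→*tbx16* +, FGF⊣*tbxta* −, *tbx16*→*tbx6* +) come back
with the correct sign. Weight *magnitudes* are loosely constrained — the
sigmoid saturates, so doubling an already-strong weight barely changes the
trajectories — which is exactly why downstream analysis works with sign
consensus and topology clusters rather than point estimates.

The same stages are scriptable from the shell:

```sh
agetkit synth --out data --seed 1          # clouds + tracks + truth AGETs
agetkit align --sources data --tracks data/tracks.csv --out aligned
agetkit build --tracks data/tracks.csv --sources data \
              --alignments aligned/alignments.json --out built
agetkit fit   --agets built/agets.csv --tracks data/tracks.csv --out fit
agetkit perturb --agets built/agets.csv --params fit/map_params.json \
                --clamp wnt=1.5 --out pert
```

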