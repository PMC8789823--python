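# smtrack

Single-molecule tracking (SMT) analysis of membrane receptor-kinase
dynamics: diffusion-state segmentation, membrane-domain confinement,
two-channel interaction kinetics, oligomer stoichiometry, and the
quantification rules for split-luciferase / BRET plate assays.

The package is written for dual-color TIRF experiments of the kind used
to study GPCR regulation — e.g. an angiotensin receptor (AT1R) imaged
together with a GPCR kinase (GRK) — where each movie yields a few hundred
linked single-particle trajectories per channel at ~30 ms frame intervals.
Everything downstream of spot detection and linking lives here.

## What it computes

**Diffusion states (VB-HMM).** Each trajectory contributes a chain of 2-D
displacements d_t = r(t+1) − r(t), modeled as zero-mean Gaussians whose
per-axis variance σ²_k depends on a hidden Markov state k. With conjugate
priors (Dirichlet on π and the rows of the transition matrix A, Gamma on
the precisions) the model is fitted by variational Bayes, and the number
of states K is selected by the highest variational lower bound. States
are ordered by mobility — immobile, slow, medium, fast for K = 4 — and
D_k = max(0, (σ²_k − 2σ_loc²)/(2Δt)) corrects for localization noise.

**Confinement (MSD).** Per state, a responsibility-weighted
mean-square-displacement curve is fitted with the square-domain confined
model msd(t) = (L²/3)(1 − e^(−12Dt/L²)) + c, giving the confinement
length L of the membrane domain restricting the slow states. Localization
precision follows the Gaussian-PSF least-squares formula
σ_loc² = F·(σ_a²/N)·(16/9 + 8πσ_a²b²/(Na²)), σ_a² = σ_psf² + a²/12.

**Colocalization kinetics.** Two particles colocalize in a frame when
they are within 100 nm *and* share a diffusion state. Events (merged
consecutive frames of a greedily matched pair) yield an on-event rate per
receptor particle-second and a dissociation rate from a left-truncated,
right-censored exponential fit to event durations, with a circular-shift
chance baseline for the density-driven coincidence rate.

**Oligomer orders.** Spot-intensity histograms per state are decomposed
into a constrained Gaussian mixture with component means n·µ₁ and SDs
√n·σ₁ (n = 1..4), anchored on the fast-state population assumed
monomeric; the mean order Σn·w_n summarizes stoichiometry.

**Assay quantification.** Baseline fold change, fixed-window averaging
(13–15 min; 27–30 min with per-timepoint vehicle normalization for
receptor internalization), and the BRET index I_acceptor/(I_donor+I_acceptor)
with its before/after fold change.

A synthetic two-channel trajectory generator with full ground truth
(states, binding intervals, oligomer orders) backs every stage with
parameter-recovery tests; no external data are required. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import smtrack as st
from smtrack.msd import state_msd, fit_msd

cfg = st.default_config()                    # 4-state, 30.5 ms, 300 frames
ts, truth = st.simulate_tracks(cfg, seed=1)  # two channels + ground truth

model, assign, table = st.select_model(ts.channel(1), range(1, 9),
                                       seed=1, sigma_loc=cfg.sigma_loc)
print("selected K =", model.K)
print("D =", [round(d, 3) for d in model.D], "um^2/s")

fit = fit_msd(state_msd(ts.channel(1), assign, 1), model="confined")
print(f"immobile-state confinement L = {fit.L*1e3:.0f} nm")
```

prints

```
selected K = 4
D = [0.003, 0.031, 0.153, 0.49] um^2/s
immobile-state confinement L = 124 nm
```

The lower bound peaks at K = 4 (the simulated truth); the recovered
diffusion coefficients bracket the generating values 0.005/0.04/0.15/0.5
µm²/s (the slowest two are reduced by domain confinement, as expected),
and the immobile-state confinement length matches the simulated 120 nm
domain. The numbered scripts under `analysis/` run the same pipeline
end to end — simulation, segmentation, confinement, colocalization,
oligomer orders, assay quantification, condition summary — writing their
tables under `results/`:

```sh
python analysis/01_simulate.py 1
python analysis/02_segment.py 1
...
```

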