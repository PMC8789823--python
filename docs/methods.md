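# Methods

This note documents the models behind `smtrack`, the choices that were
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Scope and data model

The pipeline starts from linked trajectories — one row per localization
(`cell_id, channel, track_id, frame, x_um, y_um, intensity`) — not from raw
movies. Spot detection, linking and channel registration are upstream
concerns. Positions are stored in micrometres; pixel-scale inputs are
converted with the acquisition metadata (pixel size, default 67 nm).
Frames are 0-based, and an event spanning inclusive frames
`[start, end]` has duration `(end − start + 1)·dt`; this convention is
used everywhere so duration arithmetic is unambiguous.

## Synthetic trajectory generator

The generator emulates a dual-color TIRF single-molecule acquisition of a
membrane receptor and a cytosolic kinase visiting the membrane:

- **Switching diffusion.** Each particle carries a hidden state from a
  K-state Markov chain with per-frame transition matrix `A` and initial
  distribution `pi`. In state k the true position takes an isotropic
  Gaussian step with per-axis variance `2·D_k·dt`.
- **Confinement.** A confined state restricts motion to an `L × L` square
  domain by billiard reflection. The domain is anchored at the position
  where the particle entered the state. A square domain was chosen to
  match the square-domain MSD formula used by the fitter; circular domains
  would change the plateau constant by a few percent, well inside the
  tolerances used here.
- **Observation.** Observed positions are true positions plus Gaussian
  localization noise of SD `sigma_loc` per axis (static-noise model;
  motion blur is not simulated). Tracks end by geometric photobleaching
  (`bleach_rate` per-frame survival) or movie end; blinking and gaps are
  not simulated, so re-linking is never needed.
- **Scripted binding.** Channel-2 particles bind channel-1 particles as a
  Poisson process (`k_on_script` per free particle per second). A bound
  particle is tethered to its partner — its position is the partner's plus
  an i.i.d. Gaussian offset (`bound_offset_sd`) each frame, and its state
  label follows the partner's — for an exponential lifetime with mean
  `mean_lifetime`, truncated by track/movie end (recorded as censored).
  Partners are exclusive: a channel-1 particle holds one channel-2 partner
  at a time, matching 1:1 receptor-kinase engagement and keeping the
  scripted events non-overlapping per pair. Because tethering relocates
  the bound particle, channel-2 tracks are split at each binding start —
  the bound stretch begins a new track, the way a cytosolic protein
  appears at the membrane on recruitment in TIRF — so no relocation
  artifact ever enters a displacement statistic; on release the
  trajectory continues from the release position.
- **Intensities.** Each track has an oligomer order n drawn from a
  per-state weight vector; frame intensities are Gaussian with mean
  `n·mu1` and SD `sqrt(n)·cv1·mu1`. The `sqrt(n)` scaling assumes
  independent emitters (standard photon statistics).

**Default configuration** (`smtrack/configs/default.yaml`): K = 4 states
(immobile, slow, medium, fast) with D = 0.005, 0.04, 0.15, 0.5 µm²/s; a
sticky symmetric transition matrix (diagonal 0.92, uniform stationary
distribution, mean dwell ≈ 0.38 s); immobile and slow states confined to
L = 120 and 220 nm domains; `sigma_loc` = 25 nm; dt = 30.5 ms; 300 frames;
200 tracks per channel on a 21 µm field (0.45 particles/µm² initially,
drifting to ≈ 0.3 under bleaching — inside the 0.3–0.6 /µm² working band
of a usable single-molecule field of view). The acquisition parameters
(dt, movie length, density band, pixel size, 90–250 nm confinement range)
reflect the imaging regime this pipeline targets; the kinetic numbers
(D values, dwell times, binding rates, oligomer weights) are plausible
values for a GPCR/GRK system chosen once from the membrane-protein SMT
literature — they are synthetic, not measurements.

What the generator does **not** emulate: localization-precision
heterogeneity across states (one global `sigma_loc`), motion blur,
blinking/mislinking, channel misregistration, non-exponential binding,
and anomalous (non-Markovian) diffusion. Passing recovery tests therefore
show the estimators are correct under the stated model, not that real
data satisfy that model.

## Displacement VB-HMM

Each track contributes an independent chain of 2-D displacement vectors
`d_t = r_{t+1} − r_t`; tracks are split at frame gaps and chains shorter
than one displacement are excluded (counted and logged). The emission for
state k is a zero-mean isotropic Gaussian with per-axis variance
`sigma2_k`; the per-axis precision gets a conjugate Gamma(10⁻³, 10⁻³)
prior, and the initial distribution and transition rows get symmetric
Dirichlet(1) priors. Variational inference alternates a forward-backward
E-step under the expected-log ("tilde") parameters with closed-form
Dirichlet/Gamma M-steps. The variational lower bound is the sum of chain
log-normalizers minus the Dirichlet and Gamma KL divergences; it is
monotone over iterations (asserted in tests to 10⁻⁸ relative tolerance).

- **Initialization and restarts.** The first start is a quantile split of
  log squared displacement into K bins; subsequent restarts (default 5)
  randomly perturb 30% of the initial labels. The restart with the
  highest converged bound wins; ties break by first index.
- **Convergence.** Relative lower-bound change < 10⁻⁸ or 1000 iterations.
- **Canonical order.** States are sorted by ascending `sigma2`, so state 1
  is always "immobile" and state K "fast".
- **Noise handling.** The fitted `sigma2_k` absorbs the static
  localization-noise floor; the diffusion coefficient is reported as
  `D_k = max(0, (sigma2_k − 2·sigma_loc²)/(2·dt))`.
- **Labels.** The hard label of the displacement leaving a frame defines
  the per-frame particle label; a track's last frame inherits the previous
  label. This makes the same-state colocalization criterion well defined
  at every frame.
- **Model selection.** Each K in the candidate range is fitted
  independently; the model with the highest lower bound is selected and
  the full (K, lower bound) table is reported.

Parameters are pooled globally across cells within a condition and fitted
per channel; per-cell models and joint two-channel fits are possible
extensions but match neither the pooled reporting downstream nor the
species-specific dynamics.

The E-step is exact: on tiny chains its marginals are checked against
brute-force enumeration over all label sequences to 10⁻¹⁰ (both the
single-chain reference implementation and the batched compiled kernel).

## MSD and confinement

The plain ensemble MSD pools all displacement pairs per lag — identical
to time-averaging per segment and ensemble-averaging with pair-count
weights, which is asserted by brute force. State-wise curves are built
from maximal runs of constant hard label (runs shorter than 4 frames are
dropped), with each pair additionally weighted by the product of the
state's posterior responsibilities over the displacements it spans. This
weighting exists because hard labels are imperfect: a briefly
misassigned stretch inside a run bridges two distinct confinement
domains, and pairs straddling it inflate the apparent plateau. In
ground-truth simulations the responsibility product recovers the true
domain size markedly better than unweighted pairs; the exact posterior
probability that the span stayed in the state (initial responsibility
times the product of conditional stay probabilities, available as
``stay_k`` columns) was evaluated as an alternative weight but
discriminates bridged pairs worse, because a sticky chain discounts all
long spans nearly uniformly. Residual inflation from confidently
mislabeled frames remains — roughly 10% for a slow state whose
displacement distribution overlaps its neighbors — and is an information
limit of posterior labeling, worth remembering when an estimate sits
near a domain-size bound. The default fit range is the first 10 lags;
longer lags are pair-starved in 300-frame movies.

Fits are weighted least squares (weights = pair counts):

- free: `msd(t) = 4·D·t + c`
- confined (square domain, leading order):
  `msd(t) = (L²/3)·(1 − exp(−12·D·t/L²)) + c`

The offset `c` is fitted rather than pinned to `4·sigma_loc²` so a
mis-specified noise model cannot bias `L`. The confined fit uses a bounded
multistart over plateau scales. When the implied plateau `L²/3` exceeds
the observed MSD at the largest fitted lag by more than 10×, the curve is
flagged unconfined (the plateau is not expressed in the data). Conversely,
when the plateau is reached before the first lag, (D, L, c) are not
separately identifiable and only the plateau level is meaningful — the
parameter-grid test asserts exactly that. The exact series solution for a
square domain is a possible extension; at the tolerances used here the
leading-order form is sufficient.

Localization precision follows the least-squares Gaussian-PSF formula
with pixelation correction `σ_a² = σ_psf² + a²/12` and background term
`sigma_loc² = F_em·(σ_a²/N)·(16/9 + 8π·σ_a²·b²/(N·a²))`, with excess-noise
factor `F_em = 2` by default for EM-CCD detection.

## Colocalization kinetics

Two particles colocalize in a frame when they are within 100 nm (about
2–3 SD of the pairwise localization accuracy at the default noise level)
**and** carry the same diffusion-state label. Frame-wise candidate pairs
are made mutually exclusive by greedy nearest-distance assignment
(deterministic after a distance-then-index sort); consecutive matched
frames of one pair merge into an event, and a single-frame gap ends the
event (no bridging — conservative splitting). The same-state requirement
is applied per frame, not per event; the event's reported state is the
majority label.

The on-event rate is new events per channel-1 particle-second (receptor-
referenced association). The dissociation rate is a closed-form
exponential MLE, left-truncated at the minimum observable duration (one
frame) and right-censored at track/movie end:
`k_off = n_uncensored / Σ(d_i − t_trunc)`, with a Wald CI on the log
rate. With no censoring this reduces to `1/(mean − t_trunc)`, asserted in
tests; the naive uncensored estimate is reported alongside because
whether a bleaching/censoring correction should be applied to real data
is a judgement call. By memorylessness, the truncation point can be moved
up (e.g. to two frames) to exclude the shortest duration bin, which is
dominated by chance coincidences at realistic densities — the recovery
tests use this.

Because ~0.3–0.6 particles/µm² makes chance proximity non-negligible, a
circular-shift null is provided: channel-2 tracks are rigidly displaced
by random wrapped offsets within the field and detection is re-run,
preserving densities and motion statistics while destroying real
correlations.

## Oligomer orders from intensities

Spot intensities per state are decomposed by an EM-fitted Gaussian
mixture whose component n has mean `n·mu1` and SD `sqrt(n)·sigma1`, with
only the weights free (n_max = 4 by default; higher orders fold into the
top component). The monomer anchor `(mu1, sigma1)` is estimated from the
fast-state population, which is assumed monomeric; fitting the anchor
free is supported. Intensities are taken from each track's first 10
frames to limit photobleaching bias. The mean oligomer order is
`Σ n·w_n`; condition contrasts use a seeded nonparametric bootstrap over
spots (percentile CI, default 1000 resamples). EM responsibilities equal
direct Bayes computation (asserted to 10⁻¹⁰), the likelihood is monotone,
and the fit is scale-equivariant.

## Assay quantification

Plate kinetics are normalized to the pre-ligand baseline read (the last
read before addition; t = 0 is the first post-ligand read, so
early-responding sensors may deviate from 1 already at t = 0). The
response is the mean of normalized counts inside the stated window —
13–15 min for complementation assays; for the surface-receptor
internalization assay each time point is first divided by the matched
vehicle series and the 27–30 min window is averaged. The BRET index is
`I_acceptor/(I_donor + I_acceptor)`; the per-cell fold change is the
index ≈ 14 min after stimulation over the index before. Replicates
aggregate as mean across within-experiment duplicates, then mean ± SEM
across experiments. Statistical testing (ANOVA families, 4PL fits) is
out of scope.

## Reporting

The cell is the unit of replication throughout: track-level data only
ever feed per-cell metrics, and condition tables report mean ± SEM across
cells (SEM is left missing for a single cell, never fabricated). Runs
emit a manifest with the config hash, seed and package version.

## Problem sizes

The default verification runs use one simulated cell with 200 tracks per
channel × 300 frames (≈ 4·10⁴ displacements per channel) for model
selection and confinement; recovery runs use ≥ 10⁴ displacements for
diffusion/fraction recovery and ≥ 500 scripted events for kinetic
recovery. These sizes put the sampling error comfortably below the
tolerances being asserted while keeping a full verification run in the
minutes range on one core.
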