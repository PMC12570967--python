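# Methods

## The model

`potts-surrogate` implements a stochastic Cellular-Potts (Glazier–Graner–
Hogeweg) model of in vitro vasculogenesis together with a learned
generative surrogate of it. In the Cellular-Potts model each biological
cell is the set of lattice sites sharing an integer id σ on a square
periodic lattice (0 is the acellular medium). The configuration evolves by
pixel-copy attempts biased by an effective energy

    H = Σ_{⟨i,j⟩} J_{τ(σ_i),τ(σ_j)} (1 − δ_{σ_i,σ_j})
      + λ_volume (V_cell − V_target)²
      + λ_surface (S_cell − S_target)²

plus a per-attempt chemotaxis bias

    ΔH_chem = −λ_chem [ c(x_dest)/(s·c(x_dest)+1) − c(x_src)/(s·c(x_src)+1) ]

where c is a diffusive cytokine field obeying

    ∂c/∂t = D ∇²c − k c + secretion,

secretion acting at every cell-occupied voxel. A copy attempt proposes
that a destination voxel adopt the id of a neighbouring source voxel and
is accepted with the Boltzmann rule Pr = exp(−max(0, ΔH/H′)), H′ being
the Potts temperature. One Monte-Carlo step (MCS) is `lattice_size²`
attempts — one per site on average, the conventional definition. Cells
secrete the cytokine, chemotax up its gradient, adhere differentially to
each other and to medium, and self-organise into branched networks
enclosing lacunae.

Baseline parameters: λ_volume = 5, V_target = 50, λ_surface = 1,
S_target = 16.8, J_cell,medium = 8.2 (varied 0–20 across experiments),
J_cell,cell = 6, λ_chemotaxis = 2000, s = 0.5, k = 0.6 (varied 0.05–0.6),
H′ = 8, on a 256² lattice with ~1000 cells.

### Conventions the energy does not fix

* **Contact/surface neighbourhood.** The contact sum and the surface
  count use the 4-neighbourhood (von Neumann) by default, so surface
  units are boundary-face counts; both are configurable to the
  8-neighbourhood and must agree with each other for the incremental ΔH
  to telescope exactly.
* **Copy neighbourhood.** Pixel-copy candidates are Moore (8)
  neighbours, the common Cellular-Potts practice; configurable.
* **Chemotaxis applicability.** The chemotaxis term is applied to every
  attempt in which source or destination belongs to a cell. Same-id
  attempts are skipped upstream, so medium-to-medium moves never occur.
* **Coordinates** are row-major, 0-based, periodic on both axes, for the
  Potts dynamics and the PDE alike.

### Diffusion solver

Forward Euler with the 5-point periodic Laplacian, `pde_steps_per_mcs`
sub-steps per MCS (dt = 1/pde_steps_per_mcs, dx = 1). Each sub-step is
operator-split: diffuse, then decay multiplicatively by (1 − k·dt), then
secrete. The multiplicative decay makes a uniform field decay exactly as
(1 − k·dt)^n and keeps the field non-negative whenever the diffusion CFL
bound D·dt ≤ 0.25 holds; both D·dt ≤ 0.25 and k·dt ≤ 1 are enforced when
parameters are constructed, not during stepping. The field starts at
c = 0 everywhere.

### Constants the energy table does not provide

D, the secretion magnitude and the PDE sub-step count are not fixed by
the baseline parameter table. Defaults are D = 1.0 voxel²/MCS and
`pde_steps_per_mcs` = 4 (stability-safe at D = 1). The secretion rate was
calibrated once by simulation: at secretion 1.0 the steady-state
concentration near cells (≈ secretion/k) saturates the chemotaxis
potential and the λ_chem = 2000 bias overwhelms the volume constraint —
most cells are crushed to zero volume within 1000 MCS. At secretion 0.1
all cells survive, a standing gradient forms around every cell, and the
chemotactic bias is of the same order as the adhesion and constraint
terms. The default is therefore `secretion_rate = 0.1`; all three
constants are config-exposed.

### Initialisation

Cells are seeded as square blobs of side round(√V_target) (49 voxels at
V_target = 50). Anchors are a seeded random subset of a blob-spaced grid
with a random global offset, which is collision-free by construction and
succeeds at any admissible density — purely sequential random placement
of 7×7 squares jams near 56 % coverage and cannot reach the ~75 %
coverage of 1000 cells on a 256² lattice. When even the blob-spaced grid
is too coarse (dense packings of few large cells) the spacing is
tightened and the seed blobs shrunk; the volume constraint re-grows cells
toward V_target within tens of MCS of burn-in, which erases the seed
geometry either way. Ids reaching volume 0 are removed from the live set;
there is no growth or division.

### Reproducibility

Each simulation owns a single seeded PCG64 generator; the per-MCS random
streams (sites, neighbour choices, acceptance uniforms) are drawn outside
the compiled sweep kernel, so a trajectory is a pure function of its
seed. Replicate r of class c uses seed `base_seed + c·10⁶ + r`.
Checkpoints are a single-file format (versioned JSON header + raw array
bytes) that is byte-identical for identical states.

## Training-data protocol

A base-parameter simulation is burned in for 10 000 MCS and saved as the
shared reference state t0. Every class of the 5×5 grid — J_cell,medium ∈
{0, 5, 10, 15, 20} × k ∈ {0.05, 0.1875, 0.325, 0.465, 0.6}, class index
row-major over (J, k) — resumes from that same t0 under its own
parameters (one shared t0, configurable to independent burn-ins) and
binary snapshots of the cell layer (foreground = any cell) are saved
every 100 MCS in the window [15 000, 20 001]. The window is read as
stamps start + n·interval ≤ 20 001, i.e. 15 000…20 000, because only 51
stamps per replicate yields the protocol's round dataset sizes: 100
replicates per class give 5100 images per class and 127 500 in total;
the 10-replicate evaluation variant gives 510 and 12 750. The planner
(`plan_dataset`) emits the identical manifest without simulating.

The desk-scale ("toy") preset exercises the same code paths in minutes on
one CPU: 64² lattice, 60 cells, 2×2 grid (J ∈ {0, 20} × k ∈ {0.05, 0.6}),
burn-in 1000 MCS, snapshots every 100 MCS in [1500, 2001], 5 replicates.

## Diffusion surrogate

The surrogate is a class-conditional denoising-diffusion model in the EDM
parameterisation. Training draws a noise level per sample from the
log-normal σ = exp(P_mean + P_std·z), corrupts the [−1, 1]-mapped binary
snapshot as x + σ·ε, and regresses the denoised estimate

    D(x; σ, y) = c_skip(σ)·x + c_out(σ)·F(c_in(σ)·x, c_noise(σ), y)

onto the clean image with weight λ(σ) = (σ² + σ_d²)/(σ·σ_d)². The
preconditioning coefficients are c_skip = σ_d²/(σ²+σ_d²),
c_out = σ·σ_d/√(σ²+σ_d²), c_in = 1/√(σ²+σ_d²), c_noise = ln(σ)/4, with
σ_d = 0.5 for data mapped to [−1, 1]; λ(σ)·c_out(σ)² = 1, so the loss is
computed unit-weighted in F-space. Conditioning y is the one-hot class
vector appended to the network input alongside a sinusoidal embedding of
c_noise.

Sampling integrates the probability-flow ODE with the deterministic
2nd-order Heun scheme over the warped schedule
σ_i = (σ_max^{1/ρ} + i/(N−1)(σ_min^{1/ρ} − σ_max^{1/ρ}))^ρ, ρ = 7,
N = 32 steps by default, σ ∈ [0.002, 80], starting from σ_max·ε with a
seeded generator. A generated image is a pure function of (weights,
config, label, seed); the [−1, 1] output is thresholded at 0 back to a
binary configuration. Generation uses the weights at the final training
step (no EMA averaging at desk scale).

**Desk-scale denoiser.** F is a fully-connected network (two hidden
layers of 256 SiLU units, ~600k parameters at 32×32) over flattened
pixels, trained with Adam (lr 10⁻³, batch 64, 6000 steps by default);
backprop is hand-written in numpy. This deliberately replaces the
full-scale U-Net configuration (256×256, multi-GPU, ~10⁷ steps), which
is out of scope here; the noise statistics, preconditioning, loss
weighting and sampler are the full method.

**Hyperparameter sweep.** `sweep_candidates` spans P_mean ∈ [−1.6, 1.6] ×
P_std ∈ [1.0, 3.0] as an n×n Cartesian grid (5×5 = 25 candidates by
default). Spacing is linear on both axes with a config override — the
selected full-scale value P_std = 1.667 is not a linear grid point, and
the spacing that produced it is not documented anywhere we could follow,
so linear is the default and any explicit list can be supplied.

## Verification and model selection

A single-channel image classifier (ClassifierContract) assigns a
*detected* class to each generated sample; the conditioning label is the
*intended* class. For a candidate surrogate, n samples are generated with
conditioning cycled uniformly over the classes and sequential seeds, and
the report collects per-class detected counts, the confusion matrix
(intended × detected), generation accuracy (diagonal fraction), and the
KL divergence of the detected class distribution from uniform,
Σ pᵢ ln(pᵢ·n) in natural log (the log base is a convention; natural log
makes the all-in-one-class maximum exactly ln n). KL near 0 means the
surrogate covers classes evenly; a surrogate that silently drops m of n
classes scores at least ln(n/(n−m)) — dropping 5 of 25 classes gives
ln 1.25 ≈ 0.223 — which is the mode-collapse signature the selection
procedure screens for. `select_best` ranks candidates lexicographically:
minimal KL first, ties broken by maximal accuracy, then by candidate
order; both criteria matter and no combination rule is canonical, so
KL-first encodes "uniform coverage before per-class
sharpness".

The classifier itself is a contract, not a fixed architecture: the
implementation wraps a scikit-learn multilayer perceptron over flattened
pixels (hidden layer 128, Adam, lr 0.001, 80/20 stratified
train/validation split, per-epoch validation accuracy recorded), which
meets the contract at desk scale. Any stronger single-channel network
can be substituted.

## Morphology metrics

Lacunae are connected background components: background connectivity 4,
foreground connectivity 8 (the standard complementary pair), periodic
stitching on by default (components touching across the wrap seams are
union-merged) because the simulation domain is periodic and has no
exterior. On non-periodic analysis, frame-touching components are treated
as exterior and excluded. Components below 4 voxels are suppressed as
single-voxel noise (configurable). Branch width is 2× the Euclidean
distance transform sampled at foreground-skeleton voxels; on periodic
domains the image is wrap-padded before skeletonisation/EDT and cropped
back. An image with no foreground yields "absent" (None / NaN in
reports) for both features — nothing can be quantified on an empty
configuration, mirroring how degenerate generated samples are reported.

Distributions of either feature are compared with the 1-D Wasserstein-1
(Earth Mover's) distance — the integral of |CDF_a − CDF_b|, computed by
`scipy.stats.wasserstein_distance` — pooled per class across snapshots.
Feature extraction of this kind is not standardised to the level of
connectivity or thresholds, so feature tables from other implementations
are not reproduction targets; the machinery and its invariants (symmetry, triangle inequality, translation equivariance) are.

## The toy end-to-end conditions

The procedural two-class dataset (class 0: horizontal stripes with random
phase, period 8, 1 % salt noise; class 1: wrap-smoothed Gaussian blobs at
50 % density; 500 images per class at 32×32) is the study condition for
the end-to-end property: a classifier trained on it reaches ≥ 0.9
held-out accuracy, and the desk-scale surrogate trained on it reaches
> 0.8 generation accuracy with KL-from-uniform < 0.1 under uniformly
cycled conditioning. What this shows: the full loop — noise schedule,
preconditioned training, deterministic conditional sampling,
classifier-based verification — is wired correctly and class conditioning
carries through sampling. What it does not show: fidelity on real
Cellular-Potts morphologies at 256², which needs the full-scale dataset
and a convolutional denoiser.

## Problem sizes used by the default test/acceptance runs

Oracle and invariant checks use 8²–32² lattices, ≥10⁴ random copy
attempts, 10⁵ acceptance trials, and 1000-MCS relaxation runs; the
simulation-data classifier check uses a 32² two-class reduced protocol;
the toy pipeline uses the 500-per-class 32×32 dataset above with a
6000-step training run. These sizes were chosen so the whole suite runs
in a few minutes on one CPU while every check retains its statistical
power (3-standard-error bounds where sampling noise is involved).

## Known limitations

* The Cellular-Potts neighbour-order conventions (contact order, copy
  candidates) of other Cellular-Potts implementations are rarely
  specified;
  identical parameter tables can therefore yield quantitatively
  different morphologies. Invariants and oracles, not golden images, are
  the correctness criteria for the simulator.
* The MLP denoiser has no translational inductive bias; at sizes much
  above 64² it underfits and a convolutional F should replace it (the
  module only assumes the DenoiserContract).
* Mass cell death is a real model regime (high chemotaxis-to-constraint
  ratio), not an error; the default constants avoid it at baseline.
* Between-class interpolation, guidance and full-scale benchmarks are
  out of scope.
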