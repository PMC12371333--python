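# Methods

## Problem and scope

gridbind implements a desk-scale version of a method stack for learning
protein–ligand binding affinity (pK = −log10 Kd/Ki) from molecular-dynamics
(MD) trajectories of the complex.  The stack has four parts:

1. **Featurization.** The binding site is voxelized: a cubic box (default
   edge 25 Å, 1 Å³ voxels) is placed around the ligand, and every heavy atom
   inside it deposits a 19-channel feature vector into the voxel containing
   it.  The pocket itself is defined once, on the crystallographic pose, as
   the residues with at least one heavy atom within 12 Å of the ligand's
   geometric center (inclusive boundary, center-to-any-heavy-atom; the
   alternative center-to-residue-centroid reading was rejected because it
   makes the selection discontinuous in single-atom moves).
2. **Networks.** Four architectures map grids (or grid sequences) to pK: a plain 3-D CNN, a
   dense-block CNN (each in-block layer sees the concatenation of the block
   input and all previous layer outputs, so channels grow as
   `in + layers × growth`; 1×1×1 transitions compress by `floor(c·θ)` and
   halve the spatial extent), and two spatio-temporal families — an LRCN
   (shared CNN encoder per frame, LSTM over frame embeddings) and a ConvLSTM
   (gate transforms are same-padded 3-D convolutions, no peepholes, gate
   order i, f, g, o).
3. **Training regimes.** `crystal_only` uses one grid per complex;
   `md_augmented` treats every trajectory frame as an independent sample
   labeled with the parent complex's affinity; `spatio_temporal` feeds whole
   ordered frame sequences, drawing one replicate per complex uniformly at
   random each epoch.  Loss is MSE on pK, optimized with Adam.  One random
   rotation is drawn per sample per epoch during training; evaluation uses
   no rotation.  Per-complex predictions are the arithmetic mean over
   entities (frames or whole simulations), and the ensemble consensus is the
   mean over independently seeded model replicates.
4. **Evaluation.** Pearson R and RMSE (pK), Spearman ρ overall and as an
   unweighted mean over manifest clusters (groups of ~5 complexes sharing a
   target, CASF-style); the bias gap ΔR = mean R(full complex) − mean
   R(partner-ablated) over model replicates; and ligand stability: the
   maximum ligand RMSD along a replicate after superposing each frame's
   pocket heavy atoms onto frame 0, with a replicate called stable below
   2 Å.

## Numerical and design choices

**Voxel binning** is half-open (`[k, k+1)` Å from the box minimum corner);
an atom exactly on the maximum face is dropped.  Colliding atoms' feature
vectors are summed.  These two conventions make three invariants exact and
machine-testable: channel mass conservation, additivity of partner-ablated
grids, and voxel-for-voxel equivariance under the 24 right-angle rotations
of the cube (signed permutation matrices; `rotate_grid` implements the
corresponding axis permutation/flip).

**The 19 channels** are: 9 one-hot atom-type flags (B, C, N, O, P, S, Se,
halogen = {F, Cl, Br, I}, metal = everything else except H), hybridization
(1–3), heavy and hetero valence counts, five property flags (hydrophobic,
aromatic, acceptor, donor, ring), partial charge, and a moltype channel (+1
protein, −1 ligand).  The order is frozen and written into every grid
dataset's metadata.  Hydrogens are excluded throughout.

**"One random rotation"** defaults to a uniform draw among the 24 cube
rotations (lossless on the grid); a continuous SO(3) draw is available as an
option.  All randomness flows from recorded integer seeds.

**Networks are implemented in NumPy** on a small reverse-mode autodiff
engine (`gridbind.nn`): 3-D convolution via im2col + GEMM, with gradients
validated against central finite differences in the test suite.  The CNN
trunk can average-pool the input grid (default factor 2, i.e. 1 Å → 2 Å)
before the first convolution; this preserves channel sums up to the pooling
factor while letting a 3³ kernel cover the ~5 Å scale of atomic contacts at
a fraction of the cost.  The trainer standardizes the regression target: an
affine output transform (train-label mean/sd) is stored on the model and
folded into `forward`, so checkpoints remain self-contained.  Readout of the
recurrent families is the last time step by default (mean over time is a
config option).  Exact widths/depths are all `ModelConfig` fields; the
defaults are desk-scale.

**Early stopping** tracks per-complex validation RMSE (not per-frame), with
the best checkpoint restored; split integrity (no complex id shared between
train/val/test) is asserted before and during every run and violations are
hard errors.

**Undefined correlations** (fewer than 2 points, zero variance) are
reported as missing (NaN/None), never coerced to 0.  Clusters with fewer
than 2 predicted members are excluded from the per-cluster Spearman mean and
flagged.

**RMSD alignment.** The ligand-stability statistic superposes each frame on
the *pocket* heavy atoms of frame 0 (rigid least squares via Kabsch) before
measuring the ligand RMSD, isolating ligand motion relative to the binding
site from global tumbling.  Values below 1e−12 Å are snapped to zero.  The
low/high affinity boundary defaults to the dataset median pK and is
configurable.

## The synthetic data generator

The generator emulates the *shape* of an MD affinity corpus, not its
physics.  Defaults: 120 complexes × 10 replicate trajectories × 50 frames
(so 500 frames per complex, matching the cadence of the real corpora this
pipeline targets), with an 80/20 train/validation split of the non-test
complexes and 20% held out as test, all complex-exclusive.

Each complex is a pseudo-pocket shell of 60 atoms at a per-complex radius
drawn from U(6.5, 10) Å plus a 4–10-atom ligand sampled inside 3.5 Å.  The
label is planted as

    pK = 2.5 + 0.12 × n_contacts + N(0, 0.35),  clipped to [0, 14],

where `n_contacts` counts ligand–pocket atom pairs within 5.5 Å.  Because
the shell radius varies, neither partner alone determines the contact
count: a model shown only the ligand cannot recover the label, which plants
a recoverable analogue of the partner-ablation (bias-gap) protocol.
Contact-based (rather than surface- or energy-based) signal was chosen so a
brute-force all-pairs oracle is exact and cheap.

Replicate trajectories translate the ligand as a rigid body along a random
walk with per-frame step σ(pK) = 0.08 + 0.06 × max(0, 6.5 − pK) Å, so
low-affinity ligands drift further; pocket atoms get independent N(0, 0.25 Å)
jitter.  Rigid-body drift gives the max-RMSD statistic a closed-form scale
for Monte-Carlo testing.  Under these defaults high-affinity complexes are
markedly more often stable at the 2 Å threshold than low-affinity ones,
reproducing the qualitative stability–affinity link the spatio-temporal
models are meant to exploit.

What the generator does *not* emulate: internal ligand flexibility,
induced-fit pocket motion, solvent, force-field energetics, and the
long-tailed experimental error of real affinity data.  Passing tests on
synthetic data therefore demonstrate that the pipeline is implemented
correctly and can recover a planted structural signal — not that it attains
any particular accuracy on experimental corpora.

## Desk-scale study sizes

The end-to-end checks (test suite and `scripts/acceptance.py`) train on the
default 120-complex dataset using replicate 0 subsampled at a stride of 10
frames (crystal + 5 frames per complex), a 2-layer CNN (32/64 channels,
input pooling 2), 2 model replicates per condition and at most 12 epochs —
sizes chosen so the whole pipeline runs in minutes on one CPU core while
leaving the planted signal comfortably recoverable (held-out consensus
R ≈ 0.85–0.9; ligand-only R ≈ 0–0.2, hence ΔR_lig ≈ 0.65–0.9 depending on seed).  The spatio-temporal
families are exercised end-to-end at toy grid sizes (their per-voxel LSTM
semantics, gradient flow and training smoke tests), not at the full
25³ × 50-frame scale, which is not tractable in CPU minutes.

## Known limitations

* The NumPy engine is single-threaded GEMM-bound; it is meant for
  correctness and desk-scale experiments, not production training.
* The fallback structure annotator (distance-based bonds, element-rule
  flags, zero partial charges) is deliberately simple and deterministic;
  real use should supply sidecar annotations from proper perception/charge
  tooling.
* Multi-model PDB trajectories are read through the same single-structure
  path per model; very large trajectories should use the HDF5 container.
* `leave_family_out_split` relies on the manifest's `protein_family` column;
  the package does not compute families or clusters itself.
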