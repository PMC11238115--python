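# Methods

This note documents the model, the numerical choices, and the design
decisions behind `gramconf`, in the order a reader meets them: the geometric
core, the synthetic data, the encoder and its objectives, the two-stage
pipeline, and the evaluation metrics.

## The Gram-matrix representation

A conformer with atoms at `x_1 … x_N` (Å), centered so the centroid of
**all** atoms (hydrogens included) is the origin, is encoded by the Gram
matrix `G_ij = x_i · x_j` (Å²). Properties used throughout:

- **E(3) invariance.** Centering removes translations; `G` is unchanged by
  any orthogonal transform of the coordinates, including reflections. The
  price of reflection invariance is that `G` cannot distinguish enantiomers;
  every comparison of a reconstruction against ground truth therefore
  aligns with improper rotations permitted (a flag restricts alignment to
  proper rotations for comparisons against bioactive references, where
  chirality matters).
- **Rank structure.** For exact coordinates `G = XXᵀ` has rank ≤ 3: exactly
  3 significant eigenvalues for a generic 3D conformer, 2 for planar, 1 for
  collinear. "Significant" means `> 1e-9 · λ_max`; this one relative
  tolerance defines the rank tests and the eigenvalue floor in
  reconstruction.
- **Interconversion.** `D_ij = √(G_ii + G_jj − 2 G_ij)`;
  `G_ij = ½(D_0i² + D_0j² − D_ij²)` where `D_0i = √G_ii` is the distance to
  the centroid origin. The origin distances are exactly the information `G`
  carries beyond `D`. Bond-angle cosines are ratios of Gram entries and are
  independent of the centering offset.

**Reconstruction (classical MDS).** `G` is symmetrized, eigendecomposed
with a symmetric solver, eigenvalues sorted descending, and coordinates
formed from the three largest as `x_ik = √λ_k Q_ik`. Negative eigenvalues
among the top three (which occur for noisy or predicted matrices) are
clamped to zero, as are eigenvalues below `1e-9 · λ_max` — without that
floor, round-off eigenvalues of order 1e-15 would inject √(1e-15) ≈ 3e-8 Å
of spurious out-of-plane coordinates into planar molecules. Degenerate
eigenvalues keep the solver's ordering; reconstruction is defined only up
to E(3), so all comparisons go through Kabsch alignment.

**Numerical tolerances** (constants in `gramconf.geometry`): symmetry check
1e-9 relative; negative-radicand clamp `1e-6 · max|G|` (beyond which the
input is rejected as not a Gram matrix of real points); rank floor
1e-9 relative; centering check 1e-12 absolute.

**Noise injection** for robustness studies adds i.i.d. zero-mean Gaussian
noise to `G`, symmetrized (`noise_ij = noise_ji`), deterministic under a
seed. σ is a standard deviation in Å².

## Synthetic data

No external dataset is required; three generators produce all inputs.

- **Point clouds**: uniform points in a cube scaled to the atom count,
  rejection-sampled to a minimum pairwise separation (default 0.8 Å, the
  scale below which two atoms would be unphysically close). Used for the
  exact-conversion and reconstruction suites, where chemistry is
  irrelevant.
- **Toy molecules**: random valence-respecting trees over C/N/O/F (carbon-
  rich palette), all single bonds, hydrogens filling every remaining
  valence; ≤ 9 heavy atoms and ≤ 29 total atoms, mirroring the small-
  molecule regime of quantum-chemistry benchmark sets. Coordinates come
  from idealized internal geometry — covalent-radius bond lengths,
  tetrahedral branch angles, randomized torsions — rejection-sampled
  against steric clashes. This deliberately avoids force fields and
  distance-geometry embedding: the math and the learning loop need valid,
  reproducible geometry, not physical realism. What passing tests on these
  fixtures do **not** show: behavior on flexible drug-like molecules,
  rings, stereochemistry-rich geometry, or conformer ensembles.
- **Worked examples**: hand-built conformers with analytic expectations
  (right angle, collinear chain, tetrahedral center with cos = −1/3 arm
  pairs, an enantiomer pair sharing one Gram matrix, a planar hexagon of
  rank 2).

A separate topology-only coverage set (benzene, formaldehyde, hydrogen
cyanide, both enantiomers of a chiral center, a cation, a radical,
butadiene) exercises the categorical atom/bond features the single-bonded
trees cannot produce. The sp3d/sp3d2 hybridization slots require hypervalent
elements outside the C/N/O/F palette and stay empty in the fixture suite.

## Featurization and topology

Atoms are encoded in 17 dimensions (atomic number; 5-way hybridization
one-hot sp/sp2/sp3/sp3d/sp3d2; formal charge; radical electrons; van der
Waals radius; aromaticity; implicit-H count; explicit-H count; explicit and
implicit valence; degree; 2-way tetrahedral-chirality one-hot), bonds in 7
(conjugated, aromatic, in-ring, 4-way type one-hot). Out-of-vocabulary
categories become all-zero blocks with a logged warning, never an
exception — hydrogen's "S" hybridization is the routine case and is not
even warned about. Explicit hydrogens are kept for geometry-bearing inputs;
SMILES parsing adds them on request.

Shortest-path tables use breadth-first search with neighbors expanded in
ascending index order, making the recorded path (used by the edge-encoding
bias) the lexicographically smallest shortest path and bit-reproducible.
Disconnected pairs carry a sentinel that maps to a dedicated bias bucket.

Splits: random split assigns `floor(r·N)` to validation and test with the
remainder to training; scaffold split groups molecules by Bemis–Murcko
scaffold, orders groups by (size descending, scaffold string), and fills
train, then validation, then test to capacity, so no scaffold straddles two
splits. Deduplication between a pretraining corpus and downstream data uses
stereochemistry-aware canonical SMILES — the stricter identity notion.

## Encoder

A Graphormer-style transformer over the 2D graph. Initial states are a
linear projection of the 17-dim atom features plus a learned
degree-centrality embedding (degrees capped, default 8). A super node with
its own learned initial vector is appended and connected to everything
through a reserved hop bucket. Each of L layers applies pre-norm multi-head
attention whose logits receive two additive biases — a per-head learned
scalar indexed by capped shortest-hop distance (spatial encoding), and an
edge encoding shared across heads: the mean over the shortest path's edges
of (bond features · learned per-position weight), path length capped at the
hop cap — followed by a residual connection, and a pre-norm GELU MLP with
residual. A final layer norm and linear map produce the atom states `h_u`
and super-node state. With noise off the full forward pass is
deterministic and permutation-equivariant.

**Noise injection.** Gaussian noise `N(μ, σ²)` is added elementwise to the
initial atom states (never the super node). σ is interpreted as a standard
deviation. Its role is not regularization here but symmetry breaking: atoms
with identical features and automorphic environments otherwise receive
identical embeddings forever, making any target that distinguishes them
(as 3D geometry does) unfittable in principle. The noise is drawn from a
seed, and a training run reuses each molecule's seed every epoch and at
evaluation, so the perturbation acts as a fixed per-atom fingerprint — the
"same noise at test time" convention. Defaults μ=0, σ=0.02; the overfit
demonstration uses σ=1.0 (see below).

**Heads.** The Gram head is the inner product `Ĝ_uv = h_u · h_v` over real
atoms — symmetric and PSD for any parameters, rank ≤ H. Atom-to-origin
distances come from a fully connected layer on the concatenated super-node
and atom embeddings with a softplus output (non-negative by construction).
Bond lengths use an MLP on concatenated endpoint embeddings (softplus, Å);
bond angles an MLP on the concatenated triple (sigmoid scaled to (0, π),
rad). Length and angle inputs are canonicalized (lexicographically smaller
endpoint first) so (u,v,w) and (w,v,u) give one value. The alternative
head-free pathway derives lengths and angle cosines algebraically from Ĝ,
with degenerate radicands clamped and flagged.

The spatial-bias and edge-weight tables are initialized with small random
values (σ=0.02) rather than zeros so attention distinguishes hop distances
from the first step. Biases are per-head for the spatial term and shared
across heads for the edge term.

## Objectives

From one centered conformer, the targets are `G`, `D` with origin
distances, bond lengths over all bonds, and bond angles (radians) over all
bonded triples (i, j, k), i < k. Variants: (a) mean over all N² ordered
pairs (diagonal included, as the sums are written) of squared distance
error; (b) adds mean squared origin-distance error; (c) mean squared Gram
error; (d) adds mean squared bond-length and bond-angle errors to (c),
each term unit-weighted by default with configurable weights. Per-molecule
means, then an unweighted mean over the batch. The angle penalty is squared
error by default; a flag restores the literal signed linear difference
(truth − prediction), which is documented as an option rather than a
default because a signed term can be driven negative and is inconsistent
with its sibling penalties.

The distance prediction for variants a/b is derived from the Gram head:
`D̂_ij = √(Ĝ_ii + Ĝ_jj − 2Ĝ_ij) = ‖h_i − h_j‖`, i.e. embedding-space
distance (an ε=1e-12 inside the square root keeps the zero diagonal
differentiable). No separate distance head exists; the interconversion
formula ties the two representations together exactly.

When Gram supervision is restricted to heavy atoms (a configuration
switch), hydrogens still participate in centering, bonds and angles; only
the matrix targets shrink. The default supervises all atoms.

## Autodiff and optimization

The encoder and training loop run on a purpose-built reverse-mode autodiff
tape over float64 NumPy arrays (`gramconf.nn`): broadcasted arithmetic,
batched matmul, softmax, layer norm composed from primitives, GELU /
softplus / sigmoid, embedding-row and bias-bucket gathers, concatenation,
and an Adam optimizer. Gradients of every primitive are verified against
central finite differences in the test suite. At the molecule sizes this
package targets (tens of atoms) a forward+backward pass costs a few
milliseconds, which keeps every training demonstration within CPU budgets.

## Overfit-recovery demonstration

`pipeline.overfit_recovery_run` is the end-to-end learnability check: an
L=3, H=64, 4-head encoder memorizes the heavy-atom Gram matrices of 10 toy
molecules under variant d. Molecules are drawn from the generator, filtered
to topology-distinct (canonical SMILES) and heavy-atom-asymmetric skeletons
(no two heavy atoms related by a graph automorphism, checked via canonical
ranks) — symmetric atoms have identical embeddings up to the noise
fingerprint, and the run should demonstrate the objective, not fight
automorphisms. Supervision is heavy-atom-only: reconstruction quality is
measured by heavy-atom RMSD in any case, and hydrogens within a methyl/
amine group are mutually automorphic by construction. Training uses Adam
with lr 5e-3 and β₂ = 0.95 — memorization over a 2000-step horizon profits
from a fast-adapting second moment; β₂ = 0.999 roughly halves at twice the
steps — and per-molecule fixed noise σ = 1.0. The run stops early once the
training Gram MAE drops below 0.04 Å² and reports final Gram MAE and mean
reconstruction RMSD.

## Two-stage pipeline

Stage 1 trains the encoder on conformer-bearing molecules with early
stopping on validation loss (patience 20 epochs by default), restoring the
best parameters. Stage 2 freezes stage 1 (verified by a SHA-256 checksum
over all parameter tensors), computes frozen per-atom embeddings for
downstream molecules from topology alone — no conformers anywhere in stage
2 — trains a fresh encoder of the same architecture family, concatenates
frozen and fresh embeddings per atom, applies a readout (mean over real
atoms by default; sum and super-node variants selectable — sum is the
natural choice when the label scales with molecule size), and a fully
connected head. Regression uses squared error; classification elementwise
sigmoid cross-entropy with NaN labels masked (multi-task). Embedding
extraction runs noise-free by default so repeated runs are byte-identical.

`end_to_end` chains split → pretrain → embed → property-train → evaluate
and writes a manifest containing the config, split indices, stage
summaries, parameter checksums before and after stage 2, and a SHA-256
manifest hash; with σ=0 two runs of the same config produce identical
hashes. Output paths are excluded from the hash.

## Metrics

R², RMSE and MAE are computed over flattened elements; matrix metrics pool
all N² entries across molecules (a per-molecule-then-average option
exists). Angle errors are reported in radians with a degrees convenience
column. RMSD uses Kabsch superposition after centering, over heavy atoms by
default, with the reflection convention described above; the standard form
(mean of squared deviations, then square root) is implemented. COV and MAT
over conformer ensembles: COV is the fraction of reference conformers
within RMSD δ (default 2.00 Å) of some generated conformer, MAT the mean
over references of the minimum RMSD; ensembles are truncated to a maximum
size (default 1 — the minimum-energy-conformer evaluation), making COV the
indicator mean of RMSD < δ and MAT the plain mean RMSD.

## Problem sizes

Test and acceptance runs use 1000 point clouds for reconstruction
precision, 500 for invariance/conversion/rank suites, 200 for noise
tolerance, 10 molecules × ≤ 2000 steps for the overfit demonstration, and a
16-molecule, single-layer-encoder configuration for the pipeline
determinism check — sizes chosen so the full suite runs on one CPU in
minutes while exercising every code path at meaningful scale.

## Known limitations

- The toy geometry is idealized (single bonds, tetrahedral angles); no
  rings with geometry, no stereo-defined 3D fixtures beyond the worked
  mirror pair.
- The encoder is desk-scale; no minibatching across large corpora, no GPU
  path, no distributed training.
- Variant a/b distance supervision shares parameters with the Gram head by
  construction; the package does not implement an independent distance
  head.
- The angle head predicts a single scalar per triple; torsions are out of
  scope, so reconstruction fidelity beyond bonded geometry rests entirely
  on the Gram matrix.
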