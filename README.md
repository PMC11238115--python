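# gramconf

**The Gram matrix as a compact, E(3)-invariant encoding of molecular 3D
conformation — and as a supervised pretraining objective for 2D molecular
graph transformers.**

## The problem

Molecular property prediction models usually consume 2D topology (graphs,
SMILES, fingerprints), discarding the 3D conformation that governs shape
complementarity in protein–ligand binding. Coordinate-based 3D encodings are
awkward learning targets: raw Cartesian coordinates change under every
rotation, translation and reflection of the molecule, while distance-matrix
encodings discard the information needed to rebuild coordinates directly.

For an origin-centered coordinate matrix `X ∈ R^{N×3}`, the **Gram matrix**

```
G_ij = x_i · x_j
```

is symmetric, positive semidefinite, of rank ≤ 3, invariant to the whole
E(3) group (rotations, translations after centering, reflections) — and
*losslessly invertible*: classical multidimensional scaling (MDS) recovers
the conformer, up to a rigid motion and mirror image, from the
eigendecomposition `G = QΛQ⁻¹` by keeping the three largest eigenvalues,

```
x_ik = λ_k^{1/2} Q_ik ,   k = 1, 2, 3.
```

Distances and internal coordinates fall out algebraically:
`D_ij = √(G_ii + G_jj − 2G_ij)`, `G_ij = ½(D_0i² + D_0j² − D_ij²)` (with
`D_0i` the atom-to-origin distance), and any bond-angle cosine is a ratio of
Gram entries.

`gramconf` implements this representation exactly, plus the learning
pipeline built on it: a Graphormer-style graph transformer over 2D molecular
graphs (degree-centrality state encoding, shortest-hop spatial attention
bias, path-edge-feature attention bias, a global super node) whose final
atom states `h_u` predict the Gram matrix as plain inner products
`Ĝ_uv = h_u · h_v` — symmetric and PSD by construction. Four supervision
variants combine the distance matrix (a), distances plus atom-to-origin
distances (b), the Gram matrix (c), or the Gram matrix plus MLP-head bond
lengths and angles (d). A second stage freezes the pretrained encoder and
concatenates its per-atom embeddings with a fresh encoder's for downstream
property prediction from topology alone.

## Worked example

```python
import numpy as np
from gramconf import (Conformer, gram_from_coords, gram_to_distance,
                      mds_reconstruct, aligned_rmsd, center_coordinates)

# a centered 4-atom conformer (A)
conf = Conformer(np.array([[0.0, 0, 0], [1.54, 0, 0],
                           [2.05, 1.45, 0], [2.05, 2.17, 1.3]]),
                 ["C", "C", "C", "C"])
gram = gram_from_coords(conf)                  # 4x4, A^2
dist = gram_to_distance(gram)
print(round(dist.values[0, 1], 4))             # 1.54   <- the C-C bond length
rec = mds_reconstruct(gram, conf.elements)     # coordinates from G alone
print(aligned_rmsd(center_coordinates(conf), rec,
                   allow_reflection=True, heavy_only=False))  # ~1e-16 A
```

The reconstruction error of the exact Gram matrix is at numerical round-off
(about 1e-16–1e-8 A depending on conditioning); adding Gaussian noise to G
degrades it smoothly, which `add_gram_noise` lets you quantify.

Training demonstration (the learning objective end to end):

```python
from gramconf.pipeline import overfit_recovery_run
result = overfit_recovery_run(seed=1)
print(result)   # {'gram_mae': ..., 'reconstruction_rmsd': ..., 'steps': ...}
```

This memorizes the heavy-atom Gram matrices of 10 synthetic molecules with
an L=3, H=64 encoder and reports the Gram mean absolute error (A^2) and the
mean heavy-atom RMSD of conformers rebuilt from the predicted matrices.

## Command line

```bash
gramconf fixtures --kind toy --n 50 --seed 7 --out toys.sdf
gramconf convert --in toys.sdf --out grams.h5
gramconf reconstruct --in grams.h5 --out rec.xyz --noise-sigma 0.1 --seed 3
gramconf split --in toys.sdf --mode scaffold --ratios 0.8,0.1,0.1 --out split.json
gramconf run-all --config config.yaml
```

## Layout

- `gramconf.geometry` — Conformer/Gram/Distance types, exact conversions,
  MDS reconstruction, noise injection.
- `gramconf.io` — SDF/XYZ/SMILES parsing, atom/bond featurization (17/7
  dims), shortest-path topology tables, random and Bemis–Murcko scaffold
  splits, deduplication.
- `gramconf.nn` — minimal reverse-mode autodiff and Adam.
- `gramconf.encoder` — the graph transformer and its prediction heads.
- `gramconf.objectives` — supervision targets and the four variant losses.
- `gramconf.metrics` — R²/RMSE/MAE, Kabsch-aligned RMSD, COV/MAT.
- `gramconf.pipeline` — two-stage pretrain → frozen-embedding property
  prediction workflow.
- `gramconf.fixtures` — synthetic point clouds, idealized toy molecules,
  worked examples.

See `docs/methods.md` for the modeling details and design decisions.
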