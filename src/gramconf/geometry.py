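"""Exact conversions between coordinates, Gram matrices and distance matrices.

The Gram matrix of origin-centered atomic coordinates, ``G_ij = x_i . x_j``,
is a compact E(3)-invariant encoding of a conformer: it is unchanged by any
rotation, translation (after centering) or reflection of the molecule, it is
symmetric positive semidefinite with rank at most 3, and the conformer can be
recovered from it (up to a rigid motion and mirror image) by classical
multidimensional scaling — an eigendecomposition keeping the three largest
eigenvalues.

This module provides those conversions exactly and deterministically, plus the
derived quantities used as supervision targets elsewhere in the package: the
pairwise distance matrix ``D_ij = ||x_i - x_j||``, atom-to-origin distances,
bond lengths and bond-angle cosines, and Gaussian noise injection for
robustness studies of the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Numerical tolerances, collected in one place.
SYMMETRY_RTOL = 1e-9          # relative symmetry tolerance for Gram/distance input
RADICAND_CLAMP_REL = 1e-6     # D_ij^2 may be negative by at most this * max|G|
RANK_EIGENVALUE_REL = 1e-9    # eigenvalue considered nonzero above this * lambda_max
CENTER_ATOL = 1e-12           # centroid considered zero below this


class GeometryError(ValueError):
    """Invalid or inconsistent geometric input."""


class DegenerateGeometryError(GeometryError):
    """An angle or distance is undefined because two atoms coincide."""


@dataclass
class Conformer:
    """A single 3D arrangement of a molecule's atoms.

    Parameters
    ----------
    coords : (N, 3) float array
        Cartesian coordinates in Angstrom.
    elements : list of str
        Element symbols, length N.
    heavy_mask : (N,) bool array
        True for non-hydrogen atoms. Derived from ``elements`` when omitted.
    """

    coords: np.ndarray
    elements: list[str]
    heavy_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise GeometryError("conformer must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("coordinates must be finite")
        if len(self.elements) != self.coords.shape[0]:
            raise GeometryError("elements length must match coordinate rows")
        if self.heavy_mask is None:
            self.heavy_mask = np.array([e != "H" for e in self.elements], dtype=bool)
        else:
            self.heavy_mask = np.asarray(self.heavy_mask, dtype=bool)
            if self.heavy_mask.shape != (self.coords.shape[0],):
                raise GeometryError("heavy_mask length must match atom count")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def heavy_subset(self) -> "Conformer":
        """Conformer restricted to heavy (non-hydrogen) atoms."""
        idx = np.flatnonzero(self.heavy_mask)
        if idx.size == 0:
            raise GeometryError("conformer has no heavy atoms")
        return Conformer(
            self.coords[idx],
            [self.elements[i] for i in idx],
            np.ones(idx.size, dtype=bool),
        )


@dataclass
class GramMatrix:
    """Symmetric N x N inner-product matrix of centered coordinates (A^2)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise GeometryError(f"Gram matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise GeometryError("Gram matrix must be finite")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > SYMMETRY_RTOL * scale:
            raise GeometryError("Gram matrix is not symmetric within tolerance")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


@dataclass
class DistanceMatrix:
    """N x N pairwise distances (A), optionally with atom-to-origin distances.

    ``origin_distances[i]`` is the distance from atom i to the centroid origin;
    it carries the extra information a Gram matrix holds beyond interatomic
    distances and is required to convert back to a Gram matrix.
    """

    values: np.ndarray
    origin_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise GeometryError(f"distance matrix must be square, got {v.shape}")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > SYMMETRY_RTOL * scale:
            raise GeometryError("distance matrix is not symmetric within tolerance")
        if np.abs(np.diag(v)).max() > SYMMETRY_RTOL * scale:
            raise GeometryError("distance matrix diagonal must be zero")
        if v.min() < -SYMMETRY_RTOL * scale:
            raise GeometryError("distances must be non-negative")
        if self.origin_distances is not None:
            self.origin_distances = np.asarray(self.origin_distances, dtype=np.float64)
            if self.origin_distances.shape != (v.shape[0],):
                raise GeometryError("origin_distances length must match atom count")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


def is_centered(coords: np.ndarray, atol: float = CENTER_ATOL) -> bool:
    """True when the centroid of ``coords`` is the origin within ``atol``."""
    return bool(np.abs(np.asarray(coords, dtype=np.float64).mean(axis=0)).max() <= atol)


def center_coordinates(conformer: Conformer) -> Conformer:
    """Translate a conformer so the centroid of all atoms sits at the origin.

    Hydrogens participate in the centroid: a single consistent origin is what
    makes Gram entries and atom-to-origin distances of one molecule comparable.
    """
    centered = conformer.coords - conformer.coords.mean(axis=0, keepdims=True)
    return Conformer(centered, list(conformer.elements), conformer.heavy_mask.copy())


def gram_from_coords(conformer: Conformer) -> GramMatrix:
    """Gram matrix ``G_ij = x_i . x_j`` of the centered conformer.

    Input that is not already origin-centered is centered internally, so the
    result is invariant to any rigid motion or reflection of the input.
    """
    conf = conformer if is_centered(conformer.coords) else center_coordinates(conformer)
    g = conf.coords @ conf.coords.T
    return GramMatrix((g + g.T) / 2.0)


def distance_from_coords(conformer: Conformer) -> DistanceMatrix:
    """Pairwise distance matrix; origin distances refer to the centroid origin."""
    conf = conformer if is_centered(conformer.coords) else center_coordinates(conformer)
    x = conf.coords
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, origin_distances=np.linalg.norm(x, axis=1))


def gram_to_distance(g: GramMatrix) -> DistanceMatrix:
    """Convert a Gram matrix to distances via D_ij = sqrt(G_ii + G_jj - 2 G_ij).

    Raises
    ------
    GeometryError
        If a squared distance is more negative than the clamp tolerance — the
        input is then not the Gram matrix of any set of real points.
    """
    v = g.values
    diag = np.diag(v)
    sq = diag[:, None] + diag[None, :] - 2.0 * v
    clamp = RADICAND_CLAMP_REL * max(np.abs(v).max(), 1.0)
    if sq.min() < -clamp:
        raise GeometryError(
            f"negative squared distance {sq.min():.3g} below tolerance: "
            "not a valid Gram matrix of real points"
        )
    d = np.sqrt(np.clip(sq, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, origin_distances=np.sqrt(np.clip(diag, 0.0, None)))


def distance_to_gram(d: DistanceMatrix) -> GramMatrix:
    """Recover the Gram matrix: G_ij = (D_0i^2 + D_0j^2 - D_ij^2) / 2.

    Atom-to-origin distances must be present — interatomic distances alone do
    not determine the Gram matrix.
    """
    if d.origin_distances is None:
        raise GeometryError("distance_to_gram requires origin_distances")
    o2 = d.origin_distances**2
    g = 0.5 * (o2[:, None] + o2[None, :] - d.values**2)
    return GramMatrix((g + g.T) / 2.0)


def angle_cosine_from_gram(g: GramMatrix, i: int, j: int, k: int) -> float:
    """Cosine of the angle at vertex j between arms j->i and j->k.

    Computed purely from Gram entries:
    cos = (G_ik + G_jj - G_ij - G_jk) / sqrt((G_ii + G_jj - 2G_ij)(G_jj + G_kk - 2G_jk))
    and therefore invariant to where the molecule's centroid sits.
    """
    if len({i, j, k}) != 3:
        raise GeometryError("angle indices must be distinct")
    v = g.values
    num = v[i, k] + v[j, j] - v[i, j] - v[j, k]
    arm_ij = v[i, i] + v[j, j] - 2.0 * v[i, j]
    arm_jk = v[j, j] + v[k, k] - 2.0 * v[j, k]
    rad = arm_ij * arm_jk
    if arm_ij <= 0.0 or arm_jk <= 0.0 or rad <= 0.0:
        raise DegenerateGeometryError(
            f"zero-length arm at angle ({i},{j},{k}); cosine undefined"
        )
    return float(np.clip(num / np.sqrt(rad), -1.0, 1.0))


def gram_eigenvalues(g: GramMatrix) -> np.ndarray:
    """Eigenvalues of the symmetrized Gram matrix, sorted descending."""
    w = np.linalg.eigvalsh((g.values + g.values.T) / 2.0)
    return w[::-1]


def effective_rank(g: GramMatrix, rel_tol: float = RANK_EIGENVALUE_REL) -> int:
    """Number of eigenvalues exceeding ``rel_tol`` times the largest one."""
    w = gram_eigenvalues(g)
    lam_max = max(w[0], 0.0)
    if lam_max == 0.0:
        return 0
    return int(np.sum(w > rel_tol * lam_max))


def mds_reconstruct(g: GramMatrix, elements: list[str] | None = None) -> Conformer:
    """Reconstruct coordinates from a Gram matrix by classical MDS.

    The symmetrized matrix is eigendecomposed, eigenvalues sorted descending,
    and coordinates formed as ``x_ik = sqrt(lambda_k) Q_ik`` from the three
    largest eigenvalues; negative eigenvalues among the selected three (which
    occur for noisy, predicted matrices) are clamped to zero. The output is
    origin-centered and defined only up to rotation and reflection, so callers
    compare reconstructions after alignment.
    """
    v = (g.values + g.values.T) / 2.0
    n = v.shape[0]
    w, q = np.linalg.eigh(v)
    order = np.argsort(w)[::-1][:3]
    lam = np.clip(w[order], 0.0, None)
    # round-off eigenvalues of rank-deficient input collapse to exactly zero
    lam[lam < RANK_EIGENVALUE_REL * max(lam[0], 0.0)] = 0.0
    coords = q[:, order] * np.sqrt(lam)[None, :]
    if coords.shape[1] < 3:  # N < 3: pad missing axes with zeros
        coords = np.hstack([coords, np.zeros((n, 3 - coords.shape[1]))])
    coords = coords - coords.mean(axis=0, keepdims=True)
    if elements is None:
        elements = ["C"] * n
    return Conformer(coords, list(elements))


def add_gram_noise(g: GramMatrix, sigma: float, seed: int) -> GramMatrix:
    """Perturb a Gram matrix with symmetric zero-mean Gaussian noise.

    The noise matrix is drawn i.i.d. and symmetrized (noise_ij = noise_ji), so
    the perturbed matrix remains a valid symmetric input to reconstruction.
    Deterministic under ``seed``.
    """
    if sigma < 0:
        raise GeometryError("noise sigma must be non-negative")
    if sigma == 0:
        return GramMatrix(g.values.copy())
    rng = np.random.default_rng(seed)
    n = g.n_atoms
    noise = rng.normal(0.0, sigma, size=(n, n))
    noise = np.triu(noise) + np.triu(noise, 1).T
    return GramMatrix(g.values + noise)


def bond_length_from_gram(g: GramMatrix, i: int, j: int) -> float:
    """Distance between atoms i and j from Gram entries (a bond length when
    (i, j) is a bond)."""
    v = g.values
    sq = v[i, i] + v[j, j] - 2.0 * v[i, j]
    clamp = RADICAND_CLAMP_REL * max(np.abs(v).max(), 1.0)
    if sq < -clamp:
        raise GeometryError(f"negative squared length for pair ({i},{j})")
    return float(np.sqrt(max(sq, 0.0)))
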