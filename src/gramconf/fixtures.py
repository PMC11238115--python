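"""Synthetic test inputs: random point clouds, idealized toy molecules and
hand-constructed worked examples.

The toy molecules emulate the small-molecule regime of quantum-chemistry
benchmark sets — at most 9 heavy atoms drawn from C/N/O/F plus explicit
hydrogens, at most 29 atoms in total — but with coordinates from idealized
internal geometry (covalent-radius bond lengths, tetrahedral angles,
randomized torsions) rather than any force field or distance-geometry
embedding: deterministic, dependency-light, and sufficient to exercise the
exact conversions and the learning loop. Everything is reproducible from
(kind, seed); no fixture files are checked in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .geometry import Conformer, GramMatrix, gram_from_coords
from .io import MolecularGraph, graph_from_mol, parse_smiles

# idealized single-bond covalent radii (A)
_COVALENT_RADIUS = {"H": 0.32, "C": 0.77, "N": 0.75, "O": 0.73, "F": 0.71}
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}
_TETRAHEDRAL_ANGLE = np.arccos(-1.0 / 3.0)  # 109.47 deg


class FixtureError(RuntimeError):
    """Fixture generation failed within the retry budget."""


@dataclass
class FixtureSpec:
    """What to generate: kind, count, size range, packing constraint, seed."""

    kind: str = "toy_molecule"        # point_cloud | toy_molecule | worked_example
    n_molecules: int = 10
    min_atoms: int = 3
    max_atoms: int = 9
    min_separation: float = 0.8       # A, smallest allowed pairwise distance
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_atoms <= self.max_atoms <= 64):
            raise ValueError("atom-count range must lie within [1, 64]")
        if self.min_separation <= 0:
            raise ValueError("min separation must be positive")


def generate_point_clouds(spec: FixtureSpec) -> list[Conformer]:
    """Random 3D point clouds with a minimum pairwise separation.

    Points are drawn uniformly in a cube sized to the target density and
    redrawn until the separation constraint holds (bounded retries). Elements
    are all carbon so the clouds drop straight into geometry tests.
    """
    rng = np.random.default_rng(spec.seed)
    clouds = []
    for _ in range(spec.n_molecules):
        n = int(rng.integers(spec.min_atoms, spec.max_atoms + 1))
        side = max(2.0 * spec.min_separation * n ** (1.0 / 3.0), spec.min_separation)
        pts = None
        for attempt in range(60):
            # place points one at a time; grow the box on failure
            placed: list[np.ndarray] = []
            for _ in range(n):
                for _ in range(200):
                    p = rng.uniform(-side / 2, side / 2, size=3)
                    if all(np.linalg.norm(p - q) >= spec.min_separation
                           for q in placed):
                        placed.append(p)
                        break
                else:
                    break
            if len(placed) == n:
                pts = np.array(placed)
                break
            side *= 1.1
        if pts is None:
            raise FixtureError(
                f"could not place {n} points with separation "
                f"{spec.min_separation} in a box of side {side:.2f}")
        clouds.append(Conformer(pts, ["C"] * n))
    return clouds


def _min_pairwise(pts: np.ndarray) -> float:
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    return float(d[np.triu_indices(len(pts), k=1)].min())


def generate_toy_molecules(spec: FixtureSpec) -> list[MolecularGraph]:
    """Random single-bonded tree molecules over C/N/O/F with explicit H and
    idealized 3D geometry.

    Heavy-atom skeletons are random valence-respecting trees; hydrogens fill
    every remaining valence. Coordinates are grown atom by atom with
    covalent-radius bond lengths, tetrahedral branching angles and randomized
    torsions, rejection-sampled until no two atoms approach closer than
    ``min_separation``. All outputs sanitize cleanly.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[MolecularGraph] = []
    while len(out) < spec.n_molecules:
        n_heavy = int(rng.integers(spec.min_atoms, min(spec.max_atoms, 9) + 1))
        graph = _random_tree_molecule(n_heavy, rng, spec.min_separation)
        if graph is not None:
            graph.id = f"toy-{spec.seed}-{len(out)}"
            out.append(graph)
    return out


def _random_tree_molecule(n_heavy, rng, min_sep) -> MolecularGraph | None:
    symbols = ["C"]
    parents = [-1]
    free = [_MAX_VALENCE["C"]]
    palette = ["C", "C", "C", "N", "O", "F"]  # carbon-rich, QM9-like
    for _ in range(1, n_heavy):
        anchors = [i for i, f in enumerate(free) if f > 0]
        if not anchors:
            break
        anchor = int(rng.choice(anchors))
        sym = str(rng.choice(palette))
        symbols.append(sym)
        parents.append(anchor)
        free[anchor] -= 1
        free.append(_MAX_VALENCE[sym] - 1)
    # hydrogens fill remaining valences
    n_h_per = list(free)
    bonds = [(parents[i], i) for i in range(1, len(symbols))]
    all_symbols = list(symbols)
    for i, nh in enumerate(n_h_per):
        for _ in range(nh):
            bonds.append((i, len(all_symbols)))
            all_symbols.append("H")
    if len(all_symbols) > 29:
        return None
    for attempt in range(30):
        coords = _embed_tree(all_symbols, bonds, rng)
        if len(all_symbols) == 1 or _min_pairwise(coords) >= min_sep:
            break
    else:
        return None
    rw = Chem.RWMol()
    for s in all_symbols:
        atom = Chem.Atom(s)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for u, v in bonds:
        rw.AddBond(int(u), int(v), Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(all_symbols))
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(c) for c in xyz))
    conf.Set3D(True)
    mol = rw.GetMol()
    mol.AddConformer(conf)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return graph_from_mol(mol)


def _embed_tree(symbols, bonds, rng) -> np.ndarray:
    """Grow coordinates over a bond tree with idealized internal geometry."""
    n = len(symbols)
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    parent = {0: -1}
    for u, v in bonds:
        children[u].append(v)
        parent[v] = u
    coords = np.zeros((n, 3))
    placed = {0}

    def bond_length(a, b):
        return _COVALENT_RADIUS[symbols[a]] + _COVALENT_RADIUS[symbols[b]]

    order = [0]
    head = 0
    while head < len(order):
        cur = order[head]
        head += 1
        kids = children[cur]
        if not kids:
            continue
        par = parent[cur]
        if par < 0:
            axis = _random_unit(rng)
        else:
            axis = coords[cur] - coords[par]
            axis = axis / np.linalg.norm(axis)
        base_torsion = rng.uniform(0, 2 * np.pi)
        for s_idx, kid in enumerate(kids):
            if par < 0 and s_idx == 0:
                direction = axis
            else:
                torsion = base_torsion + 2 * np.pi * s_idx / max(len(kids), 3)
                direction = _rotate_about(axis, _TETRAHEDRAL_ANGLE, torsion)
            coords[kid] = coords[cur] + bond_length(cur, kid) * direction
            placed.add(kid)
            order.append(kid)
    return coords


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about(axis: np.ndarray, polar: float, torsion: float) -> np.ndarray:
    """Unit vector at angle ``polar`` from ``axis`` at azimuth ``torsion``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return (np.cos(polar) * axis
            + np.sin(polar) * (np.cos(torsion) * e1 + np.sin(torsion) * e2))


def heavy_atoms_asymmetric(graph: MolecularGraph) -> bool:
    """True when every heavy atom has a distinct graph-canonical rank —
    i.e. no two heavy atoms are related by a graph automorphism, so a
    topology-only encoder can in principle give them distinct embeddings."""
    if graph.mol is None:
        return False
    ranks = list(Chem.CanonicalRankAtoms(graph.mol, breakTies=False))
    heavy = [r for r, e in zip(ranks, graph.elements) if e != "H"]
    return len(set(heavy)) == len(heavy)


def coverage_set() -> list[MolecularGraph]:
    """Topology-only molecules that exercise the categorical atom/bond
    features the random trees cannot: aromaticity, double/triple bonds,
    conjugation, rings, chirality tags, formal charge and radicals."""
    smiles = [
        ("c1ccccc1", "benzene"),
        ("C=O", "formaldehyde"),
        ("C#N", "hydrogen-cyanide"),
        ("N[C@H](O)F", "chiral-R"),
        ("N[C@@H](O)F", "chiral-S"),
        ("C[NH3+]", "methylammonium"),
        ("[CH3]", "methyl-radical"),
        ("C=CC=C", "butadiene"),
    ]
    return [parse_smiles(s, mol_id=name) for s, name in smiles]


@dataclass
class WorkedExample:
    """A named conformer with its analytically expected quantities."""

    name: str
    conformer: Conformer
    expected: dict


def worked_examples() -> dict[str, WorkedExample]:
    """Hand-constructed geometries with exact expected Gram/angle values."""
    examples: dict[str, WorkedExample] = {}

    examples["right_angle_triple"] = WorkedExample(
        "right_angle_triple",
        Conformer(np.array([[1.0, 0, 0], [0.0, 0, 0], [0.0, 1, 0]]), ["C"] * 3),
        {"angle_cosine": {(0, 1, 2): 0.0}},
    )
    examples["linear_chain_3"] = WorkedExample(
        "linear_chain_3",
        Conformer(np.array([[-1.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]]), ["C"] * 3),
        {"angle_cosine": {(0, 1, 2): -1.0}, "gram_rank": 1},
    )
    tet = np.array([[0.0, 0, 0],
                    [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)
    tet[0] = 0.0
    examples["tetrahedron_5"] = WorkedExample(
        "tetrahedron_5",
        Conformer(tet, ["C"] * 5),
        {"angle_cosine": {(i, 0, j): -1.0 / 3.0
                          for i in range(1, 5) for j in range(i + 1, 5)}},
    )
    chiral = np.array([[0.0, 0, 0], [1.1, 0, 0], [-0.4, 1.0, 0], [-0.4, -0.5, 0.9]])
    mirror = chiral * np.array([1.0, 1.0, -1.0])
    examples["mirror_pair_chiral"] = WorkedExample(
        "mirror_pair_chiral",
        Conformer(chiral, ["C", "N", "O", "F"]),
        {"mirror": Conformer(mirror, ["C", "N", "O", "F"]),
         "gram_equal_under_mirror": True},
    )
    theta = np.arange(6) * np.pi / 3.0
    ring = np.stack([1.39 * np.cos(theta), 1.39 * np.sin(theta), np.zeros(6)], axis=1)
    examples["planar_ring_6"] = WorkedExample(
        "planar_ring_6",
        Conformer(ring, ["C"] * 6),
        {"gram_rank": 2},
    )
    return examples


def gram_of(example: WorkedExample) -> GramMatrix:
    return gram_from_coords(example.conformer)
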