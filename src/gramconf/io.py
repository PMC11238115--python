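"""Molecule parsing, featurization, graph topology and dataset splitting.

Molecules come in as SDF (with or without 3D coordinates), XYZ, or SMILES and
are held as :class:`MolecularGraph` — topology plus fixed-width atom and bond
feature encodings, with an optional :class:`~gramconf.geometry.Conformer`.

The atom encoding is 17-dimensional: atomic number; a 5-way hybridization
one-hot (sp, sp2, sp3, sp3d, sp3d2); formal charge; radical electron count;
van der Waals radius; aromaticity flag; implicit and explicit hydrogen counts;
explicit and implicit valence; degree; and a 2-way chirality one-hot (CW,
CCW). The bond encoding is 7-dimensional: conjugation, aromaticity and ring
flags plus a 4-way bond-type one-hot (single, double, triple, aromatic).
Out-of-vocabulary categories map to an all-zero one-hot block with a logged
warning rather than an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import GetPeriodicTable
from rdkit.Chem.Scaffolds import MurckoScaffold

from .geometry import Conformer

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

ATOM_FEATURE_DIM = 17
BOND_FEATURE_DIM = 7

_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_CHIRAL_TAGS = [
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

#: Sentinel hop count for disconnected atom pairs (finite hops are capped by
#: the encoder; the sentinel maps to its own bias bucket).
DISCONNECTED_HOPS = -1


class MoleculeFormatError(ValueError):
    """Unparsable molecular input."""


@dataclass
class MolecularGraph:
    """An undirected molecular graph with featurized atoms and bonds.

    ``bonds`` stores each bond once with ``u < v``. ``mol`` keeps the backing
    RDKit molecule for canonicalization and scaffold computation.
    """

    atom_features: np.ndarray          # (N, 17) float64
    bond_features: np.ndarray          # (|E|, 7) float64
    bonds: list[tuple[int, int]]
    elements: list[str]
    conformer: Conformer | None = None
    id: str = ""
    mol: Chem.Mol | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.atom_features.shape[0]
        for u, v in self.bonds:
            if not (0 <= u < v < n):
                raise ValueError(f"bond ({u},{v}) has invalid endpoints for N={n}")
        if self.conformer is not None and self.conformer.n_atoms != n:
            raise ValueError("conformer atom count does not match graph")

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements], dtype=bool)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=np.int64)
        for u, v in self.bonds:
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass
class TopologyTables:
    """Shortest-hop matrix, one deterministic shortest path per pair, degrees."""

    shortest_hops: np.ndarray                    # (N, N) int64, -1 = disconnected
    path_edges: dict[tuple[int, int], list[int]]  # (u, v) u<v -> edge indices
    degrees: np.ndarray                          # (N,) int64


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    pt = GetPeriodicTable()
    hyb = np.zeros(5)
    try:
        hyb[_HYBRIDIZATIONS.index(atom.GetHybridization())] = 1.0
    except ValueError:
        # S / UNSPECIFIED (hydrogens, bare atoms) are routine; others are not
        if atom.GetHybridization() not in (Chem.HybridizationType.S,
                                           Chem.HybridizationType.UNSPECIFIED):
            logger.warning(
                "atom %d: hybridization %s outside vocabulary, zero block",
                atom.GetIdx(), atom.GetHybridization(),
            )
    chi = np.zeros(2)
    try:
        chi[_CHIRAL_TAGS.index(atom.GetChiralTag())] = 1.0
    except ValueError:
        pass  # unspecified chirality is the common case
    return np.concatenate([
        [float(atom.GetAtomicNum())],
        hyb,
        [float(atom.GetFormalCharge())],
        [float(atom.GetNumRadicalElectrons())],
        [pt.GetRvdw(atom.GetAtomicNum())],
        [float(atom.GetIsAromatic())],
        [float(atom.GetNumImplicitHs())],
        [float(atom.GetNumExplicitHs())],
        [float(atom.GetExplicitValence())],
        [float(atom.GetImplicitValence())],
        [float(atom.GetDegree())],
        chi,
    ])


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    btype = np.zeros(4)
    try:
        btype[_BOND_TYPES.index(bond.GetBondType())] = 1.0
    except ValueError:
        logger.warning("bond %d: type %s outside vocabulary, zero block",
                       bond.GetIdx(), bond.GetBondType())
    return np.concatenate([
        [float(bond.GetIsConjugated())],
        [float(bond.GetIsAromatic())],
        [float(bond.IsInRing())],
        btype,
    ])


def graph_from_mol(mol: Chem.Mol, mol_id: str = "") -> MolecularGraph:
    """Build a featurized graph from a sanitized RDKit molecule.

    A 3D conformer on the molecule is attached as geometry; 2D depictions
    (all-zero z column is the RDKit convention) are ignored.
    """
    atom_feats = np.array([_atom_features(a) for a in mol.GetAtoms()])
    bonds: list[tuple[int, int]] = []
    bond_feats = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds.append((min(u, v), max(u, v)))
        bond_feats.append(_bond_features(bond))
    bond_arr = np.array(bond_feats) if bond_feats else np.zeros((0, BOND_FEATURE_DIM))
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    conformer = None
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        if conf.Is3D():
            conformer = Conformer(np.array(conf.GetPositions()), elements)
    if not mol_id and mol.HasProp("_Name") and mol.GetProp("_Name"):
        mol_id = mol.GetProp("_Name")
    return MolecularGraph(atom_feats, bond_arr, bonds, elements,
                          conformer=conformer, id=mol_id, mol=mol)


def featurize(graph: MolecularGraph) -> tuple[np.ndarray, np.ndarray]:
    """Return the (N, 17) atom and (|E|, 7) bond feature matrices."""
    return graph.atom_features, graph.bond_features


def read_sdf(path, keep_hs: bool = True) -> list[MolecularGraph]:
    """Read an SDF file into featurized graphs, one per parsable record.

    Records that fail RDKit sanitization are skipped with a logged warning;
    an exception is raised only when no record at all parses.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=not keep_hs, sanitize=True)
    graphs: list[MolecularGraph] = []
    n_failed = 0
    for idx, mol in enumerate(supplier):
        if mol is None:
            n_failed += 1
            logger.warning("skipping unparsable SDF record %d in %s", idx, path)
            continue
        graphs.append(graph_from_mol(mol, mol_id=f"{idx}" if not mol.HasProp("_Name") or not mol.GetProp("_Name") else mol.GetProp("_Name")))
    if not graphs:
        raise MoleculeFormatError(f"no parsable records in {path} ({n_failed} failures)")
    if n_failed:
        logger.warning("%d of %d records skipped in %s", n_failed, n_failed + len(graphs), path)
    return graphs


def write_sdf(path, graphs: list[MolecularGraph]) -> None:
    """Write graphs (with conformers when present) to an SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        for g in graphs:
            mol = Chem.Mol(g.mol) if g.mol is not None else _mol_from_graph(g)
            if g.conformer is not None:
                mol.RemoveAllConformers()
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, xyz in enumerate(g.conformer.coords):
                    conf.SetAtomPosition(i, tuple(float(c) for c in xyz))
                conf.Set3D(True)
                mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", g.id)
            writer.write(mol)
    finally:
        writer.close()


def _mol_from_graph(g: MolecularGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for e in g.elements:
        rw.AddAtom(Chem.Atom(e))
    for (u, v), bf in zip(g.bonds, g.bond_features):
        onehot = bf[3:]
        btype = _BOND_TYPES[int(np.argmax(onehot))] if onehot.sum() > 0 else Chem.BondType.SINGLE
        rw.AddBond(u, v, btype)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def read_xyz(path, bond_inference: bool = False) -> list[MolecularGraph]:
    """Read one or more XYZ blocks; bonds inferred from covalent radii only
    when ``bond_inference`` is set (via RDKit's connectivity perception)."""
    from rdkit.Chem import rdDetermineBonds

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    graphs: list[MolecularGraph] = []
    pos = 0
    block = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise MoleculeFormatError(f"{path}:{pos + 1}: expected atom count") from exc
        if pos + 2 + natoms > len(lines):
            raise MoleculeFormatError(f"{path}:{pos + 1}: truncated XYZ block")
        comment = lines[pos + 1].strip()
        elements, coords = [], []
        for k in range(natoms):
            parts = lines[pos + 2 + k].split()
            if len(parts) < 4:
                raise MoleculeFormatError(f"{path}:{pos + 3 + k}: malformed atom line")
            elements.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise MoleculeFormatError(f"{path}:{pos + 3 + k}: bad coordinate") from exc
        rw = Chem.RWMol()
        for e in elements:
            rw.AddAtom(Chem.Atom(e))
        conf = Chem.Conformer(natoms)
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, tuple(xyz))
        conf.Set3D(True)
        mol = rw.GetMol()
        mol.AddConformer(conf)
        if bond_inference:
            rdDetermineBonds.DetermineConnectivity(mol)
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                         | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION)
        graphs.append(graph_from_mol(mol, mol_id=comment or f"xyz-{block}"))
        pos += 2 + natoms
        block += 1
    if not graphs:
        raise MoleculeFormatError(f"no XYZ blocks in {path}")
    return graphs


def write_xyz(path, graphs: list[MolecularGraph]) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            if g.conformer is None:
                raise ValueError(f"molecule {g.id!r} has no conformer")
            fh.write(f"{g.n_atoms}\n{g.id}\n")
            for e, (x, y, z) in zip(g.elements, g.conformer.coords):
                fh.write(f"{e} {x:.10f} {y:.10f} {z:.10f}\n")


def parse_smiles(smiles: str, add_hs: bool = False, mol_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a topology-only graph (no conformer).

    ``add_hs`` makes hydrogens explicit graph nodes, matching the convention
    of geometry-bearing inputs.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeFormatError(f"unparsable SMILES: {smiles!r}")
    if add_hs:
        mol = Chem.AddHs(mol)
    return graph_from_mol(mol, mol_id=mol_id or smiles)


def topology_tables(graph: MolecularGraph) -> TopologyTables:
    """All-pairs unweighted shortest hops with one deterministic path per pair.

    Breadth-first search expands neighbors in ascending index order, so the
    recorded predecessor — and hence the edge sequence of the returned path —
    is the lexicographically smallest among shortest paths and reproducible
    across runs. Disconnected pairs carry ``DISCONNECTED_HOPS``.
    """
    n = graph.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    edge_index: dict[tuple[int, int], int] = {}
    for e_idx, (u, v) in enumerate(graph.bonds):
        adj[u].append(v)
        adj[v].append(u)
        edge_index[(u, v)] = e_idx
        edge_index[(v, u)] = e_idx
    for nbrs in adj:
        nbrs.sort()

    hops = np.full((n, n), DISCONNECTED_HOPS, dtype=np.int64)
    path_edges: dict[tuple[int, int], list[int]] = {}
    for src in range(n):
        dist = np.full(n, -1, dtype=np.int64)
        pred = np.full(n, -1, dtype=np.int64)
        dist[src] = 0
        queue = [src]
        head = 0
        while head < len(queue):
            cur = queue[head]
            head += 1
            for nb in adj[cur]:
                if dist[nb] < 0:
                    dist[nb] = dist[cur] + 1
                    pred[nb] = cur
                    queue.append(nb)
        for dst in range(n):
            if dist[dst] >= 0:
                hops[src, dst] = dist[dst]
            if src < dst and dist[dst] > 0:
                edges = []
                cur = dst
                while cur != src:
                    edges.append(edge_index[(pred[cur], cur)])
                    cur = int(pred[cur])
                path_edges[(src, dst)] = edges[::-1]
    return TopologyTables(hops, path_edges, graph.degrees())


def canonical_smiles(graph: MolecularGraph) -> str:
    """Stereochemistry-aware canonical SMILES (hydrogens made implicit)."""
    if graph.mol is None:
        raise ValueError("graph has no backing molecule")
    return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(graph.mol)), isomericSmiles=True)


def _check_ratios(ratios) -> tuple[float, float, float]:
    r = tuple(float(x) for x in ratios)
    if len(r) != 3 or any(x <= 0 for x in r) or abs(sum(r) - 1.0) > 1e-8:
        raise ValueError(f"ratios must be 3 positive values summing to 1, got {ratios}")
    return r


def random_split(graphs, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Random train/validation/test index split, deterministic under ``seed``.

    Validation and test take ``floor(r * N)`` items; the remainder goes to
    training.
    """
    r = _check_ratios(ratios)
    n = len(graphs)
    if n < 3:
        raise ValueError(f"need at least 3 molecules to split, got {n}")
    n_val, n_test = int(r[1] * n), int(r[2] * n)
    perm = np.random.default_rng(seed).permutation(n)
    train = sorted(perm[: n - n_val - n_test].tolist())
    val = sorted(perm[n - n_val - n_test: n - n_test].tolist())
    test = sorted(perm[n - n_test:].tolist())
    return train, val, test


def scaffold_split(graphs, ratios=(0.8, 0.1, 0.1)):
    """Bemis–Murcko scaffold split: molecules sharing a scaffold never
    straddle two splits.

    Scaffold groups are sorted by (size descending, scaffold string ascending)
    and assigned greedily to the first of train/validation/test not yet at its
    capacity, train first — the convention used throughout molecular property
    benchmarks.
    """
    r = _check_ratios(ratios)
    groups: dict[str, list[int]] = {}
    for idx, g in enumerate(graphs):
        if g.mol is None:
            raise ValueError(f"molecule {g.id!r} has no backing mol for scaffolds")
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=Chem.RemoveHs(Chem.Mol(g.mol)))
        groups.setdefault(scaffold, []).append(idx)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(graphs)
    caps = [r[0] * n, r[1] * n, r[2] * n]
    splits: list[list[int]] = [[], [], []]
    for _, members in ordered:
        placed = False
        for s in range(3):
            if len(splits[s]) + len(members) <= caps[s] + 1e-9:
                splits[s].extend(members)
                placed = True
                break
        if not placed:
            splits[0].extend(members)  # overflow goes to training
    return tuple(sorted(s) for s in splits)


def deduplicate_against(pretrain_set, downstream_set):
    """Drop pretraining molecules whose canonical SMILES occurs downstream.

    Prevents leakage between a geometry pretraining corpus and a labeled
    benchmark; identity is stereochemistry-aware canonical SMILES.
    """
    downstream = {canonical_smiles(g) for g in downstream_set}
    kept = [g for g in pretrain_set if canonical_smiles(g) not in downstream]
    removed = len(pretrain_set) - len(kept)
    if removed:
        logger.info("deduplication removed %d of %d pretraining molecules",
                    removed, len(pretrain_set))
    return kept
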