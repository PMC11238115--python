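"""Supervision targets and the four geometric pretraining losses.

A conformer yields one consistent family of targets — the Gram matrix G of
its centered coordinates, the distance matrix D with atom-to-origin distances
D_0i, bond lengths over the bond set and bond angles (rad) over all bonded
triples. Four supervision variants combine them:

=======  =====================================================
variant  active terms
=======  =====================================================
a        mean_{ij} (D_ij - D̂_ij)^2
b        variant a  +  mean_i (D_0i - D̂_0i)^2
c        mean_{ij} (G_ij - Ĝ_ij)^2
d        variant c  +  mean_bonds (l - l̂)^2 + mean_angles (θ - θ̂)^2
=======  =====================================================

All sums run over every ordered pair including the diagonal, normalized
per molecule (1/N^2, 1/N, 1/|bonds|, 1/|angles|), then averaged unweighted
over the batch. The distance prediction is derived from the inner-product
Gram head (D̂_ij = ||h_i - h_j||, the embedding-space distance); lengths and
angles come from their dedicated MLP heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .encoder import AtomEmbeddings, ConfigurationError, GramEncoder
from .geometry import (Conformer, DistanceMatrix, GramMatrix,
                       angle_cosine_from_gram, center_coordinates,
                       distance_from_coords, gram_from_coords)
from .io import MolecularGraph, TopologyTables, topology_tables

VARIANT_TERMS: dict[str, tuple[str, ...]] = {
    "a": ("distance",),
    "b": ("distance", "origin_distance"),
    "c": ("gram",),
    "d": ("gram", "bond_length", "bond_angle"),
}

_DIST_EPS = 1e-12  # keeps sqrt differentiable on the zero diagonal


@dataclass
class SupervisionTargets:
    """Geometric ground truth for one molecule, all from one centered
    conformer. ``atom_subset`` records which atoms G/D cover (heavy-only
    supervision restricts it)."""

    gram: GramMatrix
    distance: DistanceMatrix
    bonds: list[tuple[int, int]]
    bond_lengths: np.ndarray           # (|bonds|,) A
    angles: list[tuple[int, int, int]]
    bond_angles: np.ndarray            # (|angles|,) rad
    atom_subset: np.ndarray            # indices into the molecule's atoms


@dataclass
class VariantSpec:
    """Which supervision variant to train, with per-term weights.

    ``angle_squared=False`` switches the angle term to the signed linear
    difference exactly as sometimes written; the squared form is the default
    as the only one consistent with its sibling penalty terms.
    """

    variant: str = "d"
    weights: dict[str, float] = field(default_factory=dict)
    angle_squared: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_TERMS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return VARIANT_TERMS[self.variant]

    def weight(self, term: str) -> float:
        return float(self.weights.get(term, 1.0))


@dataclass
class LossBreakdown:
    """Total loss and the per-term values that are active for the variant."""

    total: float
    terms: dict[str, float]
    normalizers: dict[str, int]


def enumerate_angles(bonds: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All bonded angle triples (i, j, k) with vertex j, canonicalized i < k."""
    neighbors: dict[int, list[int]] = {}
    for u, v in bonds:
        neighbors.setdefault(u, []).append(v)
        neighbors.setdefault(v, []).append(u)
    triples = []
    for j, nbrs in sorted(neighbors.items()):
        nbrs = sorted(nbrs)
        for a_idx in range(len(nbrs)):
            for b_idx in range(a_idx + 1, len(nbrs)):
                triples.append((nbrs[a_idx], j, nbrs[b_idx]))
    return triples


def build_targets(conformer: Conformer, graph: MolecularGraph,
                  heavy_only: bool = False) -> SupervisionTargets:
    """Derive all supervision targets from one conformer.

    Gram and distance targets are restricted to heavy atoms when
    ``heavy_only`` (hydrogens still participate in the centering, bonds and
    angles, which cover the full molecule).
    """
    if conformer.n_atoms != graph.n_atoms:
        raise ValueError("conformer and graph atom counts differ")
    centered = center_coordinates(conformer)
    subset = np.flatnonzero(conformer.heavy_mask) if heavy_only else np.arange(conformer.n_atoms)
    sub_coords = centered.coords[subset]
    g = sub_coords @ sub_coords.T
    gram = GramMatrix((g + g.T) / 2.0)
    diff = sub_coords[:, None, :] - sub_coords[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(d, 0.0)
    distance = DistanceMatrix((d + d.T) / 2.0,
                              origin_distances=np.linalg.norm(sub_coords, axis=1))

    bonds = [tuple(b) for b in graph.bonds]
    x = centered.coords
    lengths = np.array([np.linalg.norm(x[u] - x[v]) for u, v in bonds])
    angles = enumerate_angles(bonds)
    full_gram = gram_from_coords(centered)
    thetas = np.array([np.arccos(angle_cosine_from_gram(full_gram, i, j, k))
                       for i, j, k in angles]) if angles else np.zeros(0)
    return SupervisionTargets(gram, distance, bonds, lengths, angles, thetas, subset)


def predict_for_variant(model: GramEncoder, emb: AtomEmbeddings,
                        targets: SupervisionTargets,
                        spec: VariantSpec) -> dict[str, nn.Tensor]:
    """Run exactly the prediction heads the variant supervises."""
    preds: dict[str, nn.Tensor] = {}
    subset = targets.atom_subset
    needs_gram = {"gram", "distance"} & set(spec.terms)
    if needs_gram:
        h = nn.gather_rows(emb.h, subset)
        gram_hat = h @ h.T
        if "gram" in spec.terms:
            preds["gram"] = gram_hat
        if "distance" in spec.terms:
            diag = nn.gather_rows(
                gram_hat.reshape(len(subset) * len(subset)),
                np.arange(len(subset)) * (len(subset) + 1)).reshape(len(subset), 1)
            sq = diag + diag.T - 2.0 * gram_hat + _DIST_EPS
            preds["distance"] = sq.sqrt()
    if "origin_distance" in spec.terms:
        preds["origin_distance"] = nn.gather_rows(
            model.predict_origin_distances(emb).reshape(-1, 1), subset).reshape(len(subset))
    if "bond_length" in spec.terms:
        preds["bond_length"] = model.predict_bond_lengths(emb, targets.bonds)
    if "bond_angle" in spec.terms:
        preds["bond_angle"] = model.predict_bond_angles(emb, targets.angles)
    return preds


def loss_variant(predictions: dict[str, nn.Tensor],
                 targets: SupervisionTargets,
                 spec: VariantSpec) -> tuple[nn.Tensor, LossBreakdown]:
    """Variant loss for one molecule; returns the differentiable total and a
    float breakdown. Inactive terms are absent from the breakdown."""
    missing = [t for t in spec.terms if t not in predictions]
    if missing:
        raise ConfigurationError(
            f"variant {spec.variant!r} requires prediction heads {missing}")

    truth = {
        "gram": targets.gram.values,
        "distance": targets.distance.values,
        "origin_distance": targets.distance.origin_distances,
        "bond_length": targets.bond_lengths,
        "bond_angle": targets.bond_angles,
    }
    total: nn.Tensor | None = None
    terms: dict[str, float] = {}
    norms: dict[str, int] = {}
    for term in spec.terms:
        y = truth[term]
        if y is None or y.size == 0:
            continue
        delta = nn.Tensor(y) - predictions[term]
        if term == "bond_angle" and not spec.angle_squared:
            value = delta.mean()  # literal signed form
        else:
            value = (delta * delta).mean()
        terms[term] = value.item()
        norms[term] = int(np.asarray(y).size)
        weighted = value * spec.weight(term)
        total = weighted if total is None else total + weighted
    if total is None:
        raise ConfigurationError("no active loss terms for this molecule")
    return total, LossBreakdown(total.item(), terms, norms)


def batch_loss(model: GramEncoder, batch, spec: VariantSpec,
               noise_seeds=None) -> tuple[nn.Tensor, LossBreakdown]:
    """Unweighted mean of per-molecule variant losses over a batch.

    ``batch`` is a sequence of (graph, topology, targets) triples;
    ``noise_seeds`` an optional per-molecule seed list for the initial-state
    noise.
    """
    total: nn.Tensor | None = None
    agg: dict[str, float] = {}
    norms: dict[str, int] = {}
    for idx, (graph, topo, targets) in enumerate(batch):
        seed = None if noise_seeds is None else noise_seeds[idx]
        emb = model.encode(graph, topo, noise_seed=seed)
        preds = predict_for_variant(model, emb, targets, spec)
        mol_total, br = loss_variant(preds, targets, spec)
        total = mol_total if total is None else total + mol_total
        for k, v in br.terms.items():
            agg[k] = agg.get(k, 0.0) + v
            norms[k] = norms.get(k, 0) + br.normalizers[k]
    n = len(batch)
    total = total * (1.0 / n)
    return total, LossBreakdown(total.item(), {k: v / n for k, v in agg.items()}, norms)


def training_step(batch, model: GramEncoder, spec: VariantSpec,
                  optimizer: nn.Adam, noise_seeds=None) -> LossBreakdown:
    """One gradient step on the variant loss over a batch of molecules."""
    optimizer.zero_grad()
    total, breakdown = batch_loss(model, batch, spec, noise_seeds)
    if not np.isfinite(total.data):
        ids = [g.id for g, _, _ in batch]
        raise FloatingPointError(f"non-finite loss on batch {ids}")
    total.backward()
    optimizer.step()
    return breakdown


def prepare_batch(graphs: list[MolecularGraph], heavy_only: bool = False):
    """Precompute (graph, topology, targets) triples for training."""
    batch = []
    for g in graphs:
        if g.conformer is None:
            raise ValueError(f"molecule {g.id!r} has no conformer")
        topo = topology_tables(g)
        batch.append((g, topo, build_targets(g.conformer, g, heavy_only=heavy_only)))
    return batch
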