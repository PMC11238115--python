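"""Evaluation metrics for Gram-matrix prediction and conformer quality.

Scalar/matrix regression quality is scored with R^2, RMSE and MAE over
flattened elements. Conformer quality uses RMSD after optimal superposition
(Kabsch), computed over heavy atoms, optionally permitting improper rotations
— a Gram matrix cannot distinguish mirror images, so reconstructions are
scored with reflections allowed, while bioactive reference comparisons keep
them disallowed. Ensemble quality uses the coverage (COV) and matching (MAT)
metrics: the fraction of reference conformers matched within an RMSD
threshold delta, and the mean over references of the minimum RMSD to the
generated set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import GramEncoder, derive_geometry_from_gram
from .geometry import Conformer, GramMatrix, mds_reconstruct
from .objectives import SupervisionTargets, VariantSpec, build_targets, enumerate_angles
from .io import MolecularGraph, topology_tables


class MetricError(ValueError):
    """Metric undefined for the given input."""


def r_squared(truth, pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot over flattened
    elements; undefined for constant truth."""
    y = np.asarray(truth, dtype=np.float64).ravel()
    yhat = np.asarray(pred, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise MetricError("shape mismatch")
    if y.size < 2:
        raise MetricError("R^2 needs at least 2 elements")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise MetricError("R^2 undefined for constant truth")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def rmse(truth, pred) -> float:
    y = np.asarray(truth, dtype=np.float64).ravel()
    yhat = np.asarray(pred, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise MetricError("shape mismatch")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(truth, pred) -> float:
    y = np.asarray(truth, dtype=np.float64).ravel()
    yhat = np.asarray(pred, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise MetricError("shape mismatch")
    return float(np.mean(np.abs(y - yhat)))


def kabsch_rotation(candidate: np.ndarray, reference: np.ndarray,
                    allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal matrix R minimizing ||candidate @ R - reference||_F for
    centered point sets; restricted to proper rotations unless
    ``allow_reflection``."""
    c = candidate.T @ reference
    u, _, vt = np.linalg.svd(c)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        u[:, -1] *= -1.0
    return u @ vt


def aligned_rmsd(reference: Conformer, candidate: Conformer,
                 allow_reflection: bool = False, heavy_only: bool = True,
                 align: bool = True) -> float:
    """RMSD between two conformers after centering and optimal superposition.

    Both structures are centered on the scored atom subset (heavy atoms by
    default); ``align=False`` skips the rotation and scores the raw centered
    deviation.
    """
    if reference.n_atoms != candidate.n_atoms:
        raise MetricError("conformers must have the same atom count")
    if list(reference.elements) != list(candidate.elements):
        raise MetricError("conformers must share element order")
    mask = reference.heavy_mask if heavy_only else np.ones(reference.n_atoms, bool)
    if mask.sum() == 0:
        raise MetricError("no atoms selected for RMSD")
    ref = reference.coords[mask]
    cand = candidate.coords[mask]
    ref = ref - ref.mean(axis=0)
    cand = cand - cand.mean(axis=0)
    if align:
        cand = cand @ kabsch_rotation(cand, ref, allow_reflection=allow_reflection)
    return float(np.sqrt(np.mean(np.sum((cand - ref) ** 2, axis=1))))


def coverage_and_matching(generated: list[Conformer], reference: list[Conformer],
                          delta: float = 2.0, max_ensemble: int = 1,
                          allow_reflection: bool = False) -> tuple[float, float]:
    """COV and MAT between generated and reference conformer ensembles.

    COV is the fraction of reference conformers lying within RMSD ``delta``
    of at least one generated conformer; MAT the mean over references of the
    minimum RMSD to the generated set. Both ensembles are truncated to
    ``max_ensemble`` members (default 1: minimum-energy-conformer
    evaluation).
    """
    if not reference:
        raise MetricError("reference ensemble must be nonempty")
    if not generated:
        raise MetricError("generated ensemble must be nonempty")
    if delta <= 0:
        raise MetricError("delta must be positive")
    gen = generated[:max_ensemble]
    ref = reference[:max_ensemble]
    min_rmsds = np.array([
        min(aligned_rmsd(r, g, allow_reflection=allow_reflection) for g in gen)
        for r in ref
    ])
    cov = float(np.mean(min_rmsds < delta))
    mat = float(np.mean(min_rmsds))
    return cov, mat


@dataclass
class MetricReport:
    """Summary metrics plus a per-molecule table."""

    summary: dict
    per_molecule: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_molecule.to_csv(out / "metrics_per_molecule.csv", index=False)
        with open(out / "metrics_summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def evaluation_report(model: GramEncoder, graphs: list[MolecularGraph],
                      spec: VariantSpec | None = None, delta: float = 2.0,
                      noise_seed: int | None = None,
                      allow_reflection: bool = True) -> MetricReport:
    """Score a trained encoder on molecules with reference conformers.

    Predicts the Gram matrix for every molecule, derives distances from it,
    uses the dedicated bond-length/angle heads when the variant trained them
    and the Gram-derived pathway otherwise, reconstructs a conformer by MDS
    and computes pooled R^2 / RMSE / MAE panels plus RMSD statistics and
    single-conformer COV/MAT at threshold ``delta``. Molecules without a
    reference conformer are skipped and counted.
    """
    spec = spec or VariantSpec("d")
    use_mlp_heads = spec.variant == "d"
    rows = []
    pools: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        "gram": [], "distance": [], "length": [], "angle": []}
    generated, references = [], []
    skipped = 0
    for g in graphs:
        if g.conformer is None:
            skipped += 1
            continue
        topo = topology_tables(g)
        targets = build_targets(g.conformer, g,
                                heavy_only=model.config.gram_heavy_only)
        emb = model.encode(g, topo, noise_seed=noise_seed)
        gram_hat = model.predict_gram(emb).data
        gram_true = targets.gram.values
        d_hat = _distance_from_gram_values(gram_hat)
        d_true = targets.distance.values
        if use_mlp_heads:
            lengths_hat = model.predict_bond_lengths(emb, targets.bonds).data
            angles_hat = model.predict_bond_angles(emb, targets.angles).data
        else:
            full_gram_hat = _full_gram(model, emb)
            lengths_hat, cos_hat, _ = derive_geometry_from_gram(
                full_gram_hat, targets.bonds, targets.angles)
            angles_hat = np.arccos(cos_hat)
        sub_elems = [g.elements[i] for i in targets.atom_subset]
        recon = mds_reconstruct(GramMatrix((gram_hat + gram_hat.T) / 2), sub_elems)
        ref = Conformer(g.conformer.coords[targets.atom_subset], sub_elems)
        rmsd = aligned_rmsd(ref, recon, allow_reflection=allow_reflection,
                            heavy_only=True)
        generated.append(recon)
        references.append(ref)
        pools["gram"].append((gram_true.ravel(), gram_hat.ravel()))
        pools["distance"].append((d_true.ravel(), d_hat.ravel()))
        pools["length"].append((targets.bond_lengths, lengths_hat))
        if targets.bond_angles.size:
            pools["angle"].append((targets.bond_angles, angles_hat))
        rows.append({
            "id": g.id, "n_atoms": g.n_atoms,
            "gram_mae": mae(gram_true, gram_hat),
            "distance_mae": mae(d_true, d_hat),
            "length_mae": mae(targets.bond_lengths, lengths_hat),
            "angle_mae_rad": mae(targets.bond_angles, angles_hat)
            if targets.bond_angles.size else np.nan,
            "angle_mae_deg": np.degrees(mae(targets.bond_angles, angles_hat))
            if targets.bond_angles.size else np.nan,
            "rmsd": rmsd,
        })
    if not rows:
        raise MetricError("no molecules with reference conformers")
    table = pd.DataFrame(rows)
    summary: dict = {"n_molecules": len(rows), "n_skipped": skipped,
                     "delta": delta}
    for key, pool in pools.items():
        if not pool:
            continue
        y = np.concatenate([t for t, _ in pool])
        yhat = np.concatenate([p for _, p in pool])
        summary[f"{key}_mae"] = mae(y, yhat)
        summary[f"{key}_rmse"] = rmse(y, yhat)
        summary[f"{key}_r2"] = r_squared(y, yhat)
    summary["angle_mae_deg"] = (np.degrees(summary["angle_mae"])
                                if "angle_mae" in summary else None)
    summary["rmsd_mean"] = float(table["rmsd"].mean())
    summary["rmsd_median"] = float(table["rmsd"].median())
    cov, mat = _per_molecule_cov_mat(generated, references, delta, allow_reflection)
    summary["cov"] = cov
    summary["mat"] = mat
    return MetricReport(summary, table)


def _per_molecule_cov_mat(generated, references, delta, allow_reflection):
    """Mean COV/MAT across molecules, one conformer per ensemble."""
    covs, mats = [], []
    for gen, ref in zip(generated, references):
        c, m = coverage_and_matching([gen], [ref], delta=delta,
                                     allow_reflection=allow_reflection)
        covs.append(c)
        mats.append(m)
    return float(np.mean(covs)), float(np.mean(mats))


def _distance_from_gram_values(g: np.ndarray) -> np.ndarray:
    diag = np.diag(g)
    sq = np.clip(diag[:, None] + diag[None, :] - 2.0 * g, 0.0, None)
    d = np.sqrt(sq)
    np.fill_diagonal(d, 0.0)
    return d


def _full_gram(model: GramEncoder, emb) -> np.ndarray:
    h = emb.h.data
    return h @ h.T
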