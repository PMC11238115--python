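"""Two-stage workflow: geometric pretraining, then frozen-embedding property
prediction.

Stage 1 trains the graph-transformer encoder ``M_a`` on molecules with known
conformers under one of the four geometric supervision variants, early
stopping on validation loss. Stage 2 freezes ``M_a``, computes its final atom
embeddings for downstream molecules from topology alone (no conformers
anywhere), trains a fresh encoder ``M_b`` of the same architecture family,
and concatenates frozen and fresh per-atom embeddings before a readout and a
fully connected head. All randomness flows from one global seed; with noise
disabled a rerun of the whole pipeline is bit-identical, which the manifest
hash makes checkable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import nn
from .encoder import EncoderConfig, GramEncoder
from .io import MolecularGraph, random_split, topology_tables
from .metrics import evaluation_report, mae, r_squared, rmse
from .objectives import VariantSpec, batch_loss, prepare_batch, training_step


@dataclass
class Stage1Config:
    """Pretraining stage: supervision variant, encoder and optimizer."""

    variant: str = "d"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    lr: float = 1e-3
    epochs: int = 200
    patience: int = 20
    heavy_only_gram: bool = False


@dataclass
class Stage2Config:
    """Property stage: task type, readout and head."""

    task: str = "regression"          # regression | classification
    readout: str = "mean"             # mean | sum | super
    head_width: int = 64
    n_tasks: int = 1
    lr: float = 1e-3
    epochs: int = 200


@dataclass
class RunConfig:
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    seed: int = 0
    out_dir: str = "runs/gramconf"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        s1 = dict(raw.get("stage1", {}))
        enc = EncoderConfig(**s1.pop("encoder", {}))
        return cls(stage1=Stage1Config(encoder=enc, **s1),
                   stage2=Stage2Config(**raw.get("stage2", {})),
                   seed=int(raw.get("seed", 0)),
                   out_dir=raw.get("out_dir", "runs/gramconf"))


def _noise_seeds(base_seed: int, n: int, sigma: float):
    """Fixed per-molecule noise seeds (reused every epoch and at test time)
    when noise is on; None disables the perturbation entirely."""
    if sigma <= 0:
        return None
    return [(base_seed * 100003 + i * 7919) % (2**31) for i in range(n)]


def run_pretraining(train_graphs: list[MolecularGraph],
                    val_graphs: list[MolecularGraph],
                    config: Stage1Config, seed: int,
                    out_dir: Path | None = None,
                    stop_at_loss: float | None = None):
    """Train the stage-1 encoder; returns (model, report).

    Early-stops when validation loss fails to improve for ``patience`` epochs
    (or, optionally, once training loss reaches ``stop_at_loss``); the best
    parameters by validation loss are restored before returning.
    """
    missing = [g.id for g in train_graphs + val_graphs if g.conformer is None]
    if missing:
        raise ValueError(f"molecules lack conformers: {missing}")
    enc_cfg = EncoderConfig(**{**asdict(config.encoder),
                               "seed": seed,
                               "gram_heavy_only": config.heavy_only_gram})
    model = GramEncoder(enc_cfg)
    spec = VariantSpec(config.variant)
    train_batch = prepare_batch(train_graphs, heavy_only=config.heavy_only_gram)
    val_batch = prepare_batch(val_graphs, heavy_only=config.heavy_only_gram)
    opt = nn.Adam(model.params, lr=config.lr)
    train_seeds = _noise_seeds(seed, len(train_batch), enc_cfg.noise_sigma)
    val_seeds = _noise_seeds(seed + 1, len(val_batch), enc_cfg.noise_sigma)

    best_val = np.inf
    best_params = None
    best_epoch = -1
    history = []
    log_fh = open(out_dir / "stage1_log.jsonl", "w") if out_dir else None
    try:
        for epoch in range(config.epochs):
            br = training_step(train_batch, model, spec, opt, train_seeds)
            with_val = len(val_batch) > 0
            if with_val:
                val_total, _ = batch_loss(model, val_batch, spec, val_seeds)
                val_loss = val_total.item()
            else:
                val_loss = br.total
            record = {"epoch": epoch, "train_loss": br.total,
                      "val_loss": val_loss, **{f"train_{k}": v for k, v in br.terms.items()}}
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_epoch = epoch
                best_params = {k: p.data.copy() for k, p in model.params.items()}
            elif epoch - best_epoch >= config.patience:
                break
            if stop_at_loss is not None and br.total <= stop_at_loss:
                break
    finally:
        if log_fh:
            log_fh.close()
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    report = {"epochs_run": len(history), "best_epoch": best_epoch,
              "best_val_loss": best_val, "final_train_loss": history[-1]["train_loss"],
              "epoch0_train_loss": history[0]["train_loss"],
              "active_terms": list(spec.terms), "history": history}
    return model, report


def extract_frozen_embeddings(model: GramEncoder,
                              graphs: list[MolecularGraph],
                              noise_seed_base: int | None = None) -> dict[str, np.ndarray]:
    """Final per-atom embeddings from the frozen stage-1 encoder.

    Molecules need topology only — no conformers. With
    ``noise_seed_base=None`` (the default) no noise is applied and repeated
    calls are byte-identical.
    """
    table: dict[str, np.ndarray] = {}
    for idx, g in enumerate(graphs):
        seed = None if noise_seed_base is None else (noise_seed_base + idx) % (2**31)
        emb = model.encode(g, noise_seed=seed)
        table[g.id] = emb.h.data.copy()
    return table


def save_embeddings(path, table: dict[str, np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        for mol_id, h in table.items():
            f.create_dataset(mol_id, data=h)


def load_embeddings(path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {k: f[k][()] for k in f.keys()}


class PropertyModel:
    """Fresh encoder M_b plus readout and fully connected head over the
    concatenation of frozen and fresh atom embeddings."""

    def __init__(self, config: Stage2Config, encoder_config: EncoderConfig,
                 seed: int, frozen_checksum: str = ""):
        self.config = config
        enc_cfg = EncoderConfig(**{**asdict(encoder_config),
                                   "seed": seed, "noise_sigma": 0.0,
                                   "noise_mu": 0.0})
        self.encoder = GramEncoder(enc_cfg)
        self.frozen_checksum = frozen_checksum
        rng = np.random.default_rng(seed + 1)
        h2 = 2 * enc_cfg.hidden
        w = config.head_width

        def glorot(*shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return nn.parameter(rng.uniform(-limit, limit, size=shape))
        self.head = {
            "W1": glorot(h2, w), "b1": nn.parameter(np.zeros(w)),
            "W2": glorot(w, config.n_tasks), "b2": nn.parameter(np.zeros(config.n_tasks)),
        }

    def trainable_params(self) -> dict[str, nn.Tensor]:
        params = {f"mb/{k}": v for k, v in self.encoder.params.items()}
        params.update({f"head/{k}": v for k, v in self.head.items()})
        return params

    def forward(self, graph: MolecularGraph, frozen_h: np.ndarray) -> nn.Tensor:
        """Molecule-level output (n_tasks,): raw prediction for regression,
        logits for classification."""
        if frozen_h.shape[0] != graph.n_atoms:
            raise ValueError(
                f"frozen embeddings for {graph.id!r} cover {frozen_h.shape[0]} "
                f"atoms but the graph has {graph.n_atoms}")
        emb = self.encoder.encode(graph)
        x = nn.concat([nn.Tensor(frozen_h), emb.h], axis=1)
        if self.config.readout == "mean":
            h_s = x.mean(axis=0)
        elif self.config.readout == "sum":
            h_s = x.sum(axis=0)
        elif self.config.readout == "super":
            h_s = nn.concat([nn.Tensor(frozen_h).mean(axis=0), emb.super], axis=0)
        else:
            raise ValueError(f"unknown readout {self.config.readout!r}")
        hidden = nn.gelu(h_s.reshape(1, -1) @ self.head["W1"] + self.head["b1"])
        return (hidden @ self.head["W2"] + self.head["b2"]).reshape(self.config.n_tasks)

    def predict(self, graph: MolecularGraph, frozen_h: np.ndarray) -> np.ndarray:
        out = self.forward(graph, frozen_h).data
        if self.config.task == "classification":
            return 1.0 / (1.0 + np.exp(-out))
        return out


def auc_roc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum statistic (ties averaged)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    sorted_scores = scores[order]
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def train_property_model(labeled: list[tuple[MolecularGraph, np.ndarray]],
                         frozen: dict[str, np.ndarray],
                         config: Stage2Config, encoder_config: EncoderConfig,
                         seed: int, frozen_checksum: str = "",
                         out_dir: Path | None = None) -> tuple[PropertyModel, dict]:
    """Fit the stage-2 model on labeled molecules with frozen embeddings.

    Squared-error loss for regression, elementwise sigmoid cross-entropy for
    (possibly multi-task) classification with NaN labels masked out.
    """
    for g, _ in labeled:
        if g.id not in frozen:
            raise ValueError(f"no frozen embeddings for molecule {g.id!r}")
    model = PropertyModel(config, encoder_config, seed, frozen_checksum)
    opt = nn.Adam(model.trainable_params(), lr=config.lr)
    log_fh = open(out_dir / "stage2_log.jsonl", "w") if out_dir else None
    history = []
    try:
        for epoch in range(config.epochs):
            opt.zero_grad()
            total: nn.Tensor | None = None
            for g, y in labeled:
                out = model.forward(g, frozen[g.id])
                y = np.atleast_1d(np.asarray(y, dtype=np.float64))
                if config.task == "regression":
                    delta = out - nn.Tensor(y)
                    loss = (delta * delta).mean()
                else:
                    mask = np.isfinite(y)
                    target = np.where(mask, y, 0.0)
                    p = nn.sigmoid(out)
                    eps = 1e-9
                    ce = (nn.Tensor(target) * (p + eps).log()
                          + nn.Tensor(1.0 - target) * (1.0 - p + eps).log())
                    loss = -(ce * nn.Tensor(mask.astype(float))).sum() / max(mask.sum(), 1)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(labeled))
            total.backward()
            opt.step()
            record = {"epoch": epoch, "train_loss": total.item()}
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
    finally:
        if log_fh:
            log_fh.close()
    return model, {"epochs_run": len(history), "history": history,
                   "final_train_loss": history[-1]["train_loss"] if history else None}


def evaluate_property_model(model: PropertyModel,
                            labeled: list[tuple[MolecularGraph, np.ndarray]],
                            frozen: dict[str, np.ndarray]) -> dict:
    preds = np.stack([model.predict(g, frozen[g.id]) for g, _ in labeled])
    truth = np.stack([np.atleast_1d(np.asarray(y, dtype=np.float64))
                      for _, y in labeled])
    if model.config.task == "regression":
        out = {"rmse": rmse(truth, preds), "mae": mae(truth, preds)}
        try:
            out["r2"] = r_squared(truth, preds)
        except Exception:
            out["r2"] = None  # undefined for a single or constant test set
        return out
    aucs = []
    for t in range(truth.shape[1]):
        mask = np.isfinite(truth[:, t])
        if mask.sum() and 0 < truth[mask, t].sum() < mask.sum():
            aucs.append(auc_roc(truth[mask, t] > 0.5, preds[mask, t]))
    return {"auc_roc": float(np.mean(aucs)) if aucs else None,
            "n_tasks_scored": len(aucs)}


def overfit_recovery_run(seed: int, n_molecules: int = 10,
                         max_steps: int = 2000, lr: float = 5e-3,
                         noise_sigma: float = 1.0,
                         target_mae: float | None = 0.04,
                         check_every: int = 100) -> dict:
    """End-to-end learnability check: drive a small encoder to memorize the
    heavy-atom Gram matrices of a handful of toy molecules.

    Trains an L=3, H=64 encoder under the combined Gram + bond length + bond
    angle objective on ``n_molecules`` topology-distinct, heavy-atom-
    asymmetric toy molecules. Initial-state noise (drawn once per molecule
    and reused every pass, training and evaluation alike) supplies the
    symmetry breaking that lets a 2D encoder assign distinct geometric roles
    to atoms with identical features. Returns the final Gram MAE (A^2) and
    the mean heavy-atom reconstruction RMSD (A); stops early once the
    training Gram MAE falls below ``target_mae``.
    """
    from .fixtures import FixtureSpec, generate_toy_molecules, heavy_atoms_asymmetric
    from .geometry import Conformer, GramMatrix, mds_reconstruct
    from .io import canonical_smiles
    from .metrics import aligned_rmsd
    from .objectives import VariantSpec, prepare_batch, training_step

    pool = generate_toy_molecules(FixtureSpec(
        n_molecules=8 * n_molecules, min_atoms=4, max_atoms=9,
        seed=seed % (2**31)))
    chosen, seen = [], set()
    for g in pool:
        if not heavy_atoms_asymmetric(g):
            continue
        smi = canonical_smiles(g)
        if smi in seen:
            continue
        seen.add(smi)
        chosen.append(g)
        if len(chosen) == n_molecules:
            break
    cfg = EncoderConfig(layers=3, hidden=64, heads=4, ffn_width=128,
                        noise_sigma=noise_sigma, seed=seed % (2**31),
                        gram_heavy_only=True)
    model = GramEncoder(cfg)
    batch = prepare_batch(chosen, heavy_only=True)
    spec = VariantSpec("d")
    # short-horizon memorization favors a fast-adapting second moment
    opt = nn.Adam(model.params, lr=lr, betas=(0.9, 0.95))
    seeds = _noise_seeds(seed, len(batch), cfg.noise_sigma)

    def measure():
        maes, rmsds = [], []
        for idx, (g, topo, tg) in enumerate(batch):
            nseed = None if seeds is None else seeds[idx]
            emb = model.encode(g, topo, noise_seed=nseed)
            ghat = model.predict_gram(emb).data
            maes.append(np.abs(ghat - tg.gram.values).mean())
            sub = tg.atom_subset
            elems = [g.elements[i] for i in sub]
            rec = mds_reconstruct(GramMatrix((ghat + ghat.T) / 2), elems)
            ref = Conformer(g.conformer.coords[sub], elems)
            rmsds.append(aligned_rmsd(ref, rec, allow_reflection=True))
        return float(np.mean(maes)), float(np.mean(rmsds))

    steps_run = 0
    for step in range(1, max_steps + 1):
        training_step(batch, model, spec, opt, noise_seeds=seeds)
        steps_run = step
        if target_mae is not None and step % check_every == 0:
            gram_mae, _ = measure()
            if gram_mae < target_mae:
                break
    gram_mae, mean_rmsd = measure()
    return {"gram_mae": gram_mae, "reconstruction_rmsd": mean_rmsd,
            "steps": steps_run, "n_molecules": len(batch)}


def heavy_atom_count_label(graph: MolecularGraph) -> float:
    """Synthetic learnable regression label: number of heavy atoms."""
    return float(graph.heavy_mask.sum())


def end_to_end(config: RunConfig, graphs: list[MolecularGraph],
               labels: dict[str, np.ndarray] | None = None) -> dict:
    """Run split -> pretrain -> freeze/embed -> property-train -> evaluate.

    Writes checkpoints, embeddings, metrics and a manifest (config hash,
    seed, parameter checksums, metrics) into ``config.out_dir``; with noise
    disabled the manifest hash is reproducible bit for bit. Returns the
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "split"
    try:
        train_idx, val_idx, test_idx = random_split(graphs, seed=config.seed)
        train = [graphs[i] for i in train_idx]
        val = [graphs[i] for i in val_idx]
        test = [graphs[i] for i in test_idx]

        stage = "pretrain"
        model_a, report1 = run_pretraining(train, val, config.stage1,
                                           config.seed, out_dir=out)
        model_a.save(out / "stage1.ckpt.h5", metadata={"seed": config.seed})
        checksum_before = model_a.parameter_checksum()

        stage = "embed"
        frozen = extract_frozen_embeddings(model_a, graphs)
        save_embeddings(out / "frozen_embeddings.h5", frozen)

        stage = "property-train"
        if labels is None:
            labels = {g.id: np.array([heavy_atom_count_label(g)]) for g in graphs}
        labeled_train = [(g, labels[g.id]) for g in train]
        labeled_test = [(g, labels[g.id]) for g in test]
        model_b, report2 = train_property_model(
            labeled_train, frozen, config.stage2, config.stage1.encoder,
            config.seed, frozen_checksum=checksum_before, out_dir=out)

        stage = "evaluate"
        prop_metrics = evaluate_property_model(model_b, labeled_test, frozen)
        geo_report = evaluation_report(model_a, test,
                                       VariantSpec(config.stage1.variant))
        geo_report.write(out)
        checksum_after = model_a.parameter_checksum()
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "splits": {"train": train_idx, "val": val_idx, "test": test_idx},
        "stage1": {"best_val_loss": report1["best_val_loss"],
                   "epochs_run": report1["epochs_run"],
                   "active_terms": report1["active_terms"]},
        "stage1_checksum_before_stage2": checksum_before,
        "stage1_checksum_after_stage2": checksum_after,
        "stage1_frozen_during_stage2": checksum_before == checksum_after,
        "stage2": {"final_train_loss": report2["final_train_loss"],
                   "metrics": prop_metrics},
        "geometry_metrics": geo_report.summary,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir", None)  # paths must not affect the manifest hash
    return d
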