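"""Graph-transformer encoder over 2D molecular graphs with geometric heads.

The encoder follows the Graphormer recipe: atom states are initialized from a
linear projection of the 17-dimensional atom features plus a learned
degree-centrality embedding; attention logits between atoms i and j receive an
additive per-head spatial bias indexed by the capped shortest-hop distance
``phi(i, j)`` and an edge-encoding term averaging learned projections of the
bond features along one shortest path; a super node attending to and from all
atoms through a reserved hop bucket carries global context. Gaussian noise
added to the initial states breaks ties between graph-automorphic atoms so a
2D-topology encoder can target quantities that depend on 3D geometry.

Prediction heads map final atom states to geometry: the Gram matrix as plain
inner products ``G_uv = h_u . h_v`` (symmetric positive semidefinite by
construction), atom-to-origin distances from a fully connected layer on the
super-node/atom concatenation, and bond lengths / bond angles from small MLPs
on concatenated endpoint embeddings, squashed into their physical ranges
(softplus for lengths, (0, pi) scaled sigmoid for angles).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from . import nn
from .geometry import GramMatrix
from .io import (ATOM_FEATURE_DIM, BOND_FEATURE_DIM, DISCONNECTED_HOPS,
                 MolecularGraph, TopologyTables, topology_tables)

CHECKPOINT_VERSION = 1


class ConfigurationError(ValueError):
    """Inconsistent encoder configuration or missing prediction head."""


@dataclass
class EncoderConfig:
    """Hyperparameters of the graph-transformer encoder.

    ``noise_mu`` / ``noise_sigma`` parameterize the Gaussian perturbation of
    initial atom states (sigma is a standard deviation); ``max_hop_cap`` and
    ``max_degree_cap`` bound the learned bucket tables, with hops beyond the
    cap sharing the cap bucket and disconnected pairs / super-node pairs using
    reserved buckets of their own.
    """

    layers: int = 3
    hidden: int = 64
    heads: int = 4
    ffn_width: int = 128
    max_hop_cap: int = 8
    max_degree_cap: int = 8
    noise_mu: float = 0.0
    noise_sigma: float = 0.02
    dropout: float = 0.0
    seed: int = 0
    gram_heavy_only: bool = False

    def __post_init__(self) -> None:
        if self.hidden % self.heads != 0:
            raise ConfigurationError("hidden size must be divisible by heads")
        if self.max_hop_cap < 1 or self.max_degree_cap < 1:
            raise ConfigurationError("bucket caps must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")

    @property
    def n_hop_buckets(self) -> int:
        # 0..cap finite hops, then sentinel (disconnected), then super-node
        return self.max_hop_cap + 3

    @property
    def sentinel_bucket(self) -> int:
        return self.max_hop_cap + 1

    @property
    def super_bucket(self) -> int:
        return self.max_hop_cap + 2


@dataclass
class AtomEmbeddings:
    """Final (and initial) per-atom state vectors plus the super-node state."""

    h: nn.Tensor          # (N, H) final atom states
    h0: np.ndarray        # (N+1, H) initial states (atoms then super node)
    super: nn.Tensor      # (H,) final super-node state
    graph: MolecularGraph = field(repr=False, default=None)  # type: ignore


def _init_params(config: EncoderConfig) -> dict[str, nn.Tensor]:
    rng = np.random.default_rng(config.seed)
    H, F = config.hidden, config.ffn_width
    dh = H // config.heads

    def glorot(*shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return nn.parameter(rng.uniform(-limit, limit, size=shape))

    params: dict[str, nn.Tensor] = {
        "input/W": glorot(ATOM_FEATURE_DIM, H),
        "input/b": nn.parameter(np.zeros(H)),
        "centrality/z_deg": nn.parameter(rng.normal(0, 0.02, (config.max_degree_cap + 1, H))),
        "super/init": nn.parameter(rng.normal(0, 0.02, H)),
        "spatial/b_phi": nn.parameter(rng.normal(0, 0.02, (config.heads, config.n_hop_buckets))),
        "edge/w": nn.parameter(rng.normal(0, 0.02, (config.max_hop_cap, BOND_FEATURE_DIM))),
        "final/ln_g": nn.parameter(np.ones(H)),
        "final/ln_b": nn.parameter(np.zeros(H)),
        "final/W": glorot(H, H),
        "final/b": nn.parameter(np.zeros(H)),
    }
    for layer in range(config.layers):
        p = f"layer{layer}"
        params[f"{p}/ln1_g"] = nn.parameter(np.ones(H))
        params[f"{p}/ln1_b"] = nn.parameter(np.zeros(H))
        params[f"{p}/Wqkv"] = glorot(H, 3 * H)
        params[f"{p}/bqkv"] = nn.parameter(np.zeros(3 * H))
        params[f"{p}/Wo"] = glorot(H, H)
        params[f"{p}/bo"] = nn.parameter(np.zeros(H))
        params[f"{p}/ln2_g"] = nn.parameter(np.ones(H))
        params[f"{p}/ln2_b"] = nn.parameter(np.zeros(H))
        params[f"{p}/Wff1"] = glorot(H, F)
        params[f"{p}/bff1"] = nn.parameter(np.zeros(F))
        params[f"{p}/Wff2"] = glorot(F, H)
        params[f"{p}/bff2"] = nn.parameter(np.zeros(H))
    # prediction heads
    params.update({
        "origin/W1": glorot(2 * H, H), "origin/b1": nn.parameter(np.zeros(H)),
        "origin/W2": glorot(H, 1), "origin/b2": nn.parameter(np.zeros(1)),
        "length/W1": glorot(2 * H, H), "length/b1": nn.parameter(np.zeros(H)),
        "length/W2": glorot(H, 1), "length/b2": nn.parameter(np.zeros(1)),
        "angle/W1": glorot(3 * H, H), "angle/b1": nn.parameter(np.zeros(H)),
        "angle/W2": glorot(H, 1), "angle/b2": nn.parameter(np.zeros(1)),
    })
    return params


class GramEncoder:
    """Graphormer-style encoder with Gram/origin-distance/length/angle heads."""

    def __init__(self, config: EncoderConfig,
                 params: dict[str, nn.Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else _init_params(config)
        if self.params["input/W"].shape != (ATOM_FEATURE_DIM, config.hidden):
            raise ConfigurationError("parameter shapes do not match config")

    # ------------------------------------------------------------------
    def _hop_buckets(self, topo: TopologyTables) -> np.ndarray:
        """(N+1, N+1) bucket index matrix including the super node (last)."""
        cfg = self.config
        n = topo.shortest_hops.shape[0]
        hops = topo.shortest_hops
        buckets = np.where(hops == DISCONNECTED_HOPS, cfg.sentinel_bucket,
                           np.minimum(hops, cfg.max_hop_cap))
        full = np.full((n + 1, n + 1), cfg.super_bucket, dtype=np.int64)
        full[:n, :n] = buckets
        full[n, n] = 0  # super node to itself: zero-hop bucket
        return full

    def _edge_encoding(self, graph: MolecularGraph, topo: TopologyTables) -> nn.Tensor:
        """(N+1, N+1) edge-encoding bias c_ij: mean over one shortest path's
        edges of the bond-feature / per-position weight inner products."""
        cfg = self.config
        n = graph.n_atoms
        # stack[p] holds, for each pair, bond features of the p-th path edge
        # scaled by 1/path_length; zero where the path is shorter or absent.
        stack = np.zeros((cfg.max_hop_cap, (n + 1) * (n + 1), BOND_FEATURE_DIM))
        for (u, v), edges in topo.path_edges.items():
            length = min(len(edges), cfg.max_hop_cap)
            for p in range(length):
                feats = graph.bond_features[edges[p]] / length
                stack[p, u * (n + 1) + v] = feats
                stack[p, v * (n + 1) + u] = feats
        contrib = nn.Tensor(stack) @ self.params["edge/w"].reshape(
            cfg.max_hop_cap, BOND_FEATURE_DIM, 1)
        return contrib.sum(axis=0).reshape(n + 1, n + 1)

    def initialize_states(self, graph: MolecularGraph,
                          topo: TopologyTables | None = None) -> nn.Tensor:
        """Initial states h^0: feature projection plus degree-centrality
        embedding for atoms, a dedicated learned vector for the super node.
        Returns an (N+1, H) tensor with the super node last."""
        if graph.atom_features.shape[1] != ATOM_FEATURE_DIM:
            raise ConfigurationError(
                f"expected {ATOM_FEATURE_DIM} atom features, "
                f"got {graph.atom_features.shape[1]}")
        cfg = self.config
        deg = np.minimum(graph.degrees(), cfg.max_degree_cap)
        proj = nn.Tensor(graph.atom_features) @ self.params["input/W"] + self.params["input/b"]
        h0_atoms = proj + nn.gather_rows(self.params["centrality/z_deg"], deg)
        return nn.concat([h0_atoms, self.params["super/init"].reshape(1, cfg.hidden)], axis=0)

    def noise_for(self, n_states: int, seed: int) -> np.ndarray:
        """Gaussian perturbation Z ~ N(mu, sigma^2) for the atom rows of h^0;
        the super-node row is left unperturbed. Deterministic under ``seed``."""
        cfg = self.config
        noise = np.zeros((n_states, cfg.hidden))
        if cfg.noise_sigma > 0 or cfg.noise_mu != 0.0:
            rng = np.random.default_rng(seed)
            noise[: n_states - 1] = rng.normal(
                cfg.noise_mu, cfg.noise_sigma, (n_states - 1, cfg.hidden))
        return noise

    def encode(self, graph: MolecularGraph,
               topo: TopologyTables | None = None,
               noise_seed: int | None = None,
               rng: np.random.Generator | None = None) -> AtomEmbeddings:
        """Full forward pass producing final atom and super-node states.

        Noise on the initial states is drawn deterministically from
        ``noise_seed`` when given (reusing a seed reproduces the perturbation
        exactly); with ``noise_seed=None`` and sigma=0 the pass is noise-free.
        """
        cfg = self.config
        if topo is None:
            topo = topology_tables(graph)
        n = graph.n_atoms
        m = n + 1
        dh = cfg.hidden // cfg.heads

        h = self.initialize_states(graph, topo)
        if noise_seed is not None:
            h = h + nn.Tensor(self.noise_for(m, noise_seed))
        h0 = h.data.copy()

        bias = nn.bucket_bias(self.params["spatial/b_phi"], self._hop_buckets(topo))
        bias = bias + self._edge_encoding(graph, topo).reshape(1, m, m)

        drop_rng = rng
        for layer in range(cfg.layers):
            p = f"layer{layer}"
            x = nn.layer_norm(h, self.params[f"{p}/ln1_g"], self.params[f"{p}/ln1_b"])
            qkv = x @ self.params[f"{p}/Wqkv"] + self.params[f"{p}/bqkv"]
            qkv = qkv.reshape(m, 3, cfg.heads, dh).transpose(1, 2, 0, 3)
            q = nn.gather_rows(qkv.reshape(3, cfg.heads * m * dh), np.array([0])).reshape(cfg.heads, m, dh)
            k = nn.gather_rows(qkv.reshape(3, cfg.heads * m * dh), np.array([1])).reshape(cfg.heads, m, dh)
            v = nn.gather_rows(qkv.reshape(3, cfg.heads * m * dh), np.array([2])).reshape(cfg.heads, m, dh)
            logits = q @ k.transpose(0, 2, 1) * (1.0 / np.sqrt(dh)) + bias
            attn = nn.softmax(logits, axis=-1)
            ctx = (attn @ v).transpose(1, 0, 2).reshape(m, cfg.hidden)
            ctx = ctx @ self.params[f"{p}/Wo"] + self.params[f"{p}/bo"]
            ctx = self._dropout(ctx, drop_rng)
            h = h + ctx
            x = nn.layer_norm(h, self.params[f"{p}/ln2_g"], self.params[f"{p}/ln2_b"])
            ff = nn.gelu(x @ self.params[f"{p}/Wff1"] + self.params[f"{p}/bff1"])
            ff = ff @ self.params[f"{p}/Wff2"] + self.params[f"{p}/bff2"]
            ff = self._dropout(ff, drop_rng)
            h = h + ff

        h = nn.layer_norm(h, self.params["final/ln_g"], self.params["final/ln_b"])
        h = h @ self.params["final/W"] + self.params["final/b"]
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError("non-finite activations in final layer")

        h_atoms = nn.gather_rows(h, np.arange(n))
        h_super = nn.gather_rows(h, np.array([n])).reshape(cfg.hidden)
        return AtomEmbeddings(h=h_atoms, h0=h0, super=h_super, graph=graph)

    def _dropout(self, x: nn.Tensor, rng: np.random.Generator | None) -> nn.Tensor:
        p = self.config.dropout
        if p <= 0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * nn.Tensor(mask)

    # -- heads ----------------------------------------------------------
    def predict_gram(self, emb: AtomEmbeddings,
                     heavy_only: bool | None = None) -> nn.Tensor:
        """Predicted Gram matrix as inner products of final atom states.

        Symmetric and positive semidefinite by construction (rank <= hidden).
        With ``heavy_only`` the matrix covers heavy atoms only.
        """
        heavy_only = self.config.gram_heavy_only if heavy_only is None else heavy_only
        h = emb.h
        if heavy_only:
            h = nn.gather_rows(h, np.flatnonzero(emb.graph.heavy_mask))
        return h @ h.T

    def predict_origin_distances(self, emb: AtomEmbeddings) -> nn.Tensor:
        """Atom-to-origin distances from a fully connected layer on the
        concatenated super-node and atom embeddings; softplus keeps them
        non-negative. Returns an (N,) tensor."""
        n = emb.h.shape[0]
        sup = emb.super.reshape(1, -1) * nn.Tensor(np.ones((n, 1)))
        x = nn.concat([sup, emb.h], axis=1)
        hdn = nn.gelu(x @ self.params["origin/W1"] + self.params["origin/b1"])
        return nn.softplus(hdn @ self.params["origin/W2"] + self.params["origin/b2"]).reshape(n)

    def predict_bond_lengths(self, emb: AtomEmbeddings,
                             bonds: list[tuple[int, int]]) -> nn.Tensor:
        """MLP bond-length head on concatenated endpoint embeddings (A).

        Endpoints are canonicalized (smaller index first) so (u, v) and
        (v, u) give one value; softplus enforces positivity.
        """
        self._check_bonds(emb.graph, bonds)
        iu = np.array([min(u, v) for u, v in bonds], dtype=np.int64)
        iv = np.array([max(u, v) for u, v in bonds], dtype=np.int64)
        x = nn.concat([nn.gather_rows(emb.h, iu), nn.gather_rows(emb.h, iv)], axis=1)
        hdn = nn.gelu(x @ self.params["length/W1"] + self.params["length/b1"])
        return nn.softplus(hdn @ self.params["length/W2"] + self.params["length/b2"]).reshape(len(bonds))

    def predict_bond_angles(self, emb: AtomEmbeddings,
                            angles: list[tuple[int, int, int]]) -> nn.Tensor:
        """MLP bond-angle head on concatenated (i, j, k) embeddings, mapped
        into (0, pi) rad by a scaled sigmoid; arms canonicalized so
        (i, j, k) and (k, j, i) give one value."""
        bond_set = {tuple(sorted(b)) for b in emb.graph.bonds}
        for i, j, k in angles:
            if tuple(sorted((i, j))) not in bond_set or tuple(sorted((j, k))) not in bond_set:
                raise ValueError(f"({i},{j},{k}) is not a bonded angle triple")
        ii = np.array([min(i, k) for i, _, k in angles], dtype=np.int64)
        jj = np.array([j for _, j, _ in angles], dtype=np.int64)
        kk = np.array([max(i, k) for i, _, k in angles], dtype=np.int64)
        x = nn.concat([nn.gather_rows(emb.h, ii), nn.gather_rows(emb.h, jj),
                       nn.gather_rows(emb.h, kk)], axis=1)
        hdn = nn.gelu(x @ self.params["angle/W1"] + self.params["angle/b1"])
        return (nn.sigmoid(hdn @ self.params["angle/W2"] + self.params["angle/b2"])
                * np.pi).reshape(len(angles))

    @staticmethod
    def _check_bonds(graph: MolecularGraph, bonds) -> None:
        bond_set = {tuple(sorted(b)) for b in graph.bonds}
        for u, v in bonds:
            if tuple(sorted((u, v))) not in bond_set:
                raise ValueError(f"({u},{v}) is not a bond of the molecule")

    # -- persistence ----------------------------------------------------
    def save(self, path, metadata: dict | None = None) -> None:
        """Write config, parameters and metadata to a single HDF5 archive."""
        with h5py.File(path, "w") as f:
            f.attrs["version"] = CHECKPOINT_VERSION
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["metadata"] = json.dumps(metadata or {})
            grp = f.create_group("params")
            for name, p in self.params.items():
                grp.create_dataset(name, data=p.data)

    @classmethod
    def load(cls, path) -> tuple["GramEncoder", dict]:
        with h5py.File(path, "r") as f:
            if int(f.attrs["version"]) > CHECKPOINT_VERSION:
                raise ConfigurationError("checkpoint from a newer format version")
            config = EncoderConfig(**json.loads(f.attrs["config"]))
            metadata = json.loads(f.attrs["metadata"])
            params = {}
            grp = f["params"]

            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    params[name] = nn.parameter(obj[()])
            grp.visititems(visit)
        return cls(config, params), metadata

    def parameter_checksum(self) -> str:
        """Order-independent digest of all parameter tensors."""
        import hashlib
        digest = hashlib.sha256()
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return digest.hexdigest()


def inject_noise(states: np.ndarray, config: EncoderConfig, seed: int) -> np.ndarray:
    """Perturb initial states with element-wise Gaussian noise N(mu, sigma^2).

    ``states`` is an (M, H) array whose last row is the super node, which is
    left unperturbed; sigma is a standard deviation. The same ``seed``
    reproduces the identical perturbation, which is how training and test
    passes can apply "the same" noise.
    """
    if config.noise_sigma < 0:
        raise ConfigurationError("noise sigma must be non-negative")
    m, hidden = states.shape
    noise = np.zeros((m, hidden))
    if config.noise_sigma > 0 or config.noise_mu != 0.0:
        rng = np.random.default_rng(seed)
        noise[: m - 1] = rng.normal(config.noise_mu, config.noise_sigma,
                                    (m - 1, hidden))
    return states + noise


def derive_geometry_from_gram(gram: np.ndarray | GramMatrix,
                              bonds: list[tuple[int, int]],
                              angles: list[tuple[int, int, int]]):
    """Bond lengths and angle cosines computed directly from a (predicted)
    Gram matrix — the head-free supervision pathway.

    Degenerate radicands (possible for noisy predictions) are clamped to zero
    and flagged in the returned mask rather than raising.
    """
    g = gram.values if isinstance(gram, GramMatrix) else np.asarray(gram)
    diag = np.diag(g)
    lengths = np.empty(len(bonds))
    flagged = np.zeros(len(bonds) + len(angles), dtype=bool)
    for idx, (u, v) in enumerate(bonds):
        sq = diag[u] + diag[v] - 2.0 * g[u, v]
        flagged[idx] = sq < 0
        lengths[idx] = np.sqrt(max(sq, 0.0))
    cosines = np.empty(len(angles))
    for idx, (i, j, k) in enumerate(angles):
        num = g[i, k] + g[j, j] - g[i, j] - g[j, k]
        rad = ((diag[i] + diag[j] - 2 * g[i, j])
               * (diag[j] + diag[k] - 2 * g[j, k]))
        if rad <= 0:
            flagged[len(bonds) + idx] = True
            cosines[idx] = 1.0
        else:
            cosines[idx] = np.clip(num / np.sqrt(rad), -1.0, 1.0)
    return lengths, cosines, flagged
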