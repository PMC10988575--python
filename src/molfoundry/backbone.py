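"""Message-passing neural network backbone.

Architecture (all dense layers NumPy float64; ReLU nonlinearities):

  1. per-atom input embedding of the feature matrix,
  2. ``message_steps`` rounds of bond-order-conditioned message passing with a
     shared self/message weight set per round,
  3. a readout transform whose activation is the model's *latent space*: the
     penultimate layer.  The readout weights are applied per-atom to feed the
     geometry output heads during pretraining, and to the pooled (sum or mean)
     atom states to produce the molecule-level latent vector that downstream
     task heads consume — one weight set, two views.
  4. per-atom linear output heads for padded neighbor distances (Å) and
     angles (internally on a [0, 1] scale, reported in degrees).

Messages from a neighbor are linear in the neighbor's state with a weight
matrix selected by the connecting bond's order category, so single, double,
triple and aromatic bonds propagate information differently.  Because message
aggregation is a sum over neighbors and pooling is symmetric, atom states are
permutation-equivariant and the latent is permutation-invariant; chemically
identical atoms receive identical states.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from .geometry import (
    DEFAULT_MAX_ANGLE_PAIRS,
    DEFAULT_MAX_NEIGHBORS,
    GeometryTargetSet,
)
from .graphs import (
    BOND_ORDERS,
    DEFAULT_VOCABULARY,
    MolecularGraph,
    featurize_atoms,
    n_features,
)


@dataclass(frozen=True)
class BackboneConfig:
    hidden_dim: int = 128
    message_steps: int = 3
    readout_dim: int = 256
    aggregation: str = "sum"  # or "mean"
    seed: int = 0
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS
    max_angle_pairs: int = DEFAULT_MAX_ANGLE_PAIRS

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.readout_dim < 1:
            raise ValueError("dimensions must be >= 1")
        if self.message_steps < 0:
            raise ValueError("message_steps must be >= 0")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vocabulary"] = list(self.vocabulary)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        d["vocabulary"] = tuple(d["vocabulary"])
        return cls(**d)


class ConfigError(ValueError):
    pass


@dataclass
class BackboneParams:
    """Named parameter tensors plus a content fingerprint."""

    params: dict[str, np.ndarray]
    config: BackboneConfig

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.config.to_dict(), sort_keys=True).encode())
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    def copy(self) -> "BackboneParams":
        return BackboneParams({k: v.copy() for k, v in self.params.items()}, self.config)


def init_backbone(config: BackboneConfig) -> BackboneParams:
    """He-initialized parameters, deterministic in config.seed."""
    rng = np.random.default_rng(config.seed)
    F = n_features(config.vocabulary)
    H, R = config.hidden_dim, config.readout_dim

    def he(shape):
        return rng.normal(scale=np.sqrt(2.0 / shape[0]), size=shape)

    params = {
        "W_in": he((F, H)),
        "b_in": np.zeros(H),
        "W_self": he((H, H)),
        "b_step": np.zeros(H),
        "W_read": he((H, R)),
        "b_read": np.zeros(R),
        "W_dist": he((R, config.max_neighbors)),
        "b_dist": np.zeros(config.max_neighbors),
        "W_ang": he((R, config.max_angle_pairs)),
        "b_ang": np.zeros(config.max_angle_pairs),
    }
    for c in BOND_ORDERS:
        params[f"W_msg_{c}"] = he((H, H))
    return BackboneParams(params, config)


def _adjacency_by_order(graph: MolecularGraph) -> dict[str, np.ndarray]:
    n = graph.n_atoms
    mats = {c: np.zeros((n, n)) for c in BOND_ORDERS}
    for b in graph.bonds:
        i, j = b.endpoints
        mats[b.order][i, j] = 1.0
        mats[b.order][j, i] = 1.0
    return mats


def _forward(graph: MolecularGraph, params: BackboneParams) -> dict:
    """Full forward pass with cached intermediates for backpropagation."""
    cfg = params.config
    p = params.params
    X = featurize_atoms(graph, cfg.vocabulary).values
    if X.shape[1] != p["W_in"].shape[0]:
        raise ConfigError(
            f"feature width {X.shape[1]} does not match W_in input {p['W_in'].shape[0]}"
        )
    adj = _adjacency_by_order(graph)
    pre0 = X @ p["W_in"] + p["b_in"]
    H_states = [np.maximum(pre0, 0.0)]
    pres = [pre0]
    for _ in range(cfg.message_steps):
        h = H_states[-1]
        msg = np.zeros_like(h)
        for c in BOND_ORDERS:
            a = adj[c]
            if a.any():
                msg += a @ (h @ p[f"W_msg_{c}"])
        pre = h @ p["W_self"] + msg + p["b_step"]
        pres.append(pre)
        H_states.append(np.maximum(pre, 0.0))
    h_final = H_states[-1]
    # per-atom penultimate view (feeds the geometry heads)
    g_pre = h_final @ p["W_read"] + p["b_read"]
    g = np.maximum(g_pre, 0.0)
    dist = g @ p["W_dist"] + p["b_dist"]
    ang = g @ p["W_ang"] + p["b_ang"]  # [0, 1] scale; degrees = 180 * ang
    return {
        "X": X,
        "adj": adj,
        "pres": pres,
        "H_states": H_states,
        "g_pre": g_pre,
        "g": g,
        "dist": dist,
        "ang": ang,
    }


def _backward(
    cache: dict,
    d_dist: np.ndarray,
    d_ang: np.ndarray,
    params: BackboneParams,
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate parameter gradients given output-head gradients."""
    cfg = params.config
    p = params.params
    g, g_pre = cache["g"], cache["g_pre"]
    h_final = cache["H_states"][-1]

    grads["W_dist"] += g.T @ d_dist
    grads["b_dist"] += d_dist.sum(axis=0)
    grads["W_ang"] += g.T @ d_ang
    grads["b_ang"] += d_ang.sum(axis=0)

    d_g = d_dist @ p["W_dist"].T + d_ang @ p["W_ang"].T
    d_g_pre = d_g * (g_pre > 0)
    grads["W_read"] += h_final.T @ d_g_pre
    grads["b_read"] += d_g_pre.sum(axis=0)
    d_h = d_g_pre @ p["W_read"].T

    for t in range(cfg.message_steps, 0, -1):
        d_pre = d_h * (cache["pres"][t] > 0)
        h_prev = cache["H_states"][t - 1]
        grads["b_step"] += d_pre.sum(axis=0)
        grads["W_self"] += h_prev.T @ d_pre
        d_h = d_pre @ p["W_self"].T
        for c in BOND_ORDERS:
            a = cache["adj"][c]
            if a.any():
                back = a @ d_pre  # adjacency is symmetric
                grads[f"W_msg_{c}"] += h_prev.T @ back
                d_h += back @ p[f"W_msg_{c}"].T
    d_pre0 = d_h * (cache["pres"][0] > 0)
    grads["W_in"] += cache["X"].T @ d_pre0
    grads["b_in"] += d_pre0.sum(axis=0)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def encode_atoms(graph: MolecularGraph, params: BackboneParams) -> np.ndarray:
    """Per-atom hidden states after all message-passing rounds (n, hidden)."""
    return _forward(graph, params)["H_states"][-1]


def readout_latent(atom_states: np.ndarray, params: BackboneParams) -> np.ndarray:
    """Molecule-level latent: symmetric pooling then the penultimate transform."""
    if atom_states.ndim != 2 or atom_states.shape[0] == 0:
        raise ValueError("atom_states must be a non-empty (n_atoms, hidden) array")
    cfg = params.config
    pooled = atom_states.sum(axis=0)
    if cfg.aggregation == "mean":
        pooled = pooled / atom_states.shape[0]
    p = params.params
    return np.maximum(pooled @ p["W_read"] + p["b_read"], 0.0)


def latent_vector(graph: MolecularGraph, params: BackboneParams) -> np.ndarray:
    """Convenience: encode a graph and read out its latent vector."""
    return readout_latent(encode_atoms(graph, params), params)


def predict_geometry(graph: MolecularGraph, params: BackboneParams) -> GeometryTargetSet:
    """Predicted padded neighbor distances (Å) and angles (degrees).

    Masks and neighbor order come from the graph's bonded topology, matching
    the layout of targets extracted with the same config widths.
    """
    cfg = params.config
    cache = _forward(graph, params)
    n = graph.n_atoms
    distance_mask = np.zeros((n, cfg.max_neighbors))
    angle_mask = np.zeros((n, cfg.max_angle_pairs))
    neighbor_order = []
    for i in range(n):
        nbrs = graph.neighbors(i)[: cfg.max_neighbors]
        neighbor_order.append(nbrs)
        distance_mask[i, : len(nbrs)] = 1.0
        k = len(nbrs) * (len(nbrs) - 1) // 2
        angle_mask[i, : min(k, cfg.max_angle_pairs)] = 1.0
    return GeometryTargetSet(
        distances=cache["dist"].copy(),
        angles=180.0 * cache["ang"],
        distance_mask=distance_mask,
        angle_mask=angle_mask,
        neighbor_order=neighbor_order,
    )


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params: BackboneParams, path) -> None:
    """Named-tensor archive with embedded config and fingerprint."""
    meta = json.dumps(
        {"config": params.config.to_dict(), "fingerprint": params.fingerprint}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **params.params)


def load_checkpoint(path) -> BackboneParams:
    """Load a checkpoint, verifying the stored fingerprint."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    loaded = BackboneParams(params, BackboneConfig.from_dict(meta["config"]))
    if loaded.fingerprint != meta["fingerprint"]:
        raise ValueError("checkpoint fingerprint mismatch: file corrupted or edited")
    return loaded
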