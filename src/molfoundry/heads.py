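"""Frozen-backbone transfer: shallow task heads.

After pretraining, the geometry output layer is discarded and a new, untrained
feedforward network — two linear layers with one rectifier between — is
stacked on the frozen backbone's latent space.  Only the head trains during
finetuning; the backbone fingerprint must be bit-identical before and after.

Tasks:
  * regression — scalar label per molecule (e.g. log-LD50), L1 loss;
  * multilabel — independent per-class binary labels (e.g. odor classes),
    per-class binary cross-entropy;
  * reaction-yield regression — a reaction is encoded as the concatenation of
    the frozen latents of its components in a fixed role order with zero
    blocks for absent roles, so the head sees role identity; predictions are
    clipped to [0, 100] at inference.

Shipped presets size the head at ~32k parameters for single-molecule tasks
and ~260k / ~1M for the base and enlarged reaction heads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optim import Adam
from .backbone import BackboneParams, latent_vector
from .graphs import parse_smiles

#: Fixed role order for reaction encoding (concatenation layout).
ROLE_ORDER = (
    "nucleophile",
    "electrophile",
    "catalyst",
    "ligand",
    "base",
    "additive",
    "solvent",
)

TASKS = ("regression", "multilabel")


@dataclass(frozen=True)
class HeadSpec:
    """Two linear layers with one nonlinearity between — nothing deeper."""

    task: str
    input_dim: int
    hidden_dim: int
    output_dim: int

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if min(self.input_dim, self.hidden_dim, self.output_dim) < 1:
            raise ValueError("head dimensions must be >= 1")
        if self.task == "regression" and self.output_dim != 1:
            raise ValueError("regression heads have output_dim = 1")


def head_param_count(head_spec: HeadSpec) -> int:
    """Exact parameter count of the 2-layer head (weights + biases)."""
    return (
        head_spec.input_dim * head_spec.hidden_dim
        + head_spec.hidden_dim
        + head_spec.hidden_dim * head_spec.output_dim
        + head_spec.output_dim
    )


#: Presets sized to the published head budgets for a 256-wide latent:
#: ~32k parameters for toxicity and odor heads, ~260k for the base reaction
#: head and ~1M for the enlarged one (7 roles × 256 = 1792 inputs).
HEAD_PRESETS: dict[str, HeadSpec] = {
    "toxicity": HeadSpec("regression", 256, 124, 1),
    "odor": HeadSpec("multilabel", 256, 86, 113),
    "yield_base": HeadSpec("regression", 1792, 145, 1),
    "yield_large": HeadSpec("regression", 1792, 557, 1),
}


@dataclass
class ReactionRecord:
    """One reaction: role → component SMILES, optional yield in [0, 100]%."""

    components: dict[str, str]
    yield_percent: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a reaction needs at least one component")
        unknown = set(self.components) - set(ROLE_ORDER)
        if unknown:
            raise ValueError(f"unknown reaction roles: {sorted(unknown)}")
        if self.yield_percent is not None and not 0 <= self.yield_percent <= 100:
            raise ValueError(f"yield {self.yield_percent} outside [0, 100]")


class CompositeModel:
    """A trainable 2-layer head on a frozen backbone.

    The geometry output heads are not part of the composite: only the latent
    pathway of the backbone is evaluated.
    """

    def __init__(
        self,
        backbone: BackboneParams,
        head_spec: HeadSpec,
        head: dict[str, np.ndarray],
        reaction_roles: tuple[str, ...] | None = None,
    ):
        self.backbone = backbone
        self.head_spec = head_spec
        self.head = head
        self.reaction_roles = reaction_roles
        # input standardization (fit on training features at finetune time);
        # a fixed affine map of frozen features, not a backbone modification
        self.input_loc: np.ndarray | None = None
        self.input_scale: np.ndarray | None = None
        # regression targets are trained on a standardized scale
        self.target_loc: float = 0.0
        self.target_scale: float = 1.0
        self._latent_cache: dict[str, np.ndarray] = {}

    # -- encoding -----------------------------------------------------------

    def _mol_latent(self, molecule) -> np.ndarray:
        if isinstance(molecule, str):
            key = molecule
            if key not in self._latent_cache:
                self._latent_cache[key] = latent_vector(
                    parse_smiles(molecule), self.backbone
                )
            return self._latent_cache[key]
        return latent_vector(molecule, self.backbone)

    def encode(self, item) -> np.ndarray:
        """Frozen-backbone features: molecule latent or reaction concatenation."""
        if isinstance(item, ReactionRecord):
            return encode_reaction(item, self)
        return self._mol_latent(item)

    # -- head forward -------------------------------------------------------

    def _standardize(self, Z: np.ndarray) -> np.ndarray:
        if self.input_loc is None:
            return Z
        return (Z - self.input_loc) / self.input_scale

    def _head_forward(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pre = Z @ self.head["W1"] + self.head["b1"]
        hidden = np.maximum(pre, 0.0)
        out = hidden @ self.head["W2"] + self.head["b2"]
        return out, pre

    def predict(self, items) -> np.ndarray:
        """Scalar predictions (regression) or per-class probabilities (multilabel)."""
        Z = self._standardize(np.stack([self.encode(it) for it in items]))
        out, _ = self._head_forward(Z)
        if self.head_spec.task == "multilabel":
            return 1.0 / (1.0 + np.exp(-out))
        out = out[:, 0] * self.target_scale + self.target_loc
        if self.reaction_roles is not None:
            out = np.clip(out, 0.0, 100.0)  # yields are percentages
        return out

    def head_fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.head):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.head[k]).tobytes())
        return h.hexdigest()


def strip_and_attach(
    backbone: BackboneParams,
    head_spec: HeadSpec,
    seed: int,
    reaction_roles: tuple[str, ...] | None = None,
) -> CompositeModel:
    """Replace the geometry output layer with a freshly initialized head.

    The backbone is carried frozen; ``head_spec.input_dim`` must equal the
    backbone readout width (or role count × readout width for reactions).
    """
    expected = backbone.config.readout_dim
    if reaction_roles is not None:
        expected = len(reaction_roles) * backbone.config.readout_dim
    if head_spec.input_dim != expected:
        raise ValueError(
            f"head input_dim {head_spec.input_dim} does not match frozen "
            f"feature width {expected}"
        )
    rng = np.random.default_rng(seed)
    head = {
        "W1": rng.normal(
            scale=np.sqrt(2.0 / head_spec.input_dim),
            size=(head_spec.input_dim, head_spec.hidden_dim),
        ),
        "b1": np.zeros(head_spec.hidden_dim),
        "W2": rng.normal(
            scale=np.sqrt(2.0 / head_spec.hidden_dim),
            size=(head_spec.hidden_dim, head_spec.output_dim),
        ),
        "b2": np.zeros(head_spec.output_dim),
    }
    return CompositeModel(backbone, head_spec, head, reaction_roles)


def encode_reaction(record: ReactionRecord, composite: CompositeModel) -> np.ndarray:
    """Concatenated frozen latents in fixed role order; zeros for absent roles."""
    roles = composite.reaction_roles or ROLE_ORDER
    R = composite.backbone.config.readout_dim
    blocks = []
    for role in roles:
        smi = record.components.get(role)
        if smi is None:
            blocks.append(np.zeros(R))
            continue
        try:
            blocks.append(composite._mol_latent(smi))
        except Exception as exc:
            raise ValueError(f"unparseable component in role {role!r}: {smi!r}") from exc
    return np.concatenate(blocks)


def finetune(
    composite: CompositeModel,
    inputs,
    targets: np.ndarray,
    epochs: int = 200,
    learning_rate: float = 1e-3,
    seed: int = 0,
    batch_size: int = 64,
) -> tuple[CompositeModel, list[float]]:
    """Train only the head; the backbone never receives a gradient.

    Regression uses mean-absolute-error loss; multilabel uses independent
    per-class binary cross-entropy on sigmoid outputs.  Frozen features are
    computed once up front, which is exactly what freezing permits.
    """
    targets = np.asarray(targets, dtype=float)
    spec = composite.head_spec
    if spec.task == "regression":
        if targets.ndim != 1:
            raise ValueError("regression targets must be a 1-D array of scalars")
        composite.target_loc = float(targets.mean())
        composite.target_scale = max(float(targets.std()), 1e-8)
        Y = ((targets - composite.target_loc) / composite.target_scale)[:, None]
    else:
        if targets.ndim != 2 or targets.shape[1] != spec.output_dim:
            raise ValueError(
                f"multilabel targets must be (n, {spec.output_dim}) binary matrix"
            )
        Y = targets
    Z = np.stack([composite.encode(it) for it in inputs])
    if Z.shape[0] != Y.shape[0]:
        raise ValueError("inputs and targets disagree in length")
    # standardize frozen features on the training set for stable head training;
    # the floor is relative to the overall spread so features that are constant
    # in training cannot blow up on out-of-distribution inputs
    std = Z.std(axis=0)
    composite.input_loc = Z.mean(axis=0)
    composite.input_scale = np.maximum(std, 1e-3 * max(float(std.max()), 1.0))
    Z = composite._standardize(Z)

    rng = np.random.default_rng(seed)
    opt = Adam(composite.head.keys(), learning_rate)
    trace: list[float] = []
    n = Z.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            z, y = Z[idx], Y[idx]
            out, pre = composite._head_forward(z)
            if spec.task == "regression":
                resid = out - y
                # traced in original label units
                loss = float(np.mean(np.abs(resid))) * composite.target_scale
                d_out = np.sign(resid) / resid.size
            else:
                p = 1.0 / (1.0 + np.exp(-out))
                eps = 1e-12
                loss = float(
                    -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
                )
                d_out = (p - y) / y.size
            hidden = np.maximum(pre, 0.0)
            grads = {
                "W2": hidden.T @ d_out,
                "b2": d_out.sum(axis=0),
            }
            d_hidden = (d_out @ composite.head["W2"].T) * (pre > 0)
            grads["W1"] = z.T @ d_hidden
            grads["b1"] = d_hidden.sum(axis=0)
            if learning_rate > 0:
                opt.step(composite.head, grads)
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    return composite, trace


def save_composite(composite: CompositeModel, path, class_names: list[str] | None = None) -> None:
    """Head checkpoint: weights, scalings, spec, and backbone fingerprint."""
    import json

    meta = {
        "head_spec": composite.head_spec.__dict__,
        "reaction_roles": list(composite.reaction_roles) if composite.reaction_roles else None,
        "target_loc": composite.target_loc,
        "target_scale": composite.target_scale,
        "backbone_fingerprint": composite.backbone.fingerprint,
        "class_names": class_names,
    }
    arrays = dict(composite.head)
    if composite.input_loc is not None:
        arrays["input_loc"] = composite.input_loc
        arrays["input_scale"] = composite.input_scale
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **arrays,
    )


def load_composite(path, backbone: BackboneParams) -> tuple[CompositeModel, list[str] | None]:
    """Rebuild a composite from a head checkpoint and its (frozen) backbone."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    if backbone.fingerprint != meta["backbone_fingerprint"]:
        raise ValueError("head was trained on a different backbone (fingerprint mismatch)")
    spec = HeadSpec(**meta["head_spec"])
    head = {k: arrays[k] for k in ("W1", "b1", "W2", "b2")}
    roles = tuple(meta["reaction_roles"]) if meta["reaction_roles"] else None
    composite = CompositeModel(backbone, spec, head, roles)
    if "input_loc" in arrays:
        composite.input_loc = arrays["input_loc"]
        composite.input_scale = arrays["input_scale"]
    composite.target_loc = meta["target_loc"]
    composite.target_scale = meta["target_scale"]
    return composite, meta.get("class_names")


def predict_topk(composite: CompositeModel, molecule, k: int) -> list[int]:
    """Indices of the k highest-probability labels, ties broken by label index."""
    if composite.head_spec.task != "multilabel":
        raise ValueError("top-k prediction requires a multilabel head")
    if k < 1 or k > composite.head_spec.output_dim:
        raise ValueError(
            f"k must be in 1..{composite.head_spec.output_dim}, got {k}"
        )
    probs = composite.predict([molecule])[0]
    order = np.argsort(-probs, kind="stable")  # stable: equal probs -> low index first
    return [int(i) for i in order[:k]]
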