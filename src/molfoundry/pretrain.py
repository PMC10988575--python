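"""Pretraining the backbone on geometry targets.

The loss is a masked L1 (mean-absolute-error) over the padded per-atom
targets: distances contribute in Å, angles on a [0, 1] scale (degrees / 180)
so the two quantities are comparable; ``angle_weight`` balances them.  Only
masked-in entries contribute, with the mean taken over all masked-in entries
of the batch per quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._optim import Adam
from .backbone import BackboneConfig, BackboneParams, _backward, _forward, init_backbone
from .geometry import GeometryTargetSet, extract_targets


@dataclass
class PretrainReport:
    loss_trace: list[float]
    train_distance_mae: float
    train_angle_mae: float
    test_distance_mae: float | None
    test_angle_mae: float | None
    config: dict
    seed: int
    epochs_run: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=float)


def geometry_loss(
    predicted: GeometryTargetSet, target: GeometryTargetSet, angle_weight: float = 1.0
) -> float:
    """Masked L1: mean |Δdistance| (Å) + angle_weight · mean |Δangle| / 180."""
    if (
        predicted.distances.shape != target.distances.shape
        or predicted.angles.shape != target.angles.shape
    ):
        raise ValueError("predicted and target layouts differ")
    if not np.array_equal(predicted.distance_mask, target.distance_mask) or not np.array_equal(
        predicted.angle_mask, target.angle_mask
    ):
        raise ValueError("predicted and target masks differ")
    dm = target.distance_mask > 0
    am = target.angle_mask > 0
    if not dm.any() and not am.any():
        raise ValueError("no masked-in entries to score")
    loss = 0.0
    if dm.any():
        loss += float(np.mean(np.abs(predicted.distances[dm] - target.distances[dm])))
    if am.any():
        loss += angle_weight * float(
            np.mean(np.abs(predicted.angles[am] - target.angles[am]) / 180.0)
        )
    return loss


def _prepare(structures, config: BackboneConfig):
    """Extract targets once per structure."""
    out = []
    for graph, coords in structures:
        tgt = extract_targets(
            graph,
            coords,
            neighbor_mode="bonded",
            max_neighbors=config.max_neighbors,
            max_angle_pairs=config.max_angle_pairs,
        )
        out.append((graph, tgt))
    return out


def _batch_loss_and_grads(
    batch, params: BackboneParams, angle_weight: float, grads=None
):
    """Masked L1 over a batch; accumulates grads in-place when provided.

    The per-quantity means are taken over all masked-in entries of the batch,
    so gradients are normalized by the batch-wide mask counts.
    """
    caches = []
    nd = na = 0
    for graph, tgt in batch:
        cache = _forward(graph, params)
        caches.append((cache, tgt))
        nd += int(tgt.distance_mask.sum())
        na += int(tgt.angle_mask.sum())
    if nd == 0 and na == 0:
        raise ValueError("no masked-in entries to score")
    loss = 0.0
    for cache, tgt in caches:
        dmask = tgt.distance_mask
        amask = tgt.angle_mask
        resid_d = (cache["dist"] - tgt.distances) * dmask
        resid_a = (cache["ang"] - tgt.angles / 180.0) * amask
        if nd:
            loss += float(np.abs(resid_d).sum()) / nd
        if na:
            loss += angle_weight * float(np.abs(resid_a).sum()) / na
        if grads is not None:
            d_dist = np.sign(resid_d) / nd if nd else np.zeros_like(resid_d)
            d_ang = (
                angle_weight * np.sign(resid_a) / na if na else np.zeros_like(resid_a)
            )
            _backward(cache, d_dist, d_ang, params, grads)
    return loss


def train_foundational(
    structures,
    config: BackboneConfig,
    epochs: int = 200,
    learning_rate: float = 1e-3,
    seed: int = 0,
    angle_weight: float = 1.0,
    batch_size: int = 16,
    holdout=None,
    patience: int | None = None,
) -> tuple[BackboneParams, PretrainReport]:
    """Optimize the masked-L1 geometry loss with Adam.

    ``structures`` is a list of (graph, coordinates) pairs that have already
    been curated and (if desired) scaffold-split; ``holdout`` is an optional
    second list used for early stopping (stop when its loss has not improved
    for ``patience`` epochs) and for the test MAEs in the report.
    Deterministic given the seed.
    """
    cfg = BackboneConfig(**{**config.to_dict(), "seed": seed})
    params = init_backbone(cfg)
    data = _prepare(structures, cfg)
    held = _prepare(holdout, cfg) if holdout else None
    rng = np.random.default_rng(seed)
    opt = Adam(params.params.keys(), learning_rate)
    trace: list[float] = []
    best_held = np.inf
    stale = 0
    epochs_run = 0
    for _ in range(epochs):
        order = rng.permutation(len(data))
        epoch_loss = 0.0
        for start in range(0, len(data), batch_size):
            batch = [data[i] for i in order[start : start + batch_size]]
            grads = {k: np.zeros_like(v) for k, v in params.params.items()}
            loss = _batch_loss_and_grads(batch, params, angle_weight, grads)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite pretraining loss at epoch {epochs_run}: {loss}"
                )
            if learning_rate > 0:
                opt.step(params.params, grads)
            epoch_loss += loss * len(batch)
        trace.append(epoch_loss / len(data))
        epochs_run += 1
        if held and patience is not None:
            hl = _batch_loss_and_grads(held, params, angle_weight)
            if hl < best_held - 1e-12:
                best_held, stale = hl, 0
            else:
                stale += 1
                if stale >= patience:
                    break

    train_d, train_a = evaluate_geometry(params, structures)
    test_d = test_a = None
    if holdout:
        test_d, test_a = evaluate_geometry(params, holdout)
    report = PretrainReport(
        loss_trace=trace,
        train_distance_mae=train_d,
        train_angle_mae=train_a,
        test_distance_mae=test_d,
        test_angle_mae=test_a,
        config=cfg.to_dict(),
        seed=seed,
        epochs_run=epochs_run,
    )
    return params, report


def evaluate_geometry(params: BackboneParams, structures) -> tuple[float, float]:
    """Masked MAEs of predicted vs true targets: (distance Å, angle degrees)."""
    if not structures:
        raise ValueError("no structures to evaluate")
    cfg = params.config
    abs_d, abs_a = [], []
    for graph, tgt in _prepare(structures, cfg):
        cache = _forward(graph, params)
        dm = tgt.distance_mask > 0
        am = tgt.angle_mask > 0
        if dm.any():
            abs_d.append(np.abs(cache["dist"][dm] - tgt.distances[dm]))
        if am.any():
            abs_a.append(np.abs(180.0 * cache["ang"][am] - tgt.angles[am]))
    dist_mae = float(np.mean(np.concatenate(abs_d))) if abs_d else 0.0
    angle_mae = float(np.mean(np.concatenate(abs_a))) if abs_a else 0.0
    return dist_mae, angle_mae
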