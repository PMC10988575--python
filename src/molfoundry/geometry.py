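"""Rotation/translation-invariant geometry targets.

3D coordinates are never predicted directly — a molecule rotated through space
has different coordinates but identical geometry.  Instead each atom is
described by the through-space distances to its neighbors and the angles those
neighbors form at the atom, both of which are invariant under any rigid motion
(and, being unsigned, under reflection).  These per-atom vectors, padded and
masked to a fixed width, are the pretraining labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .graphs import MolecularGraph

DEFAULT_MAX_NEIGHBORS = 4
#: C(4, 2): all angle pairs for a standard tetravalent center.
DEFAULT_MAX_ANGLE_PAIRS = 6

_DEGENERATE_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Two atoms occupy (numerically) the same position."""


@dataclass
class GeometryTargetSet:
    """Per-atom padded neighbor distances (Å) and angles (degrees) with masks."""

    distances: np.ndarray      # (n_atoms, max_neighbors)
    angles: np.ndarray         # (n_atoms, max_angle_pairs), degrees in [0, 180]
    distance_mask: np.ndarray  # binary, same shape as distances
    angle_mask: np.ndarray     # binary, same shape as angles
    neighbor_order: list[list[int]]

    @property
    def max_neighbors(self) -> int:
        return self.distances.shape[1]

    @property
    def max_angle_pairs(self) -> int:
        return self.angles.shape[1]

    def validate(self) -> None:
        if np.any(self.distances[self.distance_mask > 0] <= 0):
            raise ValueError("masked-in distances must be positive")
        masked_angles = self.angles[self.angle_mask > 0]
        if np.any((masked_angles < 0) | (masked_angles > 180)):
            raise ValueError("masked-in angles must lie in [0, 180] degrees")


def _neighbor_lists(
    graph: MolecularGraph,
    coords: np.ndarray,
    neighbor_mode: str,
    max_neighbors: int,
) -> list[list[int]]:
    if neighbor_mode == "bonded":
        # canonical order = ascending canonical atom index; overflow dropped by rank
        return [graph.neighbors(i)[:max_neighbors] for i in range(graph.n_atoms)]
    if neighbor_mode == "spatial_knn":
        diffs = coords[:, None, :] - coords[None, :, :]
        dmat = np.linalg.norm(diffs, axis=-1)
        np.fill_diagonal(dmat, np.inf)
        out = []
        for i in range(graph.n_atoms):
            k = min(max_neighbors, graph.n_atoms - 1)
            # stable sort keeps canonical-index order among equidistant atoms
            idx = np.argsort(dmat[i], kind="stable")[:k]
            out.append([int(j) for j in idx])
        return out
    raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")


def extract_targets(
    graph: MolecularGraph,
    coords: np.ndarray,
    neighbor_mode: str = "bonded",
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    max_angle_pairs: int | None = None,
) -> GeometryTargetSet:
    """Compute per-atom neighbor distances and neighbor-pair angles.

    Neighbors default to bonded (1-hop) atoms in canonical index order, so the
    angles are the bond angles formed at each atom; ``spatial_knn`` instead
    takes the spatially nearest atoms.  Each atom contributes C(k, 2) angles
    for its k kept neighbors, capped at ``max_angle_pairs``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (graph.n_atoms, 3):
        raise ValueError(
            f"coordinates shape {coords.shape} does not match {graph.n_atoms} atoms"
        )
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if max_neighbors < 1:
        raise ValueError("max_neighbors must be >= 1")
    if max_angle_pairs is None:
        max_angle_pairs = max_neighbors * (max_neighbors - 1) // 2

    n = graph.n_atoms
    neighbor_order = _neighbor_lists(graph, coords, neighbor_mode, max_neighbors)
    distances = np.zeros((n, max_neighbors))
    angles = np.zeros((n, max_angle_pairs))
    distance_mask = np.zeros((n, max_neighbors))
    angle_mask = np.zeros((n, max_angle_pairs))

    for i in range(n):
        nbrs = neighbor_order[i]
        vecs = {}
        for slot, j in enumerate(nbrs):
            v = coords[j] - coords[i]
            d = float(np.linalg.norm(v))
            if d < _DEGENERATE_TOL:
                raise DegenerateGeometryError(
                    f"atoms {i} and {j} are at identical positions"
                )
            distances[i, slot] = d
            distance_mask[i, slot] = 1.0
            vecs[j] = v / d
        for slot, (a, b) in enumerate(itertools.combinations(nbrs, 2)):
            if slot >= max_angle_pairs:
                break
            # atan2 form is well-conditioned even for collinear neighbors
            u, v = vecs[a], vecs[b]
            angles[i, slot] = np.degrees(
                np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))
            )
            angle_mask[i, slot] = 1.0

    return GeometryTargetSet(distances, angles, distance_mask, angle_mask, neighbor_order)


def targets_invariance_check(
    graph: MolecularGraph,
    coords: np.ndarray,
    n_transforms: int,
    seed: int,
    neighbor_mode: str = "bonded",
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
) -> float:
    """Max element-wise target deviation under random rigid transforms.

    Applies ``n_transforms`` random rotation+translation pairs to the
    coordinates and returns the largest absolute deviation of any masked-in
    distance or angle from the untransformed targets (0.0 for n_transforms=0).
    """
    if n_transforms < 0:
        raise ValueError("n_transforms must be >= 0")
    coords = np.asarray(coords, dtype=float)
    ref = extract_targets(graph, coords, neighbor_mode, max_neighbors)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_transforms):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=10.0, size=3)
        moved = coords @ rot.T + shift
        got = extract_targets(graph, moved, neighbor_mode, max_neighbors)
        worst = max(worst, target_deviation(ref, got))
    return worst


def target_deviation(a: GeometryTargetSet, b: GeometryTargetSet) -> float:
    """Largest absolute difference over masked-in entries of two target sets."""
    if a.distances.shape != b.distances.shape or a.angles.shape != b.angles.shape:
        raise ValueError("target sets have different layouts")
    dev = 0.0
    dm = (a.distance_mask > 0) & (b.distance_mask > 0)
    am = (a.angle_mask > 0) & (b.angle_mask > 0)
    if dm.any():
        dev = max(dev, float(np.max(np.abs(a.distances[dm] - b.distances[dm]))))
    if am.any():
        dev = max(dev, float(np.max(np.abs(a.angles[am] - b.angles[am]))))
    return dev


def targets_to_table(molecule_id: str, targets: GeometryTargetSet):
    """Flatten a target set to one row per atom for columnar inspection."""
    import pandas as pd

    rows = []
    for i in range(targets.distances.shape[0]):
        row: dict = {"molecule_id": molecule_id, "atom_index": i}
        for k in range(targets.max_neighbors):
            row[f"dist_{k}"] = targets.distances[i, k]
            row[f"dist_mask_{k}"] = int(targets.distance_mask[i, k])
        for k in range(targets.max_angle_pairs):
            row[f"angle_{k}"] = targets.angles[i, k]
            row[f"angle_mask_{k}"] = int(targets.angle_mask[i, k])
        rows.append(row)
    return pd.DataFrame(rows)
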