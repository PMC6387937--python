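"""Pairwise similarity of halogen-interface feature trees.

A configuration pair is scored as a weighted sum of three components:

* the core rings (size agreement and atom-type multiset overlap),
* the halogen nodes (element agreement and V_max closeness), and
* the residues, via an exact optimal assignment between the positional
  slots of the two trees in which matched residues are compared by their
  node-property vectors and penalized by ``gamma^|offset shift|``, and
  unmatched heavy residues fall to a configurable floor.

Molecule-level similarity is the maximum over all configuration pairs,
and distances are 1 - similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chemio import MoleculeRecord
from .config import SimilarityParams
from .descriptors import HYDROGEN_VECTOR, NodePropertyVector
from .featuretree import FeatureTree, build_feature_tree, enumerate_configurations


def node_similarity(
    a: NodePropertyVector | np.ndarray,
    b: NodePropertyVector | np.ndarray,
    weights: Sequence[float] = SimilarityParams().node_property_weights,
) -> float:
    """Weighted component-ratio similarity of two property vectors.

    Each component contributes min/max of the two values (1 when both are
    zero); components are combined with the given simplex weights.
    Symmetric by construction; negative properties are rejected.
    """
    va = a.as_array() if isinstance(a, NodePropertyVector) else np.asarray(a, dtype=float)
    vb = b.as_array() if isinstance(b, NodePropertyVector) else np.asarray(b, dtype=float)
    if (va < 0).any() or (vb < 0).any():
        raise ValueError("node properties must be non-negative")
    hi = np.maximum(va, vb)
    lo = np.minimum(va, vb)
    ratios = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 1.0)
    return float(np.dot(np.asarray(weights, dtype=float), ratios))


# Slot kind codes used in the vectorized pair-score matrix.
_KIND_H, _KIND_RES, _KIND_EMPTY = 0, 1, 2
_H_ARRAY = HYDROGEN_VECTOR.as_array()


def _slot_arrays(tree: FeatureTree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    kinds = np.array(
        [{"H": _KIND_H, "residue": _KIND_RES, "empty": _KIND_EMPTY}[s.kind] for s in tree.slots],
        dtype=int,
    )
    offsets = np.array([s.offset for s in tree.slots], dtype=float)
    vecs = np.array(
        [s.properties.as_array() if s.kind == "residue" else _H_ARRAY for s in tree.slots]
    )
    return kinds, offsets, vecs


def _pair_scores(ta: FeatureTree, tb: FeatureTree, params: SimilarityParams) -> np.ndarray:
    """Square score matrix over the two trees' slots, the shorter side
    padded with empty slots.  Scores:

    * matched slots with property vectors: node_similarity * gamma^|shift|
      (a single-hydrogen residue carries the hydrogen vector);
    * hydrogen or empty slot vs an empty/padding slot: 1;
    * heavy residue vs an empty/padding slot: the empty-match floor.
    """
    ka, oa, va = _slot_arrays(ta)
    kb, ob, vb = _slot_arrays(tb)
    na, nb = len(ka), len(kb)
    n = max(na, nb)
    w = np.asarray(params.node_property_weights)

    hi = np.maximum(va[:, None, :], vb[None, :, :])
    lo = np.minimum(va[:, None, :], vb[None, :, :])
    ratios = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 1.0)
    sim = ratios @ w
    shift = params.shift_decay ** np.abs(oa[:, None] - ob[None, :])
    scores = sim * shift

    # Empty-slot rules override the vector comparison.
    a_empty = ka == _KIND_EMPTY
    b_empty = kb == _KIND_EMPTY
    a_res = ka == _KIND_RES
    b_res = kb == _KIND_RES
    scores[a_empty[:, None] & b_res[None, :]] = params.empty_match_floor
    scores[a_res[:, None] & b_empty[None, :]] = params.empty_match_floor
    scores[a_empty[:, None] & ~b_res[None, :]] = 1.0
    scores[(~a_res[:, None]) & b_empty[None, :]] = 1.0

    full = np.zeros((n, n))
    full[:na, :nb] = scores
    # Padding columns/rows behave as empty slots.
    if na < n:
        full[na:, :nb] = np.where(b_res[None, :], params.empty_match_floor, 1.0)
    if nb < n:
        full[:na, nb:] = np.where(a_res[:, None], params.empty_match_floor, 1.0)
    return full


def _core_similarity(ta: FeatureTree, tb: FeatureTree, params: SimilarityParams) -> float:
    counts_a = dict(ta.core_elements)
    counts_b = dict(tb.core_elements)
    elements = set(counts_a) | set(counts_b)
    inter = sum(min(counts_a.get(e, 0), counts_b.get(e, 0)) for e in elements)
    union = sum(max(counts_a.get(e, 0), counts_b.get(e, 0)) for e in elements)
    overlap = inter / union if union else 1.0
    if ta.ring_size != tb.ring_size:
        overlap *= params.ring_size_mismatch_factor
    return overlap


def _halogen_similarity(ta: FeatureTree, tb: FeatureTree, params: SimilarityParams) -> float:
    element_term = (
        1.0 if ta.config.element == tb.config.element else params.element_mismatch_factor
    )
    va, vb = ta.vmax, tb.vmax
    if va is None or vb is None:
        return element_term  # V_max flagged missing: element agreement only
    if va.surface != vb.surface:
        raise ValueError(
            f"mixed V_max surface tags ({va.surface} vs {vb.surface}) for "
            f"{ta.config.molecule_id} / {tb.config.molecule_id}"
        )
    return element_term * math.exp(-abs(va.value - vb.value) / params.vmax_tau)


def compare_configurations(
    ta: FeatureTree, tb: FeatureTree, params: SimilarityParams = SimilarityParams()
) -> float:
    """Similarity in [0, 1] of two halogen configurations.

    The residue component solves the slot assignment exactly (Hungarian
    algorithm over the padded score matrix) and normalizes by the larger
    slot count; the optimal value is invariant under argument order, so
    the measure is symmetric.
    """
    w_core, w_hal, w_res = params.component_weights
    scores = _pair_scores(ta, tb, params)
    rows, cols = linear_sum_assignment(scores, maximize=True)
    sim_res = float(scores[rows, cols].sum()) / scores.shape[0]
    return (
        w_core * _core_similarity(ta, tb, params)
        + w_hal * _halogen_similarity(ta, tb, params)
        + w_res * sim_res
    )


def molecule_trees(
    record: MoleculeRecord,
    vmax_provider: Callable | None = None,
) -> list[FeatureTree]:
    """All configuration trees of one molecule."""
    return [
        build_feature_tree(record, cfg, vmax_provider)
        for cfg in enumerate_configurations(record)
    ]


def molecule_similarity(
    m1: MoleculeRecord,
    m2: MoleculeRecord,
    params: SimilarityParams = SimilarityParams(),
    vmax_provider: Callable | None = None,
    trees1: list[FeatureTree] | None = None,
    trees2: list[FeatureTree] | None = None,
) -> float:
    """Maximum configuration-pair similarity between two molecules.

    The most similar pair of halogen interfaces dominates: two molecules
    sharing one near-identical interface are treated as similar however
    different their remaining configurations are.
    """
    trees1 = trees1 if trees1 is not None else molecule_trees(m1, vmax_provider)
    trees2 = trees2 if trees2 is not None else molecule_trees(m2, vmax_provider)
    if not trees1:
        raise ValueError(f"{m1.id}: no aromatic halogen configuration")
    if not trees2:
        raise ValueError(f"{m2.id}: no aromatic halogen configuration")
    return max(
        compare_configurations(ta, tb, params) for ta in trees1 for tb in trees2
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix D = 1 - similarity over molecules."""

    ids: tuple[str, ...]
    values: np.ndarray
    param_hash: str = ""

    def __post_init__(self):
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id count")

    def index(self, mol_id: str) -> int:
        return self.ids.index(mol_id)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# param_hash={self.param_hash}\n")
            fh.write("," + ",".join(self.ids) + "\n")
            for i, mol_id in enumerate(self.ids):
                row = ",".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{mol_id},{row}\n")

    def to_lower_triangle(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# param_hash={self.param_hash}\n")
            for i, mol_id in enumerate(self.ids):
                vals = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{mol_id} {vals}".rstrip() + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        param_hash = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                param_hash = first.strip().split("param_hash=")[-1]
                header = fh.readline()
            else:
                header = first
            ids = tuple(header.strip().split(",")[1:])
            values = np.array(
                [[float(x) for x in line.strip().split(",")[1:]] for line in fh]
            )
        return cls(ids=ids, values=values, param_hash=param_hash)


def distance_matrix(
    records: Sequence[MoleculeRecord],
    params: SimilarityParams = SimilarityParams(),
    vmax_provider: Callable | None = None,
) -> DistanceMatrix:
    """Pairwise distance matrix over molecules that passed the structural
    filter (each must expose at least one configuration)."""
    trees = [molecule_trees(rec, vmax_provider) for rec in records]
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                sim = molecule_similarity(
                    records[i], records[j], params, trees1=trees[i], trees2=trees[j]
                )
            except ValueError as exc:
                raise ValueError(
                    f"cannot compare {records[i].id} and {records[j].id}: {exc}"
                ) from exc
            values[i, j] = values[j, i] = 1.0 - sim
    return DistanceMatrix(
        ids=tuple(r.id for r in records), values=values, param_hash=params.param_hash()
    )
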