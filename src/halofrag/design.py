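"""Library design: filtering, consensus solubility voting, MaxMin core
selection, satellite augmentation and final assembly.

The filters mirror a fragment-vendor triage: structural (at least one
aromatic Cl/Br/I, at most 20 heavy atoms), reactive-substructure SMARTS,
and an inclusive price cap of $5/mg.  Solubility is decided by a consensus
vote over several logS predictors: at least three must predict logS better
than -2 for fragments below 16 heavy atoms, or better than -1 for
fragments of 16 to 22 heavy atoms.  Diversity selection is greedy MaxMin
over the halogen-interface distance matrix; each core member is augmented
with its most similar satellite compounds, and a deterministic ranking by
solubility and price stands in for the manual expert sub-selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import MoleculeRecord
from .config import DEFAULT_SMARTS_FILTERS
from .featuretree import enumerate_configurations
from .similarity import DistanceMatrix


@dataclass(frozen=True)
class FilterDecision:
    molecule_id: str
    kept: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.kept and not self.reasons:
            raise ValueError("a removed molecule needs at least one reason")
        if self.kept and self.reasons:
            raise ValueError("a kept molecule must have no removal reasons")


@dataclass
class FilterReport:
    """Per-molecule keep/remove decisions with tagged rule ids."""

    decisions: dict[str, FilterDecision] = field(default_factory=dict)

    def add(self, molecule_id: str, reasons: Iterable[str]) -> None:
        reasons = tuple(reasons)
        self.decisions[molecule_id] = FilterDecision(molecule_id, kept=not reasons, reasons=reasons)

    def kept_ids(self) -> list[str]:
        return [d.molecule_id for d in self.decisions.values() if d.kept]

    def removed_ids(self) -> list[str]:
        return [d.molecule_id for d in self.decisions.values() if not d.kept]

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Combine two reports over the same molecules (union of reasons)."""
        merged = FilterReport()
        for mol_id, dec in self.decisions.items():
            reasons = list(dec.reasons)
            if mol_id in other.decisions:
                for r in other.decisions[mol_id].reasons:
                    if r not in reasons:
                        reasons.append(r)
            merged.add(mol_id, reasons)
        return merged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": list(self.decisions),
                "decision": ["kept" if d.kept else "removed" for d in self.decisions.values()],
                "reasons": [";".join(d.reasons) for d in self.decisions.values()],
            }
        )


def structural_filter(records: Sequence[MoleculeRecord], hac_limit: int = 20) -> FilterReport:
    """Remove molecules without an aromatic halogen configuration or with
    more than ``hac_limit`` heavy atoms (both reasons recorded if both)."""
    report = FilterReport()
    for rec in records:
        reasons = []
        if not enumerate_configurations(rec):
            reasons.append("no_aromatic_halogen")
        if rec.mol.GetNumHeavyAtoms() > hac_limit:
            reasons.append("hac_gt_20")
        report.add(rec.id, reasons)
    return report


def compile_smarts(patterns: Mapping[str, str] | None = None) -> dict[str, Chem.Mol]:
    patterns = patterns if patterns is not None else DEFAULT_SMARTS_FILTERS
    compiled = {}
    for pat_id, smarts in patterns.items():
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"invalid SMARTS for pattern {pat_id!r}: {smarts!r}")
        compiled[pat_id] = query
    return compiled


def smarts_filter(
    records: Sequence[MoleculeRecord], patterns: Mapping[str, str] | None = None
) -> FilterReport:
    """Remove molecules matching any unwanted-substructure pattern."""
    compiled = compile_smarts(patterns)
    report = FilterReport()
    for rec in records:
        reasons = [
            f"smarts:{pat_id}"
            for pat_id, query in compiled.items()
            if rec.mol.HasSubstructMatch(query)
        ]
        report.add(rec.id, reasons)
    return report


def price_filter(
    records: Sequence[MoleculeRecord],
    prices: Mapping[str, float],
    limit: float = 5.0,
    missing_policy: str = "remove",
) -> FilterReport:
    """Remove molecules above the price limit ($/mg, limit inclusive).

    Molecules without a price entry are removed (reason ``price_missing``)
    unless ``missing_policy="keep"``.
    """
    report = FilterReport()
    for rec in records:
        price = prices.get(rec.id)
        if price is None:
            report.add(rec.id, ["price_missing"] if missing_policy == "remove" else [])
            continue
        price = float(price)
        if not np.isfinite(price):
            raise ValueError(f"non-numeric price for {rec.id!r}")
        report.add(rec.id, ["price_gt_limit"] if price > limit else [])
    return report


def load_price_table(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, dtype={"molecule_id": str})
    id_col = "molecule_id" if "molecule_id" in frame.columns else "id"
    price_col = "price_per_mg" if "price_per_mg" in frame.columns else "price"
    if id_col not in frame.columns or price_col not in frame.columns:
        raise ValueError(f"{path}: price table needs molecule_id/id and price_per_mg/price columns")
    out = {}
    for row in frame.itertuples(index=False):
        raw = getattr(row, price_col)
        try:
            out[str(getattr(row, id_col))] = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric price {raw!r} for {getattr(row, id_col)!r}") from None
    return out


class PredictionTable:
    """Per-molecule logS predictions, one column per predictor."""

    def __init__(self, predictions: dict[str, dict[str, float]]):
        self.predictions = predictions
        counts = {len(v) for v in predictions.values()}
        self.n_predictors = max(counts) if counts else 0
        if self.n_predictors and self.n_predictors < 6:
            warnings.warn(
                f"only {self.n_predictors} solubility predictors supplied "
                "(the consensus scheme was designed for 6); votes_required is unchanged",
                stacklevel=2,
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictionTable":
        frame = pd.read_csv(path, dtype={"molecule_id": str})
        id_col = "molecule_id" if "molecule_id" in frame.columns else "id"
        predictors = [c for c in frame.columns if c != id_col]
        preds = {}
        for row in frame.itertuples(index=False):
            values = {p: float(getattr(row, p)) for p in predictors}
            if any(not np.isfinite(v) for v in values.values()):
                raise ValueError(f"non-finite logS prediction for {getattr(row, id_col)!r}")
            preds[str(getattr(row, id_col))] = values
        return cls(preds)

    def values_for(self, molecule_id: str) -> list[float]:
        return list(self.predictions[molecule_id].values())

    def consensus_logs(self, molecule_id: str) -> float:
        """Median predicted logS, used for ranking at assembly."""
        return float(np.median(self.values_for(molecule_id)))


def solubility_vote(
    hac: int, predictions: Sequence[float], votes_required: int = 3
) -> bool:
    """Consensus solubility decision.

    Threshold -2 logS units for fragments with fewer than 16 heavy atoms,
    -1 for 16 to 22; pass iff at least ``votes_required`` predictions are
    strictly better than the threshold.  Heavier fragments are outside the
    rule's domain and raise.
    """
    if not predictions:
        raise ValueError("solubility vote needs at least one prediction")
    if hac > 22:
        raise ValueError(f"solubility vote undefined for HAC {hac} > 22")
    threshold = -2.0 if hac < 16 else -1.0
    return sum(1 for p in predictions if p > threshold) >= votes_required


def maxmin_select(dmat: DistanceMatrix, k: int, seed_id: str) -> list[str]:
    """Greedy MaxMin diversity picking.

    Start from ``seed_id``; repeatedly add the unselected molecule whose
    minimum distance to the selected set is largest, ties broken by
    smallest id.  Returns the ordered pick list.
    """
    n = len(dmat.ids)
    if k > n:
        raise ValueError(f"cannot pick {k} from {n} molecules")
    if seed_id not in dmat.ids:
        raise ValueError(f"seed id {seed_id!r} not in distance matrix")
    ids = np.array(dmat.ids)
    # Lexicographic id order for tie-breaking, independent of matrix order.
    id_rank = {mol_id: r for r, mol_id in enumerate(sorted(dmat.ids))}
    selected = [dmat.index(seed_id)]
    min_dist = dmat.values[selected[0]].copy()
    for _ in range(1, k):
        best = None
        for cand in range(n):
            if cand in selected:
                continue
            key = (-min_dist[cand], id_rank[ids[cand]])
            if best is None or key < best[0]:
                best = (key, cand)
        selected.append(best[1])
        min_dist = np.minimum(min_dist, dmat.values[best[1]])
    return [str(ids[i]) for i in selected]


def satellite_select(
    dmat: DistanceMatrix, core: Sequence[str], n_sat: int = 5
) -> dict[str, list[str]]:
    """The ``n_sat`` nearest non-core molecules of every core member,
    sorted ascending by distance (ties by id).  A molecule may satellite
    several cores; deduplication happens at assembly."""
    core_set = set(core)
    candidates = [i for i, mol_id in enumerate(dmat.ids) if mol_id not in core_set]
    if len(candidates) < n_sat:
        warnings.warn(
            f"only {len(candidates)} non-core molecules available for "
            f"{n_sat} satellites per core",
            stacklevel=2,
        )
    out = {}
    for core_id in core:
        row = dmat.values[dmat.index(core_id)]
        ranked = sorted(candidates, key=lambda i: (row[i], dmat.ids[i]))
        out[core_id] = [dmat.ids[i] for i in ranked[:n_sat]]
    return out


@dataclass(frozen=True)
class SelectionResult:
    """Assembled library with full provenance of every selection decision."""

    core_ids: tuple[str, ...]
    satellites: Mapping[str, tuple[str, ...]]
    final_ids: tuple[str, ...]
    provenance: Mapping[str, str]
    params: Mapping[str, object]

    def to_json_payload(self) -> dict:
        return {
            "core_ids": list(self.core_ids),
            "satellites": {k: list(v) for k, v in self.satellites.items()},
            "final_ids": list(self.final_ids),
            "provenance": dict(self.provenance),
            "params": {k: str(v) for k, v in self.params.items()},
        }


def assemble_library(
    core: Sequence[str],
    satellites: Mapping[str, Sequence[str]],
    max_total: int,
    vote_pass: Mapping[str, bool] | None = None,
    logs: Mapping[str, float] | None = None,
    prices: Mapping[str, float] | None = None,
    require_vote_pass: bool = False,
) -> SelectionResult:
    """Deterministic stand-in for the manual expert sub-selection.

    All core members are admitted first; satellite candidates are then
    ranked by (solubility-vote pass, predicted logS descending, price
    ascending, id) and fill the library up to ``max_total``.  With
    ``require_vote_pass`` satellites failing the vote are excluded
    outright.  The ranking is a labelled surrogate for expert opinion.
    """
    vote_pass = vote_pass or {}
    logs = logs or {}
    prices = prices or {}
    final = list(core)
    provenance = {mol_id: "core" for mol_id in core}
    seen = set(final)
    candidates = []
    for core_id, sats in satellites.items():
        for sat in sats:
            if sat not in seen:
                seen.add(sat)
                candidates.append(sat)

    def rank_key(mol_id: str):
        return (
            0 if vote_pass.get(mol_id, False) else 1,
            -logs.get(mol_id, float("-inf")),
            prices.get(mol_id, float("inf")),
            mol_id,
        )

    for sat in sorted(candidates, key=rank_key):
        if len(final) >= max_total:
            provenance[sat] = "rejected:capacity"
            continue
        if require_vote_pass and not vote_pass.get(sat, False):
            provenance[sat] = "rejected:solubility_vote_failed"
            continue
        final.append(sat)
        provenance[sat] = "satellite"

    return SelectionResult(
        core_ids=tuple(core),
        satellites={k: tuple(v) for k, v in satellites.items()},
        final_ids=tuple(final),
        provenance=provenance,
        params={
            "max_total": max_total,
            "require_vote_pass": require_vote_pass,
            "ranking": "expert-opinion stand-in: vote pass, logS desc, price asc, id",
        },
    )
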