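"""Sigma-hole magnitude (V_max) providers for halogen nodes.

Quantum-chemically derived or machine-predicted V_max values are ingested
from a table; for configurations without a table entry an additive
surrogate supplies a ranking-plausible stand-in.  The surrogate anchors on
the halobenzene reference values — chlorobenzene 0.008 au, bromobenzene
0.016 au, iodobenzene 0.025 au — and adds electronegativity-driven tuning
increments that decay with topological distance from the ipso carbon.  It
is NOT a trained model: its job is to order sigma-holes sensibly (I > Br >
Cl; electron-withdrawing substitution tunes upward), and every surrogate
value is labelled as such in output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chemio import MoleculeRecord
from .config import VmaxParams
from .descriptors import PAULING_EN
from .featuretree import HalogenConfiguration, ring_offsets, ring_substituents

logger = logging.getLogger(__name__)

_CHI_H = PAULING_EN[1]


@dataclass(frozen=True)
class VmaxRecord:
    """V_max of one halogen atom on one isodensity surface."""

    molecule_id: str
    halogen_atom_index: int
    value: float  # atomic units
    surface: str  # "0.001" or "0.020" isodensity tag
    origin: str  # "table" or "surrogate"


def surrogate_vmax(
    record: MoleculeRecord,
    config: HalogenConfiguration,
    params: VmaxParams = VmaxParams(),
) -> VmaxRecord:
    """Additive V_max surrogate for one halogen configuration.

    value = baseline(element)
          + sum over heavy-atom residues of
              w_tune * (chi_group - chi_H) * gamma_topo^(offset - 1)
          + sum over non-ipso ring nitrogens of
              ring_n_increment * gamma_topo^(offset - 1)

    where chi_group is the residue's group electronegativity and offset is
    the ring distance from the halogen-bearing carbon.  The unsubstituted
    halobenzenes reproduce their baselines exactly.
    """
    mol = record.mol
    halogen = mol.GetAtomWithIdx(config.halogen_atom_index)
    if not halogen.GetNeighbors()[0].GetIsAromatic():
        raise ValueError(f"{record.id}: halogen atom {config.halogen_atom_index} is not aromatic")
    value = params.baselines[config.element]
    for slot in ring_substituents(record, config):
        if slot.kind != "residue":
            continue
        chi = slot.properties.group_electronegativity
        value += params.w_tune * (chi - _CHI_H) * params.gamma_topo ** (slot.offset - 1)
    offsets = ring_offsets(config)
    for idx in config.core_ring:
        if idx == config.ipso_index:
            continue
        if mol.GetAtomWithIdx(idx).GetAtomicNum() == 7:
            value += params.ring_n_increment * params.gamma_topo ** (offsets[idx] - 1)
    return VmaxRecord(
        molecule_id=record.id,
        halogen_atom_index=config.halogen_atom_index,
        value=value,
        surface=params.surface,
        origin="surrogate",
    )


class VmaxTable:
    """Precomputed V_max values keyed by (molecule_id, halogen atom index).

    CSV columns: molecule_id, atom_index, vmax_au, surface.  Conflicting
    duplicate rows are a load-time error.
    """

    def __init__(self, entries: dict[tuple[str, int], VmaxRecord]):
        self.entries = entries

    @classmethod
    def from_csv(cls, path: str | Path) -> "VmaxTable":
        frame = pd.read_csv(path, dtype={"molecule_id": str})
        required = {"molecule_id", "atom_index", "vmax_au", "surface"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing V_max table columns {sorted(missing)}")
        entries: dict[tuple[str, int], VmaxRecord] = {}
        for row in frame.itertuples(index=False):
            key = (row.molecule_id, int(row.atom_index))
            rec = VmaxRecord(
                molecule_id=row.molecule_id,
                halogen_atom_index=int(row.atom_index),
                value=float(row.vmax_au),
                surface=str(row.surface),
                origin="table",
            )
            if key in entries and (
                entries[key].value != rec.value or entries[key].surface != rec.surface
            ):
                raise ValueError(
                    f"conflicting duplicate V_max entries for molecule {key[0]!r} atom {key[1]}"
                )
            entries[key] = rec
        return cls(entries)

    def get(self, molecule_id: str, atom_index: int) -> VmaxRecord | None:
        return self.entries.get((molecule_id, atom_index))


class VmaxProvider:
    """Table lookup with surrogate fallback.

    Callable as ``provider(record, config)``; a missing table entry falls
    through to the surrogate with a logged warning, as recorded in the
    returned record's ``origin`` field.
    """

    def __init__(self, table: VmaxTable | None = None, params: VmaxParams = VmaxParams()):
        self.table = table
        self.params = params
        self.surrogate_calls = 0

    def __call__(self, record: MoleculeRecord, config: HalogenConfiguration) -> VmaxRecord:
        if self.table is not None:
            hit = self.table.get(record.id, config.halogen_atom_index)
            if hit is not None:
                return hit
            warnings.warn(
                f"no V_max table entry for {record.id} atom "
                f"{config.halogen_atom_index}; using surrogate",
                stacklevel=2,
            )
        self.surrogate_calls += 1
        return surrogate_vmax(record, config, self.params)
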