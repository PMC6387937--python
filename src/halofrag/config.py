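"""Parameter containers and configuration I/O.

All tunables of the library design pipeline live in small frozen dataclasses
so that every run can record a stable hash of the exact parameters used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: Reactive / unwanted substructure patterns removed before selection.
#: The set covers the usual fragment-screening offenders: acylating and
#: sulfonylating agents, strained electrophiles, Michael acceptors and
#: aliphatic leaving groups.  Editable: pass your own mapping to the filter.
DEFAULT_SMARTS_FILTERS: dict[str, str] = {
    "acyl_halide": "[CX3](=O)[Cl,Br,I]",
    "sulfonyl_halide": "[SX4](=O)(=O)[Cl,Br,I]",
    "anhydride": "[CX3](=O)O[CX3](=O)",
    "epoxide_aziridine": "[OX2r3,NX3r3]1[#6r3][#6r3]1",
    "aldehyde": "[CX3H1](=O)[#6]",
    "michael_acceptor": "[CX3]=[CX3][CX3]=[OX1]",
    "isocyanate": "[NX2]=[CX2]=[OX1]",
    "isothiocyanate": "[NX2]=[CX2]=[SX1]",
    "alkyl_halide": "[CX4][Cl,Br,I]",
    "diazo": "[NX2]=[NX1]",
    "peroxide": "[OX2][OX2]",
}


@dataclass(frozen=True)
class SimilarityParams:
    """Weights and scales of the halogen-interface similarity measure.

    node_property_weights
        Six non-negative weights (summing to 1) over the node-property
        vector components: atom count, lone-pair index, proton-neutron
        information index, flexibility index, edge connectivity, group
        electronegativity.
    component_weights
        (core ring, halogen, residues) contributions, summing to 1.
    shift_decay
        Multiplier gamma applied once per ring offset a matched residue is
        shifted (ortho residue matched to meta decays by gamma).
    empty_match_floor
        Score of a non-hydrogen residue matched against an empty slot.
    vmax_tau
        Scale (au) of the exponential closeness term on halogen V_max.
    element_mismatch_factor
        Halogen-term multiplier when the two halogens differ in element.
    ring_size_mismatch_factor
        Core-term multiplier when ring sizes differ (5- vs 6-ring).
    """

    node_property_weights: tuple[float, ...] = (1 / 6,) * 6
    component_weights: tuple[float, float, float] = (0.2, 0.3, 0.5)
    shift_decay: float = 0.7
    empty_match_floor: float = 0.0
    vmax_tau: float = 0.01
    element_mismatch_factor: float = 0.5
    ring_size_mismatch_factor: float = 0.6

    def __post_init__(self) -> None:
        if len(self.node_property_weights) != 6:
            raise ValueError("node_property_weights must have 6 entries")
        for w in (*self.node_property_weights, *self.component_weights):
            if w < 0:
                raise ValueError("weights must be non-negative")
        if abs(sum(self.node_property_weights) - 1) > 1e-9:
            raise ValueError("node_property_weights must sum to 1")
        if abs(sum(self.component_weights) - 1) > 1e-9:
            raise ValueError("component_weights must sum to 1")
        if not 0 < self.shift_decay <= 1:
            raise ValueError("shift_decay must be in (0, 1]")
        if not 0 <= self.empty_match_floor < 1:
            raise ValueError("empty_match_floor must be in [0, 1)")
        if not 0 <= self.element_mismatch_factor <= 1:
            raise ValueError("element_mismatch_factor must be in [0, 1]")
        if self.vmax_tau <= 0:
            raise ValueError("vmax_tau must be positive")

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class VmaxParams:
    """Parameters of the additive sigma-hole magnitude surrogate.

    Baselines are the halobenzene reference values (au, on the 0.020 au
    isodensity surface tag used for prediction); tuning increments are
    ranking-plausible constants, not fitted to any quantum-chemical data.
    """

    baselines: Mapping[str, float] = field(
        default_factory=lambda: {"Cl": 0.008, "Br": 0.016, "I": 0.025}
    )
    w_tune: float = 0.004          # au per unit group-electronegativity excess
    gamma_topo: float = 0.5        # decay per ring bond away from the ipso carbon
    ring_n_increment: float = 0.006  # au per pyridine-type ring nitrogen (undecayed)
    surface: str = "0.020"

    def param_hash(self) -> str:
        payload = json.dumps(
            {
                "baselines": dict(self.baselines),
                "w_tune": self.w_tune,
                "gamma_topo": self.gamma_topo,
                "ring_n_increment": self.ring_n_increment,
                "surface": self.surface,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DesignParams:
    """Thresholds of the filtering, voting and selection stages."""

    hac_limit: int = 20
    price_limit: float = 5.0           # $/mg, inclusive
    price_missing_policy: str = "remove"  # or "keep"
    votes_required: int = 3
    core_size: int = 150
    n_satellites: int = 5
    max_total: int = 200
    vote_stage: str = "assembly"       # or "prefilter"


def load_config(path: str | Path) -> dict:
    """Read a structured YAML config into a plain dict (validated by the
    pipeline when consumed)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def config_hash(data: dict) -> str:
    return hashlib.sha256(json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:16]
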