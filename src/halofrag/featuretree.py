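"""Halogen configurations and the rooted halogen-interface feature tree.

Every aromatic Cl, Br or I together with its central aromatic ring is one
*configuration* — the unit the similarity measure compares.  Around each
configuration a rooted tree is built: the core ring node, the halogen node
(annotated with its sigma-hole magnitude V_max) and one residue slot per
remaining ring position.  A residue is anything hanging off the ring at
that position: a single hydrogen, a substituent, or an annulated ring
system; offsets generalize ortho/meta/para as the shortest path along the
ring from the halogen-bearing (ipso) carbon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from rdkit import Chem

from .chemio import MoleculeRecord
from .descriptors import EMPTY_VECTOR, HYDROGEN_VECTOR, NodePropertyVector, node_properties

HALOGEN_NUMS = {17: "Cl", 35: "Br", 53: "I"}


def type_atoms(record: MoleculeRecord) -> dict[int, frozenset[str]]:
    """Pharmacophoric atom typing: HBD/HBA for N and O, POS/NEG by formal
    charge sign.  Donors are N/O bearing at least one hydrogen; acceptors
    are all N/O (the same counting dialect as the molecular descriptors)."""
    out: dict[int, frozenset[str]] = {}
    for atom in record.mol.GetAtoms():
        feats = set()
        if atom.GetAtomicNum() in (7, 8):
            feats.add("HBA")
            if atom.GetTotalNumHs() >= 1:
                feats.add("HBD")
        if atom.GetFormalCharge() > 0:
            feats.add("POS")
        elif atom.GetFormalCharge() < 0:
            feats.add("NEG")
        if feats:
            out[atom.GetIdx()] = frozenset(feats)
    return out


@dataclass(frozen=True)
class HalogenConfiguration:
    """One aromatic halogen plus its central ring."""

    molecule_id: str
    halogen_atom_index: int
    element: str  # Cl, Br or I
    core_ring: tuple[int, ...]  # ring atoms in cycle order
    ipso_index: int


def _aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    return [
        ring
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]


def enumerate_configurations(record: MoleculeRecord) -> list[HalogenConfiguration]:
    """One configuration per aromatic Cl/Br/I, ordered by halogen atom index.

    Fluorine and aliphatic halogens are ignored.  The central ring is the
    smallest aromatic ring containing the ipso atom (ties broken by the
    lexicographically smallest sorted atom tuple), which in fused systems
    turns the remainder of the ring system into a fused residue.
    """
    mol = record.mol
    rings = _aromatic_rings(mol)
    configs: list[HalogenConfiguration] = []
    for atom in mol.GetAtoms():
        element = HALOGEN_NUMS.get(atom.GetAtomicNum())
        if element is None or atom.GetDegree() != 1:
            continue
        ipso = atom.GetNeighbors()[0]
        if not ipso.GetIsAromatic():
            continue
        candidates = [r for r in rings if ipso.GetIdx() in r and 5 <= len(r) <= 7]
        if not candidates:
            continue
        core = min(candidates, key=lambda r: (len(r), tuple(sorted(r))))
        configs.append(
            HalogenConfiguration(
                molecule_id=record.id,
                halogen_atom_index=atom.GetIdx(),
                element=element,
                core_ring=tuple(core),
                ipso_index=ipso.GetIdx(),
            )
        )
    configs.sort(key=lambda c: c.halogen_atom_index)
    return configs


def ring_offsets(config: HalogenConfiguration) -> dict[int, int]:
    """Shortest ring-path distance of every core atom from the ipso atom."""
    ring = config.core_ring
    n = len(ring)
    pos = {idx: p for p, idx in enumerate(ring)}
    ipso_pos = pos[config.ipso_index]
    return {idx: min((p - ipso_pos) % n, (ipso_pos - p) % n) for idx, p in pos.items()}


@dataclass(frozen=True)
class FeatureTreeNode:
    """Typed node with a property vector; children only for residue roots."""

    node_type: str  # AROMATIC_CORE, HALOGEN, RING, LINKER, RESIDUE
    properties: NodePropertyVector
    features: frozenset[str] = frozenset()  # HBD/HBA/POS/NEG present in the node
    children: tuple["FeatureTreeNode", ...] = ()
    vmax: object | None = None  # VmaxRecord, HALOGEN nodes only


@dataclass(frozen=True)
class Residue:
    """One positional slot of the core ring.

    kind is ``"H"`` for a single-hydrogen residue, ``"residue"`` for a
    heavy-atom substituent (possibly an annulated ring system, then
    ``fused`` is set) and ``"empty"`` for a slot that carries nothing
    (pyridine-type ring nitrogen, or the partner attachment position of a
    fused residue).
    """

    offset: int
    kind: str
    atom_indices: tuple[int, ...] = ()
    fused: bool = False
    properties: NodePropertyVector = field(default=HYDROGEN_VECTOR)
    node: FeatureTreeNode | None = None


def _residue_components(
    mol: Chem.Mol, config: HalogenConfiguration
) -> list[tuple[tuple[int, ...], list[int]]]:
    """Connected components of the molecule outside the core ring (halogen
    excluded), each with the core atoms it attaches to."""
    core = set(config.core_ring)
    outside = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIdx() not in core and a.GetIdx() != config.halogen_atom_index
    ]
    unvisited = set(outside)
    components = []
    while unvisited:
        start = min(unvisited)
        comp = {start}
        stack = [start]
        unvisited.discard(start)
        attach: set[int] = set()
        while stack:
            for nbr in mol.GetAtomWithIdx(stack.pop()).GetNeighbors():
                idx = nbr.GetIdx()
                if idx in core:
                    attach.add(idx)
                elif idx == config.halogen_atom_index:
                    continue
                elif idx in unvisited:
                    unvisited.discard(idx)
                    comp.add(idx)
                    stack.append(idx)
        components.append((tuple(sorted(comp)), sorted(attach)))
    return components


def ring_substituents(record: MoleculeRecord, config: HalogenConfiguration) -> list[Residue]:
    """The ring-size-minus-one residue slots of a configuration, without
    typed child decomposition (property vectors only).

    Every non-halogen ring substituent — including single hydrogens —
    lands in exactly one slot; annulated systems attached at two ring
    atoms occupy the slot of the lower offset and carry the fused flag.
    """
    mol = record.mol
    offsets = ring_offsets(config)
    core = set(config.core_ring)
    # Components assigned to their anchoring core atom.
    assigned: dict[int, list[tuple[tuple[int, ...], bool]]] = {}
    for comp, attach in _residue_components(mol, config):
        fused = len(attach) > 1
        anchors = [a for a in attach if a != config.ipso_index] or attach
        anchor = min(anchors, key=lambda a: (offsets[a], a))
        assigned.setdefault(anchor, []).append((comp, fused))

    slots: list[Residue] = []
    for ring_atom in config.core_ring:
        if ring_atom == config.ipso_index:
            continue
        offset = offsets[ring_atom]
        comps = assigned.get(ring_atom, [])
        if comps:
            # Merge multiple components anchored at one atom (rare, 7-rings).
            atoms = tuple(sorted(i for comp, _ in comps for i in comp))
            fused = any(f for _, f in comps)
            slots.append(
                Residue(
                    offset=offset,
                    kind="residue",
                    atom_indices=atoms,
                    fused=fused,
                    properties=node_properties(mol, atoms),
                )
            )
        elif mol.GetAtomWithIdx(ring_atom).GetTotalNumHs() >= 1:
            slots.append(Residue(offset=offset, kind="H"))
        else:
            slots.append(Residue(offset=offset, kind="empty", properties=EMPTY_VECTOR))
    slots.sort(key=lambda s: (s.offset, s.kind, s.atom_indices))
    return slots


def _decompose_residue(
    mol: Chem.Mol, atoms: tuple[int, ...], atom_features: Mapping[int, frozenset[str]]
) -> tuple[FeatureTreeNode, ...]:
    """Split a residue into ring-system and linker child nodes (depth <= 2);
    pharmacophoric annotations are attached per node."""
    in_ring = [i for i in atoms if mol.GetAtomWithIdx(i).IsInRing()]
    chain = [i for i in atoms if not mol.GetAtomWithIdx(i).IsInRing()]
    children = []
    for group, node_type in ((in_ring, "RING"), (chain, "LINKER")):
        for comp in _connected_parts(mol, group):
            feats = frozenset().union(*(atom_features.get(i, frozenset()) for i in comp))
            children.append(
                FeatureTreeNode(
                    node_type=node_type,
                    properties=node_properties(mol, comp),
                    features=feats,
                )
            )
    return tuple(children)


def _connected_parts(mol: Chem.Mol, atoms: Sequence[int]) -> list[tuple[int, ...]]:
    remaining = set(atoms)
    parts = []
    while remaining:
        start = min(remaining)
        comp = {start}
        stack = [start]
        remaining.discard(start)
        while stack:
            for nbr in mol.GetAtomWithIdx(stack.pop()).GetNeighbors():
                idx = nbr.GetIdx()
                if idx in remaining:
                    remaining.discard(idx)
                    comp.add(idx)
                    stack.append(idx)
        parts.append(tuple(sorted(comp)))
    return parts


@dataclass(frozen=True)
class FeatureTree:
    """Rooted tree of one halogen configuration."""

    config: HalogenConfiguration
    ring_size: int
    core_elements: tuple[tuple[str, int], ...]  # sorted (element, count) multiset
    topology_signature: tuple[str, ...]  # ring elements walked from ipso, direction-canonical
    core_node: FeatureTreeNode
    halogen_node: FeatureTreeNode
    slots: tuple[Residue, ...]

    @property
    def vmax(self):
        return self.halogen_node.vmax


def build_feature_tree(
    record: MoleculeRecord,
    config: HalogenConfiguration,
    vmax_provider: Callable[[MoleculeRecord, HalogenConfiguration], object] | None = None,
) -> FeatureTree:
    """Assemble the rooted feature tree of one configuration.

    ``vmax_provider(record, config)`` supplies the halogen node's V_max; a
    provider failure (or ``None`` provider) leaves V_max flagged missing
    rather than aborting the tree.
    """
    mol = record.mol
    atom_features = type_atoms(record)
    ring = config.core_ring
    n = len(ring)
    pos = {idx: p for p, idx in enumerate(ring)}
    ipso_pos = pos[config.ipso_index]
    symbols = [mol.GetAtomWithIdx(i).GetSymbol() for i in ring]
    fwd = tuple(symbols[(ipso_pos + k) % n] for k in range(n))
    rev = tuple(symbols[(ipso_pos - k) % n] for k in range(n))
    signature = min(fwd, rev)

    core_feats = frozenset().union(
        frozenset(), *(atom_features.get(i, frozenset()) for i in ring)
    )
    core_node = FeatureTreeNode(
        node_type="AROMATIC_CORE",
        properties=node_properties(mol, list(ring)),
        features=core_feats,
    )

    vmax_record = None
    if vmax_provider is not None:
        try:
            vmax_record = vmax_provider(record, config)
        except Exception:
            vmax_record = None
    halogen_node = FeatureTreeNode(
        node_type="HALOGEN",
        properties=node_properties(mol, [config.halogen_atom_index]),
        vmax=vmax_record,
    )

    slots = []
    for slot in ring_substituents(record, config):
        if slot.kind == "residue":
            node = FeatureTreeNode(
                node_type="RESIDUE",
                properties=slot.properties,
                features=frozenset().union(
                    frozenset(),
                    *(atom_features.get(i, frozenset()) for i in slot.atom_indices),
                ),
                children=_decompose_residue(mol, slot.atom_indices, atom_features),
            )
            slot = Residue(
                offset=slot.offset,
                kind=slot.kind,
                atom_indices=slot.atom_indices,
                fused=slot.fused,
                properties=slot.properties,
                node=node,
            )
        slots.append(slot)

    elements = Counter(symbols)
    return FeatureTree(
        config=config,
        ring_size=n,
        core_elements=tuple(sorted(elements.items())),
        topology_signature=signature,
        core_node=core_node,
        halogen_node=halogen_node,
        slots=tuple(slots),
    )
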