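"""Molecular and node-level descriptors.

Two descriptor families live here:

* whole-molecule descriptors used for filtering and profiling (MW, heavy
  atom count, H-bond donors/acceptors, rotatable bonds, TPSA, Crippen
  clogP, Fsp3) — standard RDKit implementations behind a stable surface;
* the six node properties of the halogen-interface feature tree (atom
  count, lone-pair index, proton-neutron information index, Kier
  flexibility, edge connectivity, group electronegativity), computed on
  arbitrary residue subgraphs.  The literature names these descriptor
  families without printing formulas, so the functional forms here are
  fixed, documented surrogates — what matters for the similarity measure
  is that they are reproducible and discriminate residues sensibly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

from .chemio import MoleculeRecord

# Pauling electronegativities of the elements expected in fragment space.
PAULING_EN: dict[int, float] = {
    1: 2.20, 3: 0.98, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    11: 0.93, 12: 1.31, 14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16,
    19: 0.82, 20: 1.00, 30: 1.65, 34: 2.55, 35: 2.96, 53: 2.66,
}

# Lone pairs in the neutral standard valence state; adjusted by formal charge.
_BASE_LONE_PAIRS: dict[int, int] = {
    7: 1, 8: 2, 9: 3, 15: 1, 16: 2, 17: 3, 34: 2, 35: 3, 53: 3,
}

# Kier covalent-radius corrections alpha = r_X/r_Csp3 - 1, keyed by
# (atomic number, hybridization bucket).  Values follow the published
# Hall-Kier table.
_KIER_ALPHA: dict[tuple[int, str], float] = {
    (6, "sp3"): 0.00, (6, "sp2"): -0.13, (6, "sp"): -0.22,
    (7, "sp3"): -0.04, (7, "sp2"): -0.20, (7, "sp"): -0.29,
    (8, "sp3"): -0.04, (8, "sp2"): -0.20,
    (9, "sp3"): -0.07,
    (15, "sp3"): 0.43, (15, "sp2"): 0.30,
    (16, "sp3"): 0.35, (16, "sp2"): 0.22,
    (17, "sp3"): 0.29, (35, "sp3"): 0.48, (53, "sp3"): 0.73,
}


def _electronegativity(atomic_num: int) -> float:
    try:
        return PAULING_EN[atomic_num]
    except KeyError:
        raise ValueError(
            f"no Pauling electronegativity tabulated for element Z={atomic_num}"
        ) from None


def _lone_pairs(atom: Chem.Atom) -> int:
    base = _BASE_LONE_PAIRS.get(atom.GetAtomicNum(), 0)
    return max(0, base - atom.GetFormalCharge())


def _hyb_bucket(atom: Chem.Atom) -> str:
    hyb = atom.GetHybridization()
    if atom.GetIsAromatic() or hyb == Chem.HybridizationType.SP2:
        return "sp2"
    if hyb == Chem.HybridizationType.SP:
        return "sp"
    return "sp3"


def _kier_alpha(atom: Chem.Atom) -> float:
    z = atom.GetAtomicNum()
    for key in ((z, _hyb_bucket(atom)), (z, "sp3"), (z, "sp2")):
        if key in _KIER_ALPHA:
            return _KIER_ALPHA[key]
    return 0.0


@dataclass(frozen=True)
class NodePropertyVector:
    """Property vector of one feature-tree node (all components >= 0)."""

    atom_count: float
    lone_pair_index: float
    pn_information_index: float
    flexibility_index: float
    edge_connectivity: float
    group_electronegativity: float
    #: True only for the empty residue, where electronegativity is undefined.
    en_undefined: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.atom_count,
                self.lone_pair_index,
                self.pn_information_index,
                self.flexibility_index,
                self.edge_connectivity,
                self.group_electronegativity,
            ],
            dtype=float,
        )


#: Property vector of a single-hydrogen residue.
HYDROGEN_VECTOR = NodePropertyVector(
    atom_count=1.0,
    lone_pair_index=0.0,
    pn_information_index=0.0,
    flexibility_index=0.0,
    edge_connectivity=0.0,
    group_electronegativity=PAULING_EN[1],
)

#: Vector of the empty residue (all zero, electronegativity flagged).
EMPTY_VECTOR = NodePropertyVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, en_undefined=True)


def _check_connected(mol: Chem.Mol, atoms: Sequence[int]) -> None:
    atom_set = set(atoms)
    seen = {atoms[0]}
    stack = [atoms[0]]
    while stack:
        for nbr in mol.GetAtomWithIdx(stack.pop()).GetNeighbors():
            idx = nbr.GetIdx()
            if idx in atom_set and idx not in seen:
                seen.add(idx)
                stack.append(idx)
    if seen != atom_set:
        raise ValueError("residue subgraph is disconnected")


def node_properties(mol: Chem.Mol, atoms: Sequence[int]) -> NodePropertyVector:
    """Compute the six node properties on a connected residue subgraph.

    ``atoms`` indexes the residue's heavy atoms within ``mol``; implicit
    hydrogens of those atoms are counted as residue atoms.  A single
    hydrogen residue is represented by :data:`HYDROGEN_VECTOR` (build it
    directly; it has no heavy-atom indices).
    """
    atoms = list(atoms)
    if not atoms:
        return EMPTY_VECTOR
    _check_connected(mol, atoms)
    atom_set = set(atoms)
    pt = Chem.GetPeriodicTable()

    # Per-atom contributions over heavy atoms + their hydrogens.
    mass_numbers: list[int] = []
    lone_pair = 0.0
    log_en_sum = 0.0
    n_total = 0
    for idx in atoms:
        atom = mol.GetAtomWithIdx(idx)
        z = atom.GetAtomicNum()
        mass_numbers.append(pt.GetMostCommonIsotope(z))
        lone_pair += _lone_pairs(atom) * _electronegativity(z)
        log_en_sum += math.log(_electronegativity(z))
        n_total += 1
        n_h = atom.GetTotalNumHs()
        mass_numbers.extend([1] * n_h)
        log_en_sum += n_h * math.log(PAULING_EN[1])
        n_total += n_h

    # Proton-neutron composition information content (bits).
    total_mass = float(sum(mass_numbers))
    pn_index = total_mass * math.log2(total_mass) - sum(
        a * math.log2(a) for a in mass_numbers if a > 1
    )
    pn_index = max(0.0, pn_index)

    # Heavy-atom subgraph topology.
    edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in atom_set and b.GetEndAtomIdx() in atom_set
    ]
    degree = {idx: 0 for idx in atoms}
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1

    edge_conn = _edge_connectivity(edges)
    flexibility = _kier_flexibility(mol, atoms, edges, degree)
    group_en = math.exp(log_en_sum / n_total)

    return NodePropertyVector(
        atom_count=float(n_total),
        lone_pair_index=lone_pair,
        pn_information_index=pn_index,
        flexibility_index=flexibility,
        edge_connectivity=edge_conn,
        group_electronegativity=group_en,
    )


def _edge_connectivity(edges: list[tuple[int, int]]) -> float:
    """Sum over adjacent edge pairs of (delta_e * delta_f)^(-1/2), where
    delta is the edge degree in the line graph of the residue subgraph."""
    n = len(edges)
    if n < 2:
        return 0.0
    adj = [
        (a, b)
        for a in range(n)
        for b in range(a + 1, n)
        if set(edges[a]) & set(edges[b])
    ]
    edge_degree = [0] * n
    for a, b in adj:
        edge_degree[a] += 1
        edge_degree[b] += 1
    return sum(1.0 / math.sqrt(edge_degree[a] * edge_degree[b]) for a, b in adj)


def _kier_flexibility(
    mol: Chem.Mol,
    atoms: list[int],
    edges: list[tuple[int, int]],
    degree: dict[int, int],
) -> float:
    """Kier flexibility (kappa1_a * kappa2_a) / N on the residue subgraph;
    defined as 0 for fewer than three heavy atoms."""
    n = len(atoms)
    if n < 3:
        return 0.0
    alpha = sum(_kier_alpha(mol.GetAtomWithIdx(i)) for i in atoms)
    p1 = len(edges)
    p2 = sum(d * (d - 1) // 2 for d in degree.values())  # paths of length 2
    if p1 + alpha <= 0 or p2 + alpha <= 0:
        return 0.0
    kappa1 = (n + alpha) * (n + alpha - 1) ** 2 / (p1 + alpha) ** 2
    kappa2 = (n + alpha - 1) * (n + alpha - 2) ** 2 / (p2 + alpha) ** 2
    return max(0.0, kappa1 * kappa2 / n)


@dataclass(frozen=True)
class DescriptorSet:
    """Whole-molecule descriptors used by the filters and profiles."""

    mw: float
    hac: int
    hba: int
    hbd: int
    rotatable_bonds: int
    tpsa: float
    clogp: float
    fsp3: float


def molecular_descriptors(record: MoleculeRecord, hbond_rule: str = "no_count") -> DescriptorSet:
    """Compute the profiling descriptor set.

    ``hbond_rule`` selects the H-bond counting dialect:

    * ``"no_count"`` (default): acceptors = all N/O atoms, donors = N/O
      atoms bearing at least one hydrogen;
    * ``"rdkit"``: RDKit's stricter ``NumHAcceptors`` / ``NumHDonors``.
    """
    mol = record.mol
    if hbond_rule == "no_count":
        hba = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
        hbd = sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs() >= 1
        )
    elif hbond_rule == "rdkit":
        hba = rdMolDescriptors.CalcNumHBA(mol)
        hbd = rdMolDescriptors.CalcNumHBD(mol)
    else:
        raise ValueError(f"unknown hbond_rule {hbond_rule!r}")
    n_carbon = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    if n_carbon == 0:
        warnings.warn(f"{record.id}: carbon-free molecule, Fsp3 defined as 0", stacklevel=2)
        fsp3 = 0.0
    else:
        fsp3 = rdMolDescriptors.CalcFractionCSP3(mol)
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        hac=mol.GetNumHeavyAtoms(),
        hba=hba,
        hbd=hbd,
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        clogp=Crippen.MolLogP(mol),
        fsp3=fsp3,
    )


def aromatic_proportion(mol: Chem.Mol) -> float:
    """Fraction of heavy atoms that are aromatic."""
    n = mol.GetNumHeavyAtoms()
    if n == 0:
        return 0.0
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / n


def esol_from_components(clogp: float, mw: float, rotatable_bonds: int, ap: float) -> float:
    """Delaney's ESOL regression: logS (mol/L, log10)."""
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rotatable_bonds - 0.74 * ap


def esol_logs(record: MoleculeRecord) -> float:
    """Estimated aqueous solubility of a fragment via the ESOL regression."""
    desc = molecular_descriptors(record)
    return esol_from_components(
        desc.clogp, desc.mw, desc.rotatable_bonds, aromatic_proportion(record.mol)
    )


@dataclass(frozen=True)
class ShapeDescriptors:
    """Normalized principal moment-of-inertia ratios (shape triangle)."""

    npr1: float  # I1/I3 in [0, 1]
    npr2: float  # I2/I3 in [0.5, 1]


def pmi_shape(record: MoleculeRecord, conformer_seed: int = 2019) -> ShapeDescriptors | None:
    """Embed one low-energy conformer (ETKDG + MMFF) and return NPR ratios.

    Returns ``None`` when 3D embedding fails; callers exclude such records
    from shape statistics and report them.
    """
    mol = Chem.AddHs(Chem.Mol(record.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(conformer_seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(mol, params) != 0:
        return None
    try:
        AllChem.MMFFOptimizeMolecule(mol)
    except Exception:
        pass  # unoptimized conformer still yields a valid shape point
    return ShapeDescriptors(
        npr1=rdMolDescriptors.CalcNPR1(mol), npr2=rdMolDescriptors.CalcNPR2(mol)
    )


def descriptor_table(records: Iterable[MoleculeRecord], hbond_rule: str = "no_count"):
    """Descriptor export: one row per molecule, stable column order."""
    import pandas as pd

    rows = []
    for rec in records:
        d = molecular_descriptors(rec, hbond_rule=hbond_rule)
        rows.append(
            {
                "id": rec.id, "smiles": rec.smiles, "mw": d.mw, "hac": d.hac,
                "hba": d.hba, "hbd": d.hbd, "rotatable_bonds": d.rotatable_bonds,
                "tpsa": d.tpsa, "clogp": d.clogp, "fsp3": d.fsp3,
                "esol_logs": esol_from_components(
                    d.clogp, d.mw, d.rotatable_bonds, aromatic_proportion(rec.mol)
                ),
            }
        )
    return pd.DataFrame(rows)
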