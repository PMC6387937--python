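"""Molecule and table I/O, standardization, and synthetic fixture sets.

Records are thin wrappers around RDKit molecules.  The fixture generator
enumerates halogenated (hetero)aryl fragments — one aromatic Cl/Br/I on a
small heteroaromatic scaffold plus at most one further ring substituent —
which emulates the composition of a vendor fragment catalogue without
requiring any download.
"""

from __future__ import annotations

import itertools
import random
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger

# RDKit reports parse problems through its own logger; we collect them as
# structured per-record errors instead.
RDLogger.DisableLog("rdApp.error")


@dataclass(frozen=True)
class MoleculeRecord:
    """One parsed fragment: stable id, canonical SMILES and the RDKit graph."""

    id: str
    smiles: str
    mol: Chem.Mol = field(compare=False, repr=False)
    source: str = "input"

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str, source: str = "input") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {mol_id!r}: {smiles!r}")
        return cls(id=mol_id, smiles=Chem.MolToSmiles(mol), mol=mol, source=source)


@dataclass(frozen=True)
class ParseError:
    """A rejected input entry, with its position in the source file."""

    record_number: int  # 1-based line / record index
    message: str


def _auto_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".smi": "smiles", ".smiles": "smiles", ".txt": "smiles",
            ".sdf": "sdf", ".mol": "sdf", ".csv": "csv"}.get(suffix, "smiles")


def read_molecules(
    path: str | Path, fmt: str | None = None, source: str | None = None
) -> tuple[list[MoleculeRecord], list[ParseError]]:
    """Read molecules from a SMILES (.smi), SDF (V2000) or CSV file.

    Returns ``(records, errors)``: one record per valid entry in input
    order; every invalid entry yields a :class:`ParseError` naming its
    line/record number.  An unreadable file raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _auto_format(path)
    source = source or str(path)
    records: list[MoleculeRecord] = []
    errors: list[ParseError] = []

    if fmt == "smiles":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                smi = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"M{lineno:06d}"
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    errors.append(ParseError(lineno, f"unparsable SMILES {smi!r} on line {lineno}"))
                    continue
                records.append(MoleculeRecord(mol_id, Chem.MolToSmiles(mol), mol, source))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for idx, mol in enumerate(supplier, start=1):
            if mol is None:
                errors.append(ParseError(idx, f"unparsable SDF record {idx}"))
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"M{idx:06d}"
            records.append(MoleculeRecord(mol_id, Chem.MolToSmiles(mol), mol, source))
    elif fmt == "csv":
        frame = pd.read_csv(path)
        if "smiles" not in frame.columns:
            raise ValueError(f"{path}: CSV requires a 'smiles' column")
        has_id = "id" in frame.columns
        for idx, row in enumerate(frame.itertuples(index=False), start=1):
            smi = getattr(row, "smiles")
            mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
            if mol is None:
                errors.append(ParseError(idx, f"unparsable SMILES {smi!r} in CSV record {idx}"))
                continue
            mol_id = str(getattr(row, "id")) if has_id else f"M{idx:06d}"
            records.append(MoleculeRecord(mol_id, Chem.MolToSmiles(mol), mol, source))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return records, errors


def write_molecules(records: list[MoleculeRecord], path: str | Path, fmt: str | None = None) -> None:
    """Write records as canonical SMILES (.smi), SDF or CSV."""
    path = Path(path)
    fmt = fmt or _auto_format(path)
    if fmt == "smiles":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.smiles} {rec.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rec in records:
                mol = Chem.Mol(rec.mol)
                mol.SetProp("_Name", rec.id)
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "csv":
        pd.DataFrame({"id": [r.id for r in records], "smiles": [r.smiles for r in records]}).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Keep the largest covalent fragment (salt stripping) and recompute the
    canonical SMILES.

    The tautomer/protonation state is taken as drawn.  Ties on heavy-atom
    count are broken by lexicographic canonical SMILES order.
    """
    frags = Chem.GetMolFrags(record.mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    else:
        best = record.mol
    smiles = Chem.MolToSmiles(best)
    return replace(record, smiles=smiles, mol=Chem.MolFromSmiles(smiles))


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic halogenated-fragment set."""

    seed: int = 0
    scaffolds: tuple[str, ...] = (
        "c1ccccc1",      # benzene
        "c1ccncc1",      # pyridine
        "c1cncnc1",      # pyrimidine
        "c1cnccn1",      # pyrazine
        "c1cc[nH]c1",    # pyrrole
        "c1c[nH]cn1",    # imidazole
        "c1ccsc1",       # thiophene
        "c1ccoc1",       # furan
    )
    halogens: tuple[str, ...] = ("Cl", "Br", "I")
    substituents: tuple[str, ...] = (
        "H",                 # unsubstituted
        "C",                 # methyl
        "N",                 # amino
        "O",                 # hydroxy
        "OC",                # methoxy
        "C#N",               # nitrile
        "[N+](=O)[O-]",      # nitro
        "F",                 # fluoro (never counts as an XB configuration)
        "C(F)(F)F",          # trifluoromethyl
        "C(=O)N",            # carboxamide
        "C(=O)O",            # carboxylic acid
        "c1ccccc1",          # phenyl
    )
    count: int = 300


def _substitutable_positions(scaffold: Chem.Mol) -> list[int]:
    """Aromatic atoms of the scaffold bearing at least one implicit H."""
    return [
        a.GetIdx()
        for a in scaffold.GetAtoms()
        if a.GetIsAromatic() and a.GetTotalNumHs() >= 1
    ]


def _attach(scaffold_smiles: str, attachments: list[tuple[int, str]]) -> str | None:
    """Bond each fragment's first atom to the given scaffold position."""
    core = Chem.MolFromSmiles(scaffold_smiles)
    mol = core
    anchors = []
    for pos, frag_smi in attachments:
        frag = Chem.MolFromSmiles(frag_smi)
        if frag is None:
            return None
        anchors.append((pos, mol.GetNumAtoms()))
        mol = Chem.CombineMols(mol, frag)
    rw = Chem.RWMol(mol)
    for pos, frag_start in anchors:
        rw.AddBond(pos, frag_start, Chem.BondType.SINGLE)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def generate_fixtures(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Enumerate scaffold x halogen position x substituent pattern, then
    deterministically sample ``spec.count`` molecules with ``spec.seed``.

    Every generated molecule carries exactly one aromatic Cl/Br/I from the
    halogen slot (substituents may add fluorine or aliphatic halogens,
    which do not form configurations).  Identical specs yield identical
    output lists.
    """
    if not (spec.scaffolds and spec.halogens and spec.substituents):
        raise ValueError("scaffolds, halogens and substituents must be non-empty")
    seen: set[str] = set()
    enumerated: list[str] = []
    for scaffold_smi in spec.scaffolds:
        core = Chem.MolFromSmiles(scaffold_smi)
        if core is None:
            raise ValueError(f"unparsable scaffold {scaffold_smi!r}")
        positions = _substitutable_positions(core)
        for hal_pos, halogen in itertools.product(positions, spec.halogens):
            for sub_pos, sub in itertools.product(positions, spec.substituents):
                if sub_pos == hal_pos and sub != "H":
                    continue
                attachments = [(hal_pos, halogen)]
                if sub != "H":
                    attachments.append((sub_pos, sub))
                smi = _attach(scaffold_smi, attachments)
                if smi is None or smi in seen:
                    continue
                seen.add(smi)
                enumerated.append(smi)
    if spec.count >= len(enumerated):
        if spec.count > len(enumerated):
            warnings.warn(
                f"requested {spec.count} fixtures but only {len(enumerated)} "
                "distinct molecules are enumerable; returning all",
                stacklevel=2,
            )
        chosen = enumerated
    else:
        rng = random.Random(spec.seed)
        chosen = sorted(rng.sample(enumerated, spec.count), key=enumerated.index)
    return [
        MoleculeRecord(f"F{i:05d}", smi, Chem.MolFromSmiles(smi), source="fixture")
        for i, smi in enumerate(chosen, start=1)
    ]
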