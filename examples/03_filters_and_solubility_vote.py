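"""Vendor-style triage: structural + reactive-substructure filters and the
consensus solubility vote."""

from halofrag import (
    MoleculeRecord,
    smarts_filter,
    solubility_vote,
    structural_filter,
)

records = [
    MoleculeRecord.from_smiles("Clc1ccccc1", "aryl_chloride"),
    MoleculeRecord.from_smiles("c1ccccc1", "benzene"),
    MoleculeRecord.from_smiles("CC(=O)Cl", "acetyl_chloride"),
    MoleculeRecord.from_smiles("Brc1ccc(CCCCCCCCCCCCCC)cc1", "too_large"),
]
report = structural_filter(records).merge(smarts_filter(records))
for mol_id, decision in report.decisions.items():
    verdict = "kept" if decision.kept else f"removed ({', '.join(decision.reasons)})"
    print(f"{mol_id:18s} {verdict}")

# The vote: at least 3 of the predictors must beat logS -2 (below 16 heavy
# atoms) or -1 (16-22 heavy atoms).
preds = [-1.5, -1.8, -1.9, -3.0, -3.0, -3.0]
print("\npredictions:", preds)
print("HAC 10 ->", "pass" if solubility_vote(10, preds) else "fail", "(threshold -2)")
print("HAC 18 ->", "pass" if solubility_vote(18, preds) else "fail", "(threshold -1)")
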