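"""Generate a synthetic halogenated-fragment set and look at its descriptors.

The generator enumerates heteroaromatic scaffolds x halogen positions x
substituents, emulating a vendor fragment catalogue in which every member
carries one aromatic Cl/Br/I.
"""

from halofrag import FixtureSpec, generate_fixtures, molecular_descriptors

records = generate_fixtures(FixtureSpec(seed=0, count=12))
print(f"{'id':8s} {'smiles':28s} {'MW':>7s} {'HAC':>4s} {'HBA':>4s} {'TPSA':>6s}")
for rec in records:
    d = molecular_descriptors(rec)
    print(f"{rec.id:8s} {rec.smiles:28s} {d.mw:7.1f} {d.hac:4d} {d.hba:4d} {d.tpsa:6.1f}")

# Each row is one fragment: molecular weight in Da, heavy atom count,
# H-bond acceptors (N/O count) and Ertl topological polar surface area in
# A^2 -- the quantities the rule-of-three and solubility filters act on.
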