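# halofrag

Design and profiling of **halogen-enriched fragment libraries** (HEFLibs):
fragment collections in which every member carries at least one aromatic
Cl, Br or I, built so that screening hits can reveal halogen bonds as key
binding motifs.

Halogen bonding is the attraction between the σ-hole — the region of
positive electrostatic potential on a covalently bound halogen along the
extension of the C–X axis — and a Lewis base of the target. Whether a
fragment can form such a bond, and how strongly, is governed by the
halogen's *proximal* environment: the (hetero)aromatic ring it sits on and
that ring's substituents, which tune the σ-hole magnitude V_max. A
diversity selection for this purpose therefore should not compare whole
molecules; it should compare **halogen bonding interfaces**.

`halofrag` is a library (plus a thin `halofrag` CLI) for computational
chemists assembling such libraries from vendor catalogues or enumerated
candidates.

## The method

**Configurations and feature trees.** Every aromatic Cl/Br/I together with
its central aromatic ring is one *configuration*. Around it a rooted tree
is built: a core-ring node, the halogen node annotated with V_max, and one
residue slot per remaining ring position — ortho/meta/para generalized to
ring offsets o ∈ {1…⌊n/2⌋}. A residue is anything attached at that
position: a single hydrogen, a substituent, or an annulated ring system.
Each residue carries a six-component property vector: atom count,
lone-pair index, proton–neutron composition information index, Kier
flexibility, edge connectivity and group electronegativity.

**Similarity.** For two configurations,

```
sim = w_core · sim_core + w_X · sim_X + w_res · sim_res
sim_X = element_term · exp(−|ΔV_max| / τ)
sim_res = (optimal slot assignment) / max(slot count),
          pair score = Σ_k w_k · min(p_k,q_k)/max(p_k,q_k) · γ^|o_a − o_b|
```

The residue assignment is solved exactly (Hungarian algorithm); shifted
residues decay by γ per offset, unmatched heavy residues fall to a
configurable floor. Molecule similarity is the maximum over configuration
pairs, and D = 1 − sim is the distance used for selection.

**Design pipeline.** Filters (aromatic halogen required, ≤ 20 heavy atoms,
reactive-substructure SMARTS, price ≤ $5/mg) → consensus solubility vote
(≥ 3 predictors must beat logS −2 below 16 heavy atoms, −1 for 16–22) →
pairwise distance matrix → greedy **MaxMin** diversity core → the 5 most
similar *satellite* compounds per core member (similar chemotype,
different halogen interface) → deterministic assembly ranked by vote
pass, predicted logS and price.

V_max values are read from a table of predicted/computed values when
available; otherwise a clearly-labelled additive surrogate anchored on the
halobenzene references (Cl 0.008, Br 0.016, I 0.025 au) supplies
ranking-plausible magnitudes.

## Worked example

```python
from halofrag import MoleculeRecord, VmaxProvider, molecule_similarity

provider = VmaxProvider()   # surrogate V_max (no table supplied)
a = MoleculeRecord.from_smiles("Clc1ccccc1", "a")
b = MoleculeRecord.from_smiles("Brc1ccccc1", "b")
print(molecule_similarity(a, b, vmax_provider=provider))
```

Running `examples/02_halogen_interface_similarity.py` prints:

```
chlorobenzene vs itself                    similarity = 1.0000
chlorobenzene vs bromobenzene              similarity = 0.7674
2- vs 3-chloropyridine                     similarity = 0.9222
chlorobenzene vs 4-nitro-iodobenzene       similarity = 0.6412
```

Identical interfaces score 1; the Cl→Br swap costs element agreement and
σ-hole closeness; the pyridine positional isomers stay similar (one ring
nitrogen shifted by one slot); element + tuning + substitution differences
compound. `examples/04_design_pipeline.py` runs the full pipeline on 300
synthetic fragments and prints the stage counts

```
{"after_filters": 272, "core": 20, "distance_matrix_n": 272,
 "final": 40, "input": 300, "satellite_candidates": 100}
```

— 300 candidates in, 272 past the filters, a MaxMin core of 20 grown to a
final library of 40 with satellites. The other examples cover fixture
generation, filtering/voting and library profiling (rule-of-three counts,
mean Fsp3, per-halogen V_max quartiles).

## Command line

```sh
halofrag fixtures --seed 0 --count 300 --out frags.smi
halofrag filter --input frags.smi --out report.csv
halofrag distmat --input frags.smi --out d.csv
halofrag select --distmat d.csv --k 20 --out selection.json
halofrag run --config config.yaml --out results/
```

Every run writes a manifest (config hash, input digests, stage counts,
seeds); identical config and inputs reproduce byte-identical outputs.

## Layout

- `src/halofrag/` — `chemio` (I/O, standardization, fixtures),
  `descriptors` (molecular + node properties, ESOL, PMI shape),
  `featuretree`, `vmax`, `similarity`, `design`, `profiling`,
  `pipeline` + `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, formulas, parameter choices and limitations
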