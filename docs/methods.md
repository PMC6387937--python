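# Methods

This note documents the models and procedures implemented in `halofrag`,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## 1. Halogen configurations and the rooted feature tree

A *configuration* is one aromatic Cl, Br or I plus its central aromatic
ring. Fluorine is excluded: its halogen bonds arise only in rare
situations irrelevant to fragment screening. Aliphatic halogens never
form configurations (they are also removed by the reactive-substructure
filter as alkylating agents). The central ring is the **smallest**
aromatic ring (size 5–7) containing the halogen-bearing (ipso) atom; in a
fused system the remainder becomes a fused-flagged residue. A molecule
contributes one configuration per aromatic halogen — a dichloride has
two, each treating the other chlorine as an ordinary residue.

The tree rooted at a configuration has:

- a **core node**: ring size, atom-type multiset, and a
  direction-canonical element walk from the ipso atom;
- a **halogen node** annotated with V_max (see §3), childless;
- **residue slots**, one per non-ipso ring position, keyed by the offset
  o = shortest ring path from the ipso atom (two slots per offset except
  the antipodal position of even rings; Σ slots = ring size − 1). A slot
  holds a single hydrogen, a heavy-atom residue, or nothing (e.g. a
  pyridine-type nitrogen). Fused residues attached at two ring atoms
  occupy the lower-offset slot; the partner slot is empty.

Residues are decomposed one level deep into RING and LINKER child nodes
with pharmacophoric annotations (HBD = N/O bearing ≥ 1 H, HBA = any N/O,
POS/NEG = formal charge sign). Matching compares whole residues through
their property vectors; the children summarize internal structure rather
than being matched recursively, which keeps the measure focused on the
halogen-proximal interface.

## 2. Node properties

Six per-residue descriptors, all ≥ 0 and invariant under atom
renumbering. The descriptor families are classical; the exact functional
forms below are this package's fixed, versioned definitions (what the
similarity needs is reproducibility and sensible discrimination, not any
one historical parameterization):

1. **atom count** — all atoms including hydrogens.
2. **lone-pair index** — Σ over atoms of (lone pairs × Pauling χ), lone
   pairs from the standard valence model (N 1, O 2, halogen 3, S 2),
   adjusted by formal charge.
3. **proton–neutron information index** (bits) —
   A·log₂A − Σᵢ aᵢ·log₂aᵢ with aᵢ the mass number of the most abundant
   isotope and A = Σaᵢ; 0 exactly for single-atom residues.
4. **flexibility index** — (¹κ_α·²κ_α)/N on the residue's heavy-atom
   subgraph with the published Hall–Kier α corrections; defined 0 for
   N < 3. The unperturbed n-butyl residue gives (4·3)/4 = 3.
5. **edge connectivity** — Σ over adjacent bond pairs of
   (δ_e·δ_f)^(−1/2), δ = bond degree in the line graph; benzene gives
   exactly 3.
6. **group electronegativity** — geometric mean of Pauling χ over all
   residue atoms including hydrogens.

A single-hydrogen residue has the fixed vector (1, 0, 0, 0, 0, 2.20); the
empty residue is all-zero with electronegativity flagged undefined.

## 3. σ-hole magnitude (V_max)

Trees prefer **table values** (CSV: molecule, halogen atom, value in au,
isodensity surface tag 0.001 or 0.020 au). Two surfaces are never mixed
in one distance matrix or profile — that is enforced, since values on
different surfaces differ systematically.

Without a table entry, an **additive surrogate** supplies

```
V = baseline(X) + Σ_residues w_tune·(χ_group − χ_H)·γ_topo^(o−1)
               + Σ_ring-N  n_inc·γ_topo^(o−1)
```

with baselines Cl 0.008, Br 0.016, I 0.025 au (the unsubstituted
halobenzene references, reproduced exactly by construction), w_tune =
0.004 au per unit electronegativity excess, γ_topo = 0.5 per ring bond,
and n_inc = 0.006 au per pyridine-type ring nitrogen. The surrogate is a
*ranking-plausible stand-in*, not a trained predictor: it guarantees
I > Br > Cl at fixed substitution and monotone upward tuning by
electron-withdrawing groups, and every value is labelled
`origin=surrogate` in output. It does not reproduce quantum-chemically
computed magnitudes.

## 4. The similarity measure

For configurations a, b:

- **core**: atom-type multiset overlap Σmin/Σmax; multiplied by 0.6 when
  ring sizes differ (5- vs 6-ring; a soft rather than hard mismatch).
- **halogen**: element agreement (factor 0.5 on mismatch) ×
  exp(−|ΔV_max|/τ), τ = 0.01 au. If either V_max is flagged missing the
  term reduces to element agreement.
- **residues**: the slot lists of both trees, the shorter side padded
  with empty slots, scored pairwise — property-vector similarity
  Σ w_k·min/max (both-zero components count 1) × γ^|Δo| with γ = 0.7;
  hydrogen-or-empty against empty scores 1; a heavy residue against empty
  scores the floor (default 0) — and assigned optimally with the
  Hungarian algorithm, normalized by the larger slot count. The optimal
  value is invariant under argument order, so symmetry is exact; the
  solver is deterministic, so reruns agree bitwise.

Weights: node-property weights uniform (1/6), component weights
(w_core, w_X, w_res) = (0.2, 0.3, 0.5). These defaults are versioned and
every distance matrix embeds a parameter hash; no claim is made that they
equal the original empirical weighting, which was never published.

Molecule similarity = **max** over configuration pairs: two molecules
sharing one near-identical halogen interface are similar regardless of
their other configurations, which is the right convention for a selection
that wants distinct interfaces. D = 1 − sim is symmetric, zero-diagonal
and bounded in [0,1] but is *not* claimed to satisfy the triangle
inequality; MaxMin selection does not require it.

## 5. Filters, vote, selection, assembly

- **Structural**: remove molecules with zero configurations or > 20
  heavy atoms (boundary inclusive: 20 is kept).
- **SMARTS**: a shipped, editable list of reactive/unwanted groups (acyl
  and sulfonyl halides, anhydrides, epoxides/aziridines, aldehydes,
  Michael acceptors, iso(thio)cyanates, alkyl halides, diazo, peroxides).
  The original curation was never published; this list covers the usual
  fragment-screening offenders.
- **Price**: remove above $5/mg; the limit is read as inclusive (exactly
  $5.00 is kept). Missing prices remove by default (configurable).
- **Solubility vote**: pass iff ≥ 3 predictions are strictly better than
  logS −2 (HAC < 16, read strictly) or −1 (16 ≤ HAC ≤ 22). HAC > 22 is
  outside the rule's stated domain and raises rather than extrapolating.
  With fewer than six predictors supplied the vote count stays at 3 and a
  warning is logged.
- **MaxMin**: greedy; each step adds the candidate with the largest
  minimum distance to the selected set, ties broken by smallest id. The
  recorded pick order makes the step-wise max-min property assertable
  after the fact.
- **Satellites**: the n (default 5) nearest non-core molecules per core
  member, ties by id; a molecule may satellite several cores and is
  deduplicated at assembly.
- **Assembly**: core first, then satellites ranked by (vote pass, median
  predicted logS descending, price ascending, id) up to the capacity.
  This deterministic ranking is an explicit stand-in for the manual
  expert sub-selection by affordability and solubility; it is labelled as
  such in the selection output.

The vote is applied at assembly by default (matching the narrative order
of selection-then-subselection); a pre-filter stage placement is
available in config.

## 6. Molecular descriptors and profiling

HBA = N/O count and HBD = N/O-with-H count (donor *atoms*, not donor
hydrogens); RDKit's stricter definitions are selectable as the `rdkit`
preset, since published fragment-library characterizations mix toolkits
and the counts are dialect-sensitive. Rotatable bonds use the strict
(non-amide) definition; TPSA is Ertl's method; clogP is Crippen's; Fsp3 =
sp³ carbons / carbons (defined 0 with a warning for carbon-free input).
The built-in solubility estimate is Delaney's ESOL regression
logS = 0.16 − 0.63·clogP − 0.0062·MW + 0.066·RB − 0.74·AP (AP = aromatic
heavy-atom fraction).

Shape uses one ETKDG conformer per molecule (fixed seed) with MMFF
minimization; NPR1/NPR2 place each molecule in the rod–disc–sphere
triangle. Embedding failures are reported and excluded from shape
statistics. V_max profiles report per-element min/Q1/median/Q3/max with
linear-interpolation (type-7) quartiles — stated because quartile method
changes box plots — against the halobenzene reference lines.

The rule-of-three report counts violations per rule independently
(MW > 300, clogP > 3, HBD > 3, HBA > 3, RB > 3) plus the fully compliant
count, and TPSA > 60 / > 90 Å² counts.

## 7. Synthetic study conditions

The fixture generator enumerates 8 small (hetero)aromatic scaffolds
(benzene, pyridine, pyrimidine, pyrazine, pyrrole, imidazole, thiophene,
furan) × halogen placement (Cl/Br/I) × one further ring substituent from
a 12-member set spanning donors, acceptors, EWGs and a phenyl, then
deterministically samples the requested count. The default conditions —
300 fragments, MaxMin core of 20, 5 satellites, capacity 40 — are a
scaled-down vendor-catalogue scenario (the original campaign filtered a
catalogue to 2,685 candidates and picked a core of 150, growing to ~200);
the scaling keeps the full pipeline comfortably fast on one CPU while
exercising every stage at meaningful size. Synthetic price tables
(lognormal $/mg with a tail above the cap) and prediction tables (ESOL
plus five seeded-noise pseudo-predictors, σ = 0.5 log units) emulate the
external tables a real run ingests.

What the fixtures do **not** emulate: real vendor chemotype clustering
and multi-substituent decoration, true inter-predictor disagreement
structure, tautomer/protonation-state multiplicity (inputs are taken as
drawn; state enumeration is out of scope), and quantum-chemical V_max
distributions. Passing tests therefore demonstrate correctness and
determinism of the machinery, not that a particular vendor catalogue
would yield a particular library.

## 8. Numerical and degenerate-input conventions

- Similarity symmetry is exact because both orientations score the same
  padded matrix (transposed) and the assignment optimum is
  order-invariant; the distance matrix additionally computes each
  unordered pair once.
- Property-ratio 0/0 counts as agreement (1), so hydrogen residues match
  each other perfectly at equal offsets.
- Kier flexibility clamps at 0 when α-corrections would drive the
  product negative on tiny residues; disconnected residue subgraphs are
  rejected.
- Salt stripping keeps the fragment with most heavy atoms, ties broken
  lexicographically by canonical SMILES; standardization is idempotent.
- Stereochemistry in input SMILES is preserved but plays no role in the
  similarity measure (the node properties are constitution-level).
- Manifests exclude wall-clock time (it goes to the log stream), so a
  rerun under identical config and inputs is byte-identical — that is
  the reproducibility contract, checked by test and acceptance script.
- Fixture sampling, synthetic tables and conformer embedding all derive
  from explicit seeds; no global RNG state is used.

## 9. Known limitations

- The V_max surrogate is ordinal, not quantitative; comparisons against
  computed σ-hole magnitudes require a supplied table.
- The empirical weighting of the original similarity measure is
  unpublished; defaults here are uniform/round numbers, recorded by hash.
- Residues are matched as whole subtrees; deep internal rearrangements
  of a large residue are only visible through its property vector.
- The published 198-fragment showcase library is not redistributable, so
  its characterization check runs only when the user supplies the
  supplementary SMILES file under `data/SM1_heflib.smi`.
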