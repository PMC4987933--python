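# Methods

## Model

A protein–small-molecule complex is treated as a labelled geometric
graph: heavy atoms are nodes carrying one or more of eight pharmacophore
classes, and pairwise Euclidean distances are the edge attribute. The
feature vector is a *cutoff scan*: for each unordered class pair and each
cutoff on a regular distance grid, the cumulative count of atom pairs at
or below that cutoff. Two blocks are computed — pairs among binding-pocket
atoms (protein heavy atoms within `pocket_radius` of any ligand heavy
atom, closed boundary) and pocket-atom × ligand-atom cross pairs — and a
fixed twelve-descriptor ligand physicochemical panel is appended.
Affinity, expressed as pK = −log₁₀(K_D|K_i) in molar units, is regressed
on this vector with an exact Gaussian process.

Assumptions worth stating explicitly:

- The signature is purely distance-based. It is invariant to rigid motion
  and atom ordering by construction, and deliberately sensitive to
  geometry (scaling coordinates changes it); it encodes no interaction
  typing (no H-bond geometry checks, no π-stacking detection) and no
  solvation terms.
- An atom may carry several classes (a carboxylate oxygen is both
  negative and an acceptor). A pair of atoms increments every unordered
  class combination admitted by the two class sets, each exactly once.
- Cleanup mirrors the curated-benchmark convention: waters (HOH/WAT/DOD)
  are removed, all heteroatom groups except the designated ligand are
  discarded, the first MODEL of a multi-model file is used, and alternate
  locations resolve to the highest-occupancy copy (tie → altloc 'A', then
  first seen). Hydrogens are parsed but excluded from signatures by
  default, since deposited structures carry them inconsistently.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `pocket_radius` | 8.0 | Å | binding-site environment radius; generous enough to include second-shell contacts |
| `d_min`, `d_max`, `step` | 1.0, 30.0, 0.5 | Å | dense short-to-medium-range scan in the cutoff-scanning lineage; 59 cutoffs × 36 class pairs × 2 blocks + 12 descriptors = 4260 features |
| `normalize` | raw counts | — | cumulative counts; a per-paircount option divides by total pairs for scale robustness |
| `bond_tolerance` | 0.45 | Å | slack over summed covalent radii in geometric bond perception; permissive for crystallographic error |
| GP kernel | RBF + white noise | — | smooth, noise-aware default; `rbf` (noise-free) and `matern52` available |
| `length_scale_init` | √(n_features) | — | median-distance heuristic for standardized features; tuned by marginal likelihood from there |
| `noise_init` | 0.1 | pK | ~0.3² pK² initial noise variance scale |
| target normalization | off | — | pK labels already live on a well-scaled ~2–12 range |

Feature standardization is fit on training data only (per fold during
cross-validation), so there is no leakage into held-out predictions.

## Pharmacophore typing

Protein atoms are typed by a versioned plain-text (residue, atom) table
(`protein_typing_v1.tsv`) constructed from standard amino-acid chemistry:
carboxylate side-chain oxygens negative + acceptor, lysine NZ and the
arginine guanidinium positive + donor, aromatic-ring carbons aromatic +
hydrophobic, histidine treated as an aromatic donor/acceptor (not
positive — no pH model), cysteine/methionine sulfur (selenomethionine SE
mapped likewise). Unknown (residue, atom) pairs fall back to element
rules with a warning. Ligand atoms, which carry no chemistry in HETATM
records, are typed from the perceived bond graph: planar 5/6-membered
C/N/O/S rings are aromatic (planarity ≤ 0.15 Å from the best-fit plane);
terminal oxygens on a C/P/S centre bearing ≥ 2 terminal oxygens are
negative (carboxylate/phosphate/sulfate at physiological pH); other
oxygens are acceptors; amide-like nitrogens are donors, other
non-aromatic nitrogens positive + donor; carbons and halogens default to
hydrophobic; anything unmatched is neutral. Typing is a pure function of
identity and bonded environment, so it is rigid-motion invariant.

Because a model is only valid under the typing table it was trained
with, trained-model files record the table version and refuse to load
under a different one.

## Ligand descriptors

Descriptors are evaluated with RDKit on a molecule built from the
geometric bond graph. Two heuristics recover chemistry lost in the
heavy-atom record: a terminal oxygen within 1.28 Å of its C/P/S centre
becomes a double bond (one per centre, shortest first; remaining short
terminal oxygens get formal charge −1), and geometrically aromatic rings
are marked aromatic. Hydrogens are inferred implicitly from valence.
When an SDF/MOL2 sidecar is supplied its explicit bonds override
perception. The twelve-descriptor panel is a declared reconstruction of
the standard graph-computable physicochemical set; the schema names each
descriptor so retraining under a different panel is explicit.

## Synthetic data

The generator emulates only what the code paths need: real residue and
atom names (ALA/LYS/ASP/PHE/SER with idealized internal geometry) on a
seeded random shell around a ligand template (benzene, acetate,
neopentane — literature bond lengths), optional waters and sulfate
decoys for cleanup tests, everything reproducible from one seed recorded
in a REMARK header. The first residue is placed exactly at the shell
radius so the pocket is never empty. Template distances avoid values on
the default cutoff grid, so bitwise invariance checks are well-posed.

Labelled datasets draw per-complex geometry (4–8 residues, shell radius
4–7 Å, random template) and label each complex with a declared linear
model over true signature features — cross-block contact counts at 6–10 Å
plus a pocket-density term — with intercept 2.0 and Gaussian noise
(default 0.3 pK). The weights were chosen once so labels span roughly
2–12 pK, the dynamic range of curated affinity sets. What passing
recovery tests shows: the featurization → GP pipeline can recover a known
signal of realistic magnitude from realistic-looking files. What it does
not show: anything about real binding physics — the toys have no chemistry
beyond the rules above, no conformational strain, no solvation, and the
true model is linear by construction.

## Numerical choices

- Distances are double-precision Euclidean values between atom centres;
  bin membership is `d ≤ c` with no tolerance. Cumulative counts are
  computed by sorting distances and `searchsorted` against the grid,
  which is exactly equivalent to the per-cutoff recount.
- Rigid-motion invariance is bitwise for the in-memory transform
  (`transform_complex`); the text-level `rigid_transform` rewrites
  fixed-width PDB fields and thus quantises coordinates to 0.001 Å, which
  can legitimately move a pair across a cutoff lying within ~2 mÅ of its
  distance. Invariance claims are therefore stated for the exact
  transform.
- Ligand atoms are canonically ordered (by atom name) at selection time,
  so descriptor sums do not depend on file record order even at the
  last-ulp level.
- Cross-validation folds are a seeded shuffle + round-robin partition
  (sizes differ by ≤ 1). A no-skill GP can collapse to a constant
  out-of-fold prediction (e.g. under permuted labels); `cross_validate`
  reports zero correlation for that case rather than refusing, while the
  bare `pearson`/`residual_sd` functions treat constant input as a
  contract violation.
- Residual SD follows the benchmark convention: the standard deviation of
  observed affinities about the least-squares line on predictions, n−2
  denominator. The Fisher r-to-z test is two-sided; the F-test on
  residual SDs (n−2 degrees of freedom per side) is one-sided by default
  with a two-sided flag — the pairing under which both tests reproduce
  the published significance pattern among scoring-function summaries on
  the common 195-complex blind test.
- Censored affinity labels ('<', '>', '~') and IC50 entries are excluded
  from training by default (flags admit them), matching the
  refined-set convention of exact K_i/K_D measurements.

## Design choices that were genuinely open

- **Pocket-internal block**: only pocket–pocket pairs are counted (not
  all protein pairs within the sphere); the cross block pairs pocket
  atoms with ligand atoms. Both blocks share one grid.
- **Class pairs are unordered** (36, not 64): atom pairs are undirected.
- **Multi-label typing** rather than one class per atom; counting per
  admitted class combination.
- **Ligand designation**: with no key given, the heteroatom group with
  the most heavy atoms wins (tie → chain, then residue number) and the
  choice is recorded in the prediction output; multi-ligand structures
  can be resolved explicitly via `ligand_key`.
- **Problem sizes in validation**: oracle-equivalence runs use 100 small
  toys (3–5 residues), invariance 10 toys × 20 motions, recovery 200
  complexes with 10-fold CV and a permutation null at 100 — sizes chosen
  to exercise every code path at full statistical contrast while keeping
  the whole validation suite a few minutes on one CPU.

## Known limitations

- Exact GP training is O(n³); fine to a few thousand complexes, no
  sparse approximation provided.
- Geometric bond perception cannot distinguish protonation states or
  tautomers, and bond orders beyond the carbonyl/aromatic heuristics
  default to single; an SDF sidecar is the remedy when bond orders
  matter.
- Covalently linked heteroatom groups (glycans, covalent ligands) are
  not distinguished from non-covalent ligands.
- No mmCIF input, no assembly generation, no protonation or side-chain
  repair.
- Models trained on curated benchmark data are only as good as that
  data's curation; the package ships no trained weights.
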