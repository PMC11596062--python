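# abcbind

Consensus cardenolide binding-region selection from multi-ligand docking
poses, with Michaelis–Menten kinetics for experimental cross-validation.

## The problem

ABCB transporters (P-glycoproteins) are candidate carriers for
cardenolides — steroid glycoside plant toxins such as ouabain and
digoxin — in cardenolide-adapted insects. Docking several cardenolides
into one transporter model yields a handful of poses per ligand, and the
question is whether the different ligands converge on **one** binding
region. Because the cardenolides differ in their sugars and
substituents, poses can only be compared over the aglycone they share:
the tetracyclic steroid nucleus plus the butenolide (lactone) ring,
25 heavy atoms in all.

`abcbind` implements the two-step consensus search over such pose sets,
plus the kinetics side needed to confront the in-silico prediction with
ATPase assay data:

1. **Steric congruence.** For two poses with corresponding scaffold
   atoms $A_i$, $B_i$ ($i = 1..N$) in the shared receptor frame, the
   scaffold RMSD is

   $$\mathrm{RMSD} = \sqrt{\tfrac{1}{N}\sum_{i=1}^{N} \lVert A_i - B_i \rVert^2}$$

   with **no superposition** — the placement in the receptor is the
   signal. All poses enter an all-vs-all matrix; every *constellation*
   (one pose per ligand) is ranked by its mean pairwise scaffold RMSD
   and the top 15 are kept.

2. **Interaction similarity.** For a constellation with $B_{total}$
   residue-level protein–ligand interactions of which $B_{similar}$
   recur in ≥ 2 distinct ligands' member poses (matching residue and
   interaction class), the similarity factor is

   $$S_f = B_{similar} / B_{total} \in [0, 1].$$

   Among the top-15 congruent candidates, the $S_f$ maximum is chosen
   ($S_f$ has priority over RMSD rank; ties fall back to lower mean
   RMSD). Docking scores are echoed in reports but never used for
   ranking.

3. **Kinetics.** Vanadate-sensitive ATPase activity (paired ±500 µM
   orthovanadate differencing) is fit with
   $v = V_{max} S / (K_m + S)$ by bounded nonlinear least squares;
   whole curves are compared with the extra-sum-of-squares F-test; and
   per-substrate deltas of docking score and $K_m$ between two
   transporters are tabulated to compare predicted with measured
   substrate specificity.

A synthetic-data module generates the full study design with known
ground truth — 5 ligands × 9 models with one planted consensus pose per
ligand, geometry-consistent interaction tables, and noisy paired
dose–response data — for recovery testing.

## Worked example

```sh
abcbind simulate --outdir demo --seed 7   # synthetic 2-transporter workspace
abcbind all --workspace demo --outdir out
cat out/transporter1/selection.txt
```

```
chosen constellation: index 1
mean scaffold RMSD: 1.223 A
interactions: 20 similar of 30 total, Sf = 0.67
  cymarin: model 9, docking score -7.9 kcal/mol
  digoxin: model 2, docking score -9.1 kcal/mol
  frugoside: model 1, docking score -8.1 kcal/mol
  oleandrin: model 4, docking score -9.9 kcal/mol
  ouabain: model 9, docking score -8.4 kcal/mol
```

The chosen constellation is the planted one: its members sit ~1.2 Å
apart on the shared scaffold (the decoys are ≥ 5 Å away), and 20 of
their 30 recorded interactions recur across ligands (the 4 shared
binding-site residue keys on each of the 5 planted poses), giving
Sf = 20/30 ≈ 0.67, the maximum among the top-15 candidates.

`out/delta_report.tsv` then contrasts the two synthetic transporters:

```
substrate  score_t1  score_t2  km_t1   km_t2   delta_score  delta_km
digoxin    -9.1      -9.0      34.21   10.22    0.1         -23.99
ouabain    -8.4      -9.0      51.21    8.40   -0.6         -42.81
...
```

Negative `delta_km` means transporter 2 reaches half-maximal velocity
at lower substrate concentration (higher apparent affinity); a more
negative `delta_score` predicts the same direction from docking. The
fitted Km values recover the generator's ground truth (33.73 and
9.33 µM for digoxin) within noise.

The same stages are available as library functions
(`abcbind.pairwise_matrix`, `abcbind.select_constellation`,
`abcbind.fit_michaelis_menten`, …) and as individual subcommands
(`congruence`, `select`, `kinetics`, `redock`).

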