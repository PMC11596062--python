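# Methods

## Scaffold correspondence

Cross-ligand RMSD requires an atom-level bijection between every pose
and a common scaffold. The shipped template holds the 25 heavy atoms of
the cardenolide aglycone: the 17 gonane ring carbons C1–C17, the
angular methyls C18/C19, the butenolide carbons C20–C23, the lactone
ring oxygen and the carbonyl oxygen. This composition is a
reconstruction — "steroid structure plus lactone ring" fixes the count
but not the exact member list — and is therefore configurable rather
than hard-coded; any connected template with per-atom elements and
bonds can replace it.

Two correspondence modes exist. `by_name` looks template labels up via
a per-ligand name map (identity for the shipped synthetic files) and is
the default because it is deterministic and auditable. `by_graph`
perceives pose connectivity from interatomic distances (single-bond
covalent radii + 0.45 Å tolerance — wide enough for strained docked
geometries, narrow enough that the shortest non-bonded contact of an
embedded scaffold, ≈ 2.2 Å, is never misread as a bond) and matches the
template as an element-labelled induced subgraph. Sugar and substituent
atoms bond only to unmapped neighbours and therefore never enter the
core. The shipped template graph has a trivial automorphism group, so
its embedding is unique whenever it exists; for symmetric templates all
embeddings are enumerated, geometrically distinct ones raise an error,
and coincident ones are tie-broken by the lexicographically smallest
pose-serial sequence (logged).

Hydrogens are parsed but excluded from every RMSD.

## Congruence

Scaffold RMSD is computed in the raw shared receptor frame; no Kabsch
superposition and no symmetry-corrected RMSD (a `superpose=True` option
exists for diagnostics only). Matrix cells keep full precision in
memory and are rounded to 3 decimals only at TSV serialization. The
redocking validation uses the same statistic over a named atom subset
(31 heavy atoms for ATP) with a congruence threshold of 4 Å, exposed as
a named config default.

## Constellation enumeration and ranking

A constellation's score is the arithmetic mean over **all** C(L,2)
member pairs (not pairs-to-a-reference); "compared with each other"
favours the all-pairs reading. Full enumeration is the default and caps
at 10⁶ combinations (the design case, 9⁵ = 59,049, is trivial); beyond
the cap a beam search over ligands (default width 50) prunes partial
assignments by their accumulated pair sum. Beam results recompute final
sums in the canonical pair order so that, where both are feasible, beam
and full enumeration agree bit-for-bit; this equivalence is
property-tested. Sorting is ascending mean RMSD with ties broken by the
lexicographic member tuple, and the constellation index is the 1-based
rank under this sort — a convention of this package; published
constellation numberings based on heat-map positions are not
reproducible from ranks and are never claimed.

## Similarity factor

A record's key is (chain, residue number, residue name) plus the
interaction class in the default `residue_and_class` mode ("occurrence
**and type** were compared"); `residue_only` is a documented coarser
option and can only merge keys, so its Sf dominates (property-tested).
"Proposed in multiple ligand models" is read as: the key occurs in the
member poses of ≥ 2 **distinct ligands**. Each record counts once in
B_total and once in B_similar when its key qualifies — this reading
reproduces all fifteen printed similar/total/Sf triples of the
self-consistent reference block at two decimals. Report rounding is
half-up (10/16 → 0.63, not banker's 0.62) to match the printed values;
full precision is kept internally. A published companion block for the
second transporter is internally inconsistent with Sf = B_similar/B_total
(e.g. 22/30 printed as 0.79) and is not used as ground truth.

The bond-class summary counts records per interaction class; the
H-bond/alkyl ratio is (conventional + carbon H-bonds)/(alkyl + pi-alkyl)
and is reported as absent when the denominator is zero.

## Selection

Among the top-k (default 15) congruent candidates the Sf maximum wins;
ties fall back to lower mean RMSD, then lower index. This is a strict
priority, not a weighted composite — the smallest faithful reading of
"Sf has higher priority than RMSD". Docking scores never enter the
ranking; they are echoed per member in the report. With no interaction
records at all the selection degenerates to the congruence rank-1
constellation with a logged warning; a record-less individual candidate
scores Sf = 0.

## Kinetics

Transporter ATPase activity is isolated as the paired difference
(no vanadate) − (500 µM vanadate) per concentration and replicate.
Negative differences are retained — truncation would bias the fits
upward — and flagged in the log.

The Michaelis–Menten fit uses bounded (positive-parameter) nonlinear
least squares with relative tolerance 1e−8 and at most 10⁴ function
evaluations; start values are Vmax₀ = max(v) and Km₀ = the smallest S
whose activity reaches Vmax₀/2. Standard errors come from the curvature
of the squared-error surface at the optimum (Gauss–Newton covariance);
on exactly-fitting data the curvature-based SE degenerates to 0.
Calibration under the default synthetic conditions (5 % noise, 7-point
grid, 5 replicates) is verified by Monte-Carlo: |Km − truth| ≤ 2 SE in
≥ 90 % of simulations and mean Km bias < 10 %.

Whole curves are compared with the extra-sum-of-squares F-test between
the pooled fit (shared Vmax, Km) and separate fits (both freed, so the
numerator df is 2; denominator df is n_A + n_B − 4). The published
analysis names only its plotting software and the df pair, so this
construction is an interpretation consistent with that df structure.
With identical noiseless inputs RSS_separate = 0 and F is defined as 0.

The delta table reports per-substrate differences (transporter 2 −
transporter 1) of docking score and Km; Km-less, docking-only
substrates carry an empty Km delta. Deltas are computed, never copied:
one published delta-Km entry (−35.51 µM for ouabain) conflicts with its
own printed per-transporter Km values (7.05 − 48.56 = −41.51); the
package always reports the arithmetic difference and the internally
consistent digoxin case (−24.40 µM) is the one asserted in tests.

## Synthetic data

The generator reproduces the study design: 5 ligands × 9 models. Per
ligand one *planted* pose is the scaffold placed at a shared site with
per-coordinate Gaussian jitter σ_in = 0.5 Å (typical sub-Å spread of a
converged docking cluster); the remaining 8 are decoys, randomly
rotated and displaced by 5–20 Å (outside the site but inside a
transporter-sized cavity). Since rotation preserves a pose's centroid,
a decoy's scaffold RMSD to any planted pose is bounded below by its
≥ 5 Å centroid shift, while planted–planted RMSD concentrates near
σ_in·√6 ≈ 1.2 Å — the planted constellation is congruence rank 1 by
construction margin, and recovery failures can only come from
implementation defects, which is the point of the test.

Interaction tables are proximity-consistent: the 4 shared binding-site
residue keys (lysine/glutamine H-bond donors and
alanine/phenylalanine/valine hydrophobic contacts, the residue flavour
of cardenolide–transporter interfaces) appear on planted poses only;
every pose also gets 2 private keys with globally unique residue
numbers, so decoy constellations score Sf = 0 and the planted one
20/30 ≈ 0.67. Docking scores are drawn independently of geometry and
the planted pose is **never** the best-scored model of its ligand — any
selection shortcut through scores would fail the recovery tests.

Dose–response data use the 0–800 µM grid with 5 replicates and Gaussian
noise of 5 % of Vmax; the vanadate arm models complete inhibition
(baseline + noise), so the paired difference recovers the MM curve
exactly in expectation. Demo kinetic truths (e.g. Vmax 12.54, Km
9.33 µM) are realistic magnitudes for these assays, not fitting
targets.

What the synthetic tests do **not** show: recovery on real docking
output, where decoys can cluster near the true site, interaction
detection is noisy and correlated with geometry, scores are not
independent of placement, and vanadate inhibition is partial. The
generator is a correctness harness for the pipeline's logic, not a
docking-realism model.

## Problem sizes and numerical conventions

Default test and demo sizes are the study design itself (5×9 poses,
59,049 enumerated constellations, 200-replicate Monte-Carlo batches for
kinetics calibration, 100-seed recovery batches), which keep the whole
suite in the order of a minute. Coordinates are Å everywhere, scores
kcal/mol, activities nmol Pi/mg protein/min, concentrations µM; no unit
conversion exists anywhere in the package. All randomness flows through
explicit integer seeds; every generator is a pure function of
(parameters, seed) and regenerates byte-identical files.

## Known limitations

- No geometric interaction detection: interaction tables are inputs
  (or synthetic); the pipeline trusts their residue assignments.
- No mmCIF input, no receptor topology beyond residue identities, no
  charge handling (PDBQT charges are parsed and discarded).
- The beam search has no optimality guarantee below the width at which
  it is provably exact; it is validated empirically against full
  enumeration.
- Kinetic SEs are asymptotic (local curvature); with few points or high
  noise, profile-likelihood intervals would be more honest.
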