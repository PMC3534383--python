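# Methods

## Temperature-factor encoding of local accuracy

The B-factor of an atom oscillating isotropically with mean-square
displacement ⟨u²⟩ is B = 8π²⟨u²⟩. `mrprime` repurposes this relation in
reverse: a *positional error estimate* u (Å) for an atom of a search model
is written into its B column as B = 8π²u², so that MR programs that damp
atomic contributions by B treat unreliable atoms as smeared density.

Two bounds are enforced on output (both configurable):

* `B_FLOOR = 2.00 Å²` — a zero B makes an atom an infinitely sharp
  scatterer, which downstream refinement/MR programs handle badly; 2 Å² is
  a conservative crystallographic floor.
* `B_CAP = 999.99 Å²` — the PDB B column is fixed-width `%6.2f`.

The transform is exact (ratio 8π² to machine precision) between the
boundary values u ≈ 0.159 Å and u ≈ 3.56 Å.

## Search-model variants

The variant factory composes four primitive operations — side-chain
stripping, polyalanine conversion, uniform-B assignment, and profile
application — into the ten standard variants (`ALL_20` … `POLYALA_20`,
see the README table). Conventions where the construction is genuinely
open:

* Polyalanine models keep an existing CB and never fabricate one (glycine
  stays {N, CA, C, O}); fabrication would require ideal-geometry placement,
  which is out of scope. Template B-factors are preserved in `POLYALA`
  (only `POLYALA_20` resets them), since original template B-factors are
  themselves informative for MR.
* `per_residue_ca` application broadcasts the C-α deviation of a residue
  to all of its atoms — the form required when the accuracy source
  (a C-α-only predictor) says nothing about side chains.
* PDB input: first model, first chain; hydrogens dropped; for alternate
  conformers the highest-occupancy atom wins (ties: first encountered).
  Occupancies pass through untouched.

## Insertion trimming

Model residues not mapped by the target alignment form insertion runs;
maximal runs longer than 8 residues are deleted, shorter runs kept.
Insertions are where comparative models err most, and retaining long
unalignable stretches actively harms MR searches. Terminal overhangs count
as runs and obey the same threshold. The threshold is a `RunConfig` field.

## Superposition and quality measures

All superpositions are least-squares rigid fits (Kabsch via SVD, proper
rotation enforced). Collinear point sets are rejected as degenerate.

* **Deviation profiles** come from a *single global fit* over all mapped
  C-α pairs; per-residue u is the post-fit C-α distance, per-atom u the
  distance for name-matched atoms. One documented convention, used
  everywhere (consensus distances use it too).
* **cRMSD** is the RMSD of mapped C-α pairs under the optimal fit.
* **GDT_TS** is 100 × the mean over cutoffs {1, 2, 4, 8} Å of the largest
  fraction of mapped C-α pairs that any examined rigid fit brings within
  the cutoff. The subset search is deterministic: up to 10 mapped pairs,
  every subset of size ≥ 3 is fitted directly (a few hundred 3×3 SVDs),
  making the search exhaustive at toy scale; above that, fits are seeded
  from sliding windows of lengths 3/5/7 plus the full set and refined by
  iterative re-selection (superpose on the current subset, re-select pairs
  within the cutoff, repeat to a fixed point, ≤ 10 iterations). Window
  seeding alone demonstrably misses ~2% of toy optima, which motivated the
  exhaustive small-n branch. Since the full-set fit is always examined,
  GDT_TS is never below the single-global-fit bound. Distance comparisons
  use a 1e-9 Å tolerance to avoid float-boundary flapping.
* **MR success** (evaluation-side proxy): residues sharing a seq_index
  anchor the superposition of the rebuilt model onto the target; the
  coverage fraction counts target residues whose C-α is matched one-to-one
  (greedy, nearest pair first) by a rebuilt C-α within 3.0 Å. Success is
  fraction ≥ 0.5 — "at least half of the chain built", boundary inclusive.
  The 3.0 Å match tolerance is a declared proxy parameter (configurable);
  the underlying benchmark criterion says nothing about match tolerance.

## Consensus (3D-Jury) scoring

Given ≥ 2 alternative models of one target, models are ranked by a base
score and the top ceil(0.15 · N) (minimum 2, ties broken by model id) are
compared all-against-all. For top model j and residue i,

S_ij = (1/(N−1)) Σ_{k≠j} d_ijk,

where d_ijk is the C-α distance of residue i between models j and k after
*pairwise global* superposition over their common residues. Residues
missing from some partner are averaged over the available pairs
(denominator adjusted); imputing a penalty distance was rejected as
unanchored. Note that S is a property of the ensemble: adding duplicate
models changes it (a duplicate contributes d = 0 against its twin), which
is the behaviour the defining formula forces.

The base scorer is a pluggable `model_id → scalar` contract. The default —
negative mean all-against-all consensus distance — is a self-contained
structural ranking for when no external single-model quality estimate is
available; any external ranker can be supplied as a TSV.

When a consensus profile is transferred to a model that contains residues
the consensus never scored, those residues default to the model's largest
S (unscored = least trusted; configurable).

## The MR-success predictor

Features are opaque scalars extracted from a profile alignment; the five
column-count features are cumulative with *inclusive* thresholds
("at least 1.5" etc.), so ge_1.5 ≤ ge_0.5 ≤ ge_−0.5 ≤ ge_−1.5 and
ge_−1.5 + below_−1.5 = aligned_columns. This last identity makes the
saturated 10-feature design exactly collinear — the likelihood is still
identified, so the saturated fit falls back to L-BFGS when Newton's
Hessian is singular, and the first elimination step removes a redundant
column at p ≈ 1. Sequence identity is accepted as fraction or percent and
normalized to fraction.

* **Backward elimination**: drop the feature with the largest p-value
  while it exceeds α = 0.05; significance by likelihood-ratio test per
  feature (Wald z as a config option); ties broken alphabetically for
  determinism. Features enter unstandardized.
* **LOOCV** refits the *entire* procedure — elimination included — on each
  leave-one-out fold (honest cross-validation); a flag reuses the globally
  selected feature set instead for the cheaper classical variant. Folds
  are deterministic and permutation-equivariant.
* **ROC**: curve points at every distinct score threshold; AUC is the
  Mann–Whitney statistic with half-credit for ties (verified against
  brute-force pair enumeration). The operating threshold minimizes the
  Euclidean distance to the (FPR, TPR) = (0, 1) corner; ties prefer the
  higher (more conservative) threshold.
* **Hanley–McNeil**: per-curve variance from the Q1/Q2 approximation; for
  paired designs the correlation term is the average of the within-class
  Pearson correlations of the two score vectors (an explicit approximation
  to the published table lookup). Two-sided z-test at α = 0.05.
* Positives are "solved by MR" throughout.

## Synthetic generators

All generators are pure functions of (parameters, seed); a single
`numpy.random.default_rng` stream per call.

* `make_native` builds a persistent self-avoiding C-α walk (step exactly
  3.8 Å, non-neighbour clash distance 3.5 Å with stepwise relaxation if
  stuck) and decorates each residue with N/C/O (and CB except glycine) at
  fixed offsets in a local frame. This is *not* Ramachandran-valid
  geometry: it is sufficient for superposition, GDT, consensus and
  B-encoding arithmetic, and nothing else is claimed for it.
* `make_decoy` adds isotropic per-atom Gaussian noise with per-residue σ
  and returns the realized displacements as ground truth (recorded before
  superposition, so measured deviations recover them only up to
  superposition effects — empirically ±0.1 Å on 100-residue structures
  when a single residue is perturbed).
* `make_ensemble` draws one decoy per σ with base score −σ, giving a known
  ranking.
* `make_feature_table` draws features in plausible ranges with the
  cumulative-count invariant enforced by construction (four sorted
  uniforms scaled by the column count) and labels from the specified
  logistic model.

Real comparative-model error is structured (alignment shifts, loop
rebuilding, domain motions), not isotropic noise. Passing the recovery
tests therefore shows the *estimators* are correct and calibrated on known
ground truth; it does not certify performance on real decoy ensembles,
whose error correlations the generator deliberately does not emulate.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with tight oracles: 200 random ≤ 8-residue instances for the
exhaustive GDT comparison, 50 random rigid motions for invariance checks,
20-seed ensembles of 10 × 100-residue decoys for consensus rank recovery,
n = 5000 × 20 seeds for coefficient recovery (observed bias ≈ 1–2%,
asserted < 15%), n = 2000 for elimination-support recovery, n = 150 for
the LOOCV-vs-resubstitution comparison, and 100 random alignments for the
trimming oracle. Benchmark success ratios are recomputed from solved-case
counts (e.g. 190/615 → 30.9%) with ratios reported to one decimal and
relative changes as integer percentages.

## Known limitations

* Single-chain models only; no mmCIF, no multi-chain assemblies, no
  side-chain rebuilding.
* GDT above 10 mapped pairs is a heuristic; it is validated exhaustively
  only at toy scale and is a documented stand-in for the reference
  implementations' unspecified search schedules.
* The MR-success criterion is geometric; no crystallographic software is
  invoked anywhere, and solved flags from real pipelines should be
  supplied externally via the manifest.
* The consensus base-scorer default is itself a clustering criterion, so
  fully independent single-model ranking requires an external scorer.
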