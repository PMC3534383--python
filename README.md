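# mrprime

Search-model preparation and evaluation for **Molecular Replacement (MR)**,
the crystallographic phasing technique that places a homologous model in the
asymmetric unit to approximate the missing phases. MR lives or dies on the
quality of the search model — and in particular on *where* the model is
wrong. `mrprime` makes comparative models more useful for MR by encoding
their **local accuracy** into atomic temperature factors, so that MR
programs which weight atoms by B-factor (MOLREP, AMoRe) automatically
down-weight the unreliable regions.

It is written for structural bioinformaticians and crystallographers who
prepare search models from comparative modelling pipelines, and for method
developers who need reference implementations of the associated quality
measures.

## What it computes

**B-factor encoding of positional error.** An atom believed to sit *u* Å
from its true position is assigned

```
B = 8 π² u²      [Å²]
```

clamped to the writable PDB range [2.00, 999.99]. The deviation *u* can be
*real* (measured against a reference structure) or *predicted* (by a
consensus model-quality assessment).

**Ten search-model variants.** All-atom / backbone-only / polyalanine
models, each with uniform B = 20 or with accuracy-derived B, per atom or
broadcast from the residue's C-α — the standard grid for testing how much
local accuracy information helps MR (`ALL_20`, `ALL_IDEAL`, `BACKBONE_20`,
`BACKBONE_IDEAL`, `ALL_CA_IDEAL`, `BACKBONE_CA_IDEAL`, `MQAP_EVAL`,
`MQAPCLUST_EVAL`, `POLYALA`, `POLYALA_20`). Insertions longer than 8
residues relative to the target alignment are trimmed before variant
construction.

**Model quality.** Sequence-dependent Kabsch superposition; per-residue and
per-atom deviation profiles; C-α RMSD; GDT_TS (mean over cutoffs
{1, 2, 4, 8} Å of the largest C-α fraction superposable within the cutoff,
×100); and the geometric MR-success criterion (at least half of the target
C-α chain rebuilt).

**Consensus (3D-Jury) scoring.** For an ensemble of alternative models the
top-ranked 15% are compared pairwise; the score of residue *i* in model *j*
is S_ij = (1/(N−1)) Σ_{k≠j} d_ijk, the mean C-α distance to the
corresponding residue across superposed top models. S feeds directly into
the B-factor encoding as a predicted deviation.

**AmIgoMR-style MR-success prediction.** Ten alignment-derived features
(global score, aligned columns, sequence identity, gap fraction, target
length, and cumulative column counts with per-column score ≥ 1.5, 0.5,
−0.5, −1.5 and < −1.5) enter a logistic regression fitted by backward
elimination (drop the least significant variable while any p > 0.05),
validated by leave-one-out cross-validation, and calibrated by ROC
analysis: Mann–Whitney AUC, the operating threshold closest to the (0, 1)
corner, and Hanley–McNeil comparison of correlated AUCs.

## Worked example

Generate a synthetic native with three noisy decoys (ground-truth
deviations written alongside), build a backbone search model whose B
column encodes the C-α deviations, and score the decoy against the native:

```
$ mrprime simulate decoys --seed 11 --n-residues 60 --n-models 3 --sigma 1.2 -o sim/
wrote decoys fixtures to sim/

$ mrprime prepare --model sim/decoy00.pdb --variant BACKBONE_CA_IDEAL \
      --profile sim/decoy00_u.tsv -o search_model.pdb
wrote search_model.pdb (240 atoms, variant BACKBONE_CA_IDEAL)

$ mrprime evaluate --model sim/decoy00.pdb --reference sim/native.pdb
{"ca_rmsd": 2.0298520577997063, "gdt_ts": 69.16666666666667, "n_mapped": 60}
```

The 60-residue decoy carries σ = 1.2 Å coordinate noise, so roughly 2 Å
C-α RMSD and GDT_TS ≈ 69 are expected: about two-thirds of the chain can
be superposed within the GDT cutoffs. The prepared model keeps only
N/CA/C/O atoms (240 = 60 × 4) and its B column now stores 8π²u² per
residue — atoms the profile marks as badly placed get large B and are
down-weighted by the MR search:

```
ATOM      1  N   GLN A   1       1.281   0.194   1.042  1.00796.54           N
```

Train the MR-success predictor on a feature table with known logistic
structure and inspect what backward elimination retains:

```
$ mrprime simulate features --seed 9 --n-rows 300 -o feat/
$ mrprime amigomr train --features feat/features.tsv --labels feat/labels.tsv -o model.json
{"retained": ["global_score", "seq_identity", "ge_m0_5"], "auc": 0.812, "optimal_threshold": 0.44}
```

The generative signal lives in `global_score` and `seq_identity`; at
n = 300 a single extra feature surviving at the 0.05 level is within
expectation.

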