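# Methods

## Model

`grank` scores a protein–protein docking model from an atom-level graph of
its inter-chain interface. The representation and network follow the
GVP-GNN family: every embedding is a tuple (s, **V**) of a scalar feature
vector and a stack of geometric 3-vectors, and every learned map touches
3-D geometry only through channel mixing of vectors, their norms, and
per-channel gating. This gives exact E(3) invariance of the scalar output:
rotations, translations and reflections of the input coordinates change the
score only at floating-point level (the test suite bounds it at 1e-4; in
practice it is ~1e-15).

### Interface and graph

* Interface atoms: all atoms with at least one cross-chain partner within
  **8.5 Å** (atom-level membership; a residue-level mode that keeps whole
  contact residues is available via `--interface-mode residues`). Models
  with an empty interface are excluded and counted.
* Elements: only C, N, O, S, H are modeled; all other atoms (metals, etc.)
  are removed beforehand. HETATM records, waters, and altlocs other than
  the first-listed are dropped at parse time; multi-MODEL files use the
  first model.
* Edges: all ordered atom pairs within **4.5 Å**, both directions, no
  self-loops. Edge scalars are a Gaussian RBF expansion of the distance
  with **16 centers evenly spaced on [0, 4.5] Å** and σ equal to the center
  spacing; the paper-level description fixes the encoding but not the
  count/width, so these follow common GVP-GNN practice and are
  configurable. The edge vector is the unit vector from source j to target
  i (the message direction); the opposite convention would be equally valid
  — one is fixed for reproducibility.
* Node scalars: one-hot atom type in the fixed order (C, N, O, S, H). The
  node vector channel starts empty; vector features are created by message
  passing from edge vectors.

### GVP layer

The vector-gated form: V_h = W_h V; s_m = W_m·concat(s, rownorm(V_h)) + b;
output scalars = ReLU(s_m) (identity on the last GVP of each chain);
output vectors = (W_μ V_h) ⊙ sigmoid(W_g s_m + b_g) per channel. With no
input vectors the output vector channel is zero — there is no equivariant
map from scalars alone to vectors. Whether the original scorer used the
gated or the earlier non-gated GVP is not recoverable from its description;
the gated form is the design choice here and satisfies every equivariance
contract the tests pin down.

Tuple layer norm: standard affine normalization on the scalar channel; the
vector channel is divided by the RMS of its channel norms (no centering, so
equivariance is preserved). Dropout drops scalar entries elementwise and
whole 3-vectors row-wise; it is active only in training mode.

### Architecture

one-hot/RBF inputs → input GVPs → **5 GVPConvLayer blocks** → output GVP
reducing to scalars → mean pool over nodes → dense(ReLU) → dense → score.
Each block is a graph-propagation layer (messages from concat(node, edge)
embeddings through **3 chained GVPs**, incoming messages averaged by
in-degree k′, residual + tuple norm, isolated nodes skip the aggregation
term since 1/k′ is undefined at k′=0) followed by a point-wise feed-forward
layer (**2 chained GVPs**, hidden width 2× the scalar dim, residual + tuple
norm). Default dims: node (100 scalar, 16 vector), edge (32, 1), dense
head 128, dropout 0.1 — the source description is silent on these; all are
config-exposed. The head has no output activation: scores are unbounded
regression targets used for ranking and MSE.

### Numerical core

No deep-learning framework is used: the network runs on a small
reverse-mode autodiff tape over float64 NumPy arrays
(`grank/_autodiff.py`), with gather/scatter primitives for message passing
and gradients validated against central finite differences. Graphs are
batched as disjoint unions; all updates are per-node and pooling is
per-graph, so a graph's score is independent of its batch-mates (asserted
to 1e-6). Eval-mode scoring is deterministic and bit-reproducible from a
serialized checkpoint (`.npz` of named float64 arrays plus the JSON
config).

## Quality labels

* **f-nat** — fraction of native cross-chain residue contacts present in
  the model. A contact is any residue pair with a heavy-atom pair ≤ 5 Å
  (hydrogens are graph nodes but never count toward contacts, following
  CAPRI assessment convention). Near-native ⇔ f-nat ≥ 0.3; the boundary is
  inclusive by convention here.
* **lRMSD** — superpose model on native by receptor backbone (N, CA, C, O;
  missing atoms tolerated), then RMSD over ligand backbone without
  refitting.
* **iRMSD** — backbone RMSD over native interface residues (any heavy atom
  ≤ 10 Å of the partner chain) after superposing on those same atoms.
* **Kabsch superposition** — proper rotation via SVD with determinant
  correction (scipy's `Rotation.align_vectors`); the RMSD is recomputed
  from residuals because the library's residual norm loses precision for
  near-perfect fits. Collinear/coplanar sets resolve deterministically.
* **CAPRI class** — best class whose criteria hold: high ⇔ f-nat ≥ 0.5 ∧
  (lRMSD ≤ 1 ∨ iRMSD ≤ 1); medium ⇔ f-nat ≥ 0.3 ∧ (lRMSD ≤ 5 ∨ iRMSD ≤ 2);
  acceptable ⇔ f-nat ≥ 0.1 ∧ (lRMSD ≤ 10 ∨ iRMSD ≤ 4); else incorrect.
  The exact thresholds of the reference supplement are not in its main
  text, so this reconstruction of the CAPRI standard is config-overridable.

Model/native residue numbering is assumed identical (true for docking
decoys of one target); labeling errors out on a missing residue rather
than attempting alignment.

## Training protocol

MSE on f-nat; Adam with canonical moment defaults, batch size 64, learning
rate 1e-4, 50 epochs by default; per-epoch shuffling seeded from
(seed, fold, epoch); validation loss evaluated with dropout off; the
checkpoint returned is the argmin-validation-loss epoch. Cross-validation
splits are disjoint **by complex**: all decoys of a complex share a split,
and held-out test complexes never appear in any fold's training set.
Ensembling is the arithmetic mean of member eval-mode scores.

## Evaluation

All metrics are per complex, then aggregated — never pooled across
complexes, since score scales are not comparable between targets.
ROC-AUC/PR-AUC come from scikit-learn; PR-AUC is average precision, i.e.
step-wise interpolation (precision held between recall points), stated
because trapezoidal interpolation would differ. Ranking ties break
lexicographically by model id; the AUCs use the ½-tie convention
independently of that order. Summaries report median and 25/75% quantiles
with linear interpolation between order statistics. Complexes with no
positive decoy have undefined hit rate/AUCs and are skipped. The positive
definition is pluggable: f-nat ≥ 0.3 (default) or CAPRI ≥ acceptable.

## Synthetic data

`synthetic_decoys` emulates the *shape* of docking benchmarks at desk
scale. A native is two 6-residue coarse chains (N, CA, C, O, one side-chain
pseudo-atom with elements drawn C/N/O/S at 0.6/0.15/0.2/0.05, one amide H),
placed so the side chains interdigitate at van-der-Waals-like distances;
seeded jitter makes complexes distinct. Decoys rigidly perturb the ligand
chain: rotation about its centroid around a random axis, then a
random-direction translation, with magnitudes striding a grid of
translations {0, 0.5, 1, 2, 4, 8, 16} Å × rotations {0, 5, 15, 45}°. This
spans f-nat from 1 to 0 and produces genuinely contact-free decoys that
exercise the exclusion path. Labels are always measured by the labeling
module, never assumed from the construction.

What passing tests on this generator do **not** show: the decoys have no
internal deformation, no side-chain chemistry, realistic neither in size
nor in energetics, and their class balance (roughly half positive) is far
from the ~6% positive rate of real benchmark sets. Results on synthetic
data demonstrate that the machinery is correct and that the network can
learn a geometry→quality mapping — not that it reaches benchmark accuracy
on real docking decoys, which would require the large external datasets
and full-scale training that are out of scope here.

## Problem sizes and defaults used in checks

The learning-sanity check trains on 40 complexes × 20 decoys with reduced
dims (node (32, 4), edge (16, 1), 2 blocks) for 30 epochs — sizes chosen so
the whole check runs in minutes on one CPU while leaving the prescribed
loss/optimizer settings (MSE, Adam, batch 64, lr 1e-4) untouched. Eight
complexes are held out entirely; the reported statistic is the median
per-complex Spearman correlation between score and f-nat on them, with the
training-MSE ratio (final epoch / untrained model) as the learning
indicator. Oracle checks use 100 random complexes (geometry), 50 random
small graphs (network references) and 1000 random vectors (metrics).

## Known limitations

* Exactly two chains; mmCIF, assemblies and multi-chain complexes are out
  of scope, as is renumbering/alignment between model and native.
* The NumPy core is CPU-only and sized for small graphs; reproducing
  benchmark-scale training is a non-goal.
* Hidden dimensionalities and dropout of the reference scorer are unknown;
  defaults are field-standard choices, so learned scores are not expected
  to match any externally trained weights.
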