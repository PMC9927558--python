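# grank

Scoring and ranking of protein–protein docking models with an
E(3)-invariant geometric-vector-perceptron graph neural network (GVP-GNN).

## The problem

Computational docking produces thousands of candidate structures (decoys)
for a protein–protein complex; only a handful are near-native. A scoring
function must rank the decoys of each target so that near-native models
appear at the top. `grank` scores a decoy from the geometry of its
inter-chain interface alone:

1. **Interface extraction** — atoms within 8.5 Å of the partner chain are
   kept; decoys whose chains do not touch are excluded.
2. **Graph featurization** — atoms become nodes (one-hot over C, N, O, S,
   H); every ordered atom pair within 4.5 Å becomes a directed edge carrying
   a 16-component Gaussian radial-basis encoding of its length and the unit
   vector along its direction.
3. **GVP-GNN scoring** — node/edge embeddings are tuples (s, **V**) of
   scalars and geometric 3-vectors. Each of five GVPConvLayer blocks applies
   a graph-propagation layer,

       m(j→i) = φ(concat(h_Vj, h_E(j→i))),   φ = 3 chained GVPs
       h_Vi ← LayerNorm(h_Vi + (1/k′) Dropout(Σ_{j∈N(i)} m(j→i))),

   followed by a point-wise feed-forward layer
   `h_Vi ← LayerNorm(h_Vi + Dropout(φ(h_Vi)))` with φ = 2 chained GVPs.
   A final GVP reduces nodes to scalars, mean pooling aggregates them, and
   two dense layers emit one scalar score per decoy. Because coordinates
   enter only through distances, directions and vector norms, the score is
   exactly invariant under rotation, translation and reflection.
4. **Training** — the network regresses **f-nat** (the fraction of native
   inter-chain residue contacts the decoy reproduces, heavy atoms within
   5 Å) with MSE loss, Adam, batch size 64, learning rate 1e-4; the epoch
   with the lowest validation loss is retained, and fold models are
   ensembled by score averaging.
5. **Evaluation** — per-complex ROC-AUC, PR-AUC, hit rate
   `hit-rate(k) = N_hits(k)/N_pos` and across-complex success rate at top-k,
   with decoys labeled near-native at f-nat ≥ 0.3 or, alternatively, CAPRI
   class ≥ acceptable (classes derive from f-nat, ligand RMSD and interface
   RMSD via Kabsch superposition).

A synthetic decoy generator (miniature two-chain complexes, rigid-body
ligand perturbations spanning f-nat from 1 to 0) makes the whole pipeline
runnable and testable without any external dataset. The network and its
training run on a small NumPy reverse-mode autodiff core, so the package
has no deep-learning framework dependency.

## Worked example

```bash
grank run --n-complexes 6 --n-decoys 6 --n-folds 2 --n-test-complexes 2 \
      --n-epochs 2 --n-blocks 1 --node-dims 8,2 --edge-dims 4,1 --seed 5 \
      --out demo/
```

prints (timings aside):

```
wrote 36 decoys for 6 complexes (1 without contact atoms) to demo/sim
featurized 35 models (1 excluded) to demo/graphs
fold 0: best epoch 2, val loss 0.6219 -> demo/ckpt
scored 12 models -> demo/scores.tsv
evaluated 2 complexes -> demo/metrics.json
pipeline done -> demo
```

`demo/sim` holds the synthetic natives/decoys (PDB), their manifest and
measured quality labels; one far-perturbed decoy had no inter-chain
contact atoms and was excluded. Training kept epoch 2, the epoch with the
lowest validation MSE on the regression of f-nat. `demo/metrics.json`
contains, for each held-out complex, the ROC-AUC/PR-AUC of the scores
against the near-native labels and the full hit-rate curve, plus a
median/quartile summary — with 2 epochs on 24 tiny graphs the AUCs are
essentially chance; the learning-sanity check below trains long enough to
rank held-out decoys well. Each stage can also be run separately
(`grank simulate|featurize|label|splits|train|score|evaluate`); see
`grank <stage> --help`.

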