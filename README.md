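# parsebp

Consensus (multi-model) quality scoring for RNA 3D structure ensembles.

Given a pool of candidate 3D structures ("decoys") all modelling the same
RNA sequence — the typical output of an RNA structure prediction pipeline
or a CASP-style blind challenge — the hard problem is picking the good
models without knowing the experimental structure. Single-model scoring
functions judge each decoy in isolation; this package instead scores each
decoy by its agreement with the rest of the ensemble, combining global 3D
fold similarity with 2D base-pairing consistency.

## The method

For an ensemble S = {S_1, …, S_N}:

1. **T** — the N×N matrix of pairwise TM-scores (superposition-based fold
   similarity of the C1′ traces, length-normalized, values in (0, 1]).
2. **I** — the N×N matrix of pairwise Interaction Network Fidelity
   scores, INF = √(precision · recall) over the base-pair sets extracted
   from each decoy (built-in geometric annotator, or pair lists from an
   external annotator such as MC-annotate, FR3D, or RNAView).
3. **M = T ∘ I** — the element-wise product, a consensus matrix in which
   3D agreement counts only where it is reinforced by consistent pairing.
4. **Q_i = (1/(N−1)) Σ_{j≠i} M_ij** — each decoy's quality score: its
   mean agreement with all other decoys.

A baseline variant (`Q_no_bp`) scores from T alone; comparing the two
columns shows exactly which decoys lose support because their base
pairing, not their backbone fold, disagrees with the pool.

The package also ships the matching evaluation harness (composite score
G = 0.3·TM + 0.3·GDT_TS + 0.4·lDDT, per-target min–max normalization,
global and per-target Pearson/Spearman with Fisher-z averaging, top-1
loss) and a synthetic decoy generator that builds A-form duplex pools with
graded, known distortion — so the whole pipeline closes the loop against
known ground truth without any external data.

## Worked example

Generate a 6-decoy pool on a 24-nt duplex (two decoys each at 0.2, 1.0
and 3.0 Å coordinate noise), then score it:

```sh
parsebp synth --out demo --length 24 --decoys 6 --noise 0.2,1.0,3.0 --seed 42
parsebp score demo/decoys --out demo_scores
cat demo_scores/scores.csv
```

```
decoy_id,Q_parsebp,Q_no_bp,rank
decoy_000,0.122335,0.165646,2
decoy_001,0.127577,0.172705,1
decoy_002,0.027404,0.075571,4
decoy_003,0.031920,0.080507,3
decoy_004,0.000000,0.033434,6
decoy_005,0.005421,0.044063,5
```

The two low-noise decoys (000, 001) rank first, the mid-noise pair next,
the 3 Å decoys last — matching the known generation tiers. Absolute Q
values are low because two-thirds of this small pool is heavily distorted:
Q measures agreement with the whole ensemble, so it is a relative ranking
signal, not an absolute accuracy estimate. `demo/truth.csv` holds each
decoy's TM-score to the unperturbed reference; evaluating the predictions
against it:

```python
import pandas as pd
scores = pd.read_csv("demo_scores/scores.csv")
truth = pd.read_csv("demo/truth.csv")
pred = truth[["target_id", "decoy_id"]].merge(
    scores.rename(columns={"Q_parsebp": "score"})[["decoy_id", "score"]],
    on="decoy_id")
pred.to_csv("demo/predictions.csv", index=False)
```

```sh
parsebp eval demo/predictions.csv demo/truth.csv --truth-metric tm --out demo_eval
```

reports `global_r = 0.990`, `global_rho = 0.943` and
`per_target_loss = 0.055` for this pool: the consensus ranking tracks the
true quality closely, and the best-ranked decoy is within 0.055 normalized
TM units of the actual best decoy. Any predictions CSV with
`target_id,decoy_id,score` columns — from any scoring method — can be
evaluated the same way.

Library use mirrors the CLI:

```python
from parsebp import read_ensemble, score_ensemble

ensemble = read_ensemble("demo/decoys")
result = score_ensemble(ensemble)
print(dict(zip(result.parsebp.ids, result.parsebp.q)))
```

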