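# mssf — multi-source similarity fusion for drug side-effect frequency classes

How often a side effect occurs with a drug — very rare, rare,
infrequent, frequent or very frequent — matters as much to clinicians
and drug developers as whether it occurs at all.  `mssf` predicts these
five ordered frequency classes for (drug, side effect) pairs by fusing
heterogeneous similarity evidence, treating the task as multi-class
classification instead of the usual regression-plus-thresholding.

The model fuses **11 drug similarity matrices** (five chemical–chemical
association channels, Tanimoto fingerprint similarity, drug–target and
substructure-embedding cosine similarities, a pathway–enzyme profile
similarity, and two frequency-profile similarities DIPA/DIPF) and **4
side-effect similarity matrices** (DAG-based semantic similarity, word
embedding cosine, and the side-effect DIPA/DIPF).  For a pair (dᵢ, sⱼ)
the similarity rows are combined three ways — concatenation, elementwise
addition, and 44 (= 11 × 4) rank-1 **interaction maps**
`Xᵈᵢᵖ ⊗ Xˢⱼᑫ` from learnable per-source projections — and processed by
two attention autoencoders and a small CNN.  The branch latents are
fused by self-attention, passed through a **variational head**
(F_l = μ + ε·σ, KL-regularized toward N(0, I)), and classified by an MLP
with five sigmoid outputs.  The training loss is

    L = BCE + α₁·MSE_con + α₂·MSE_add + α₃·KL(μ, σ) + γ·‖θ‖²

Evaluation supports pairwise 10-fold cross-validation (with the
frequency-derived similarities refit per fold to avoid leakage),
drug-wise **cold-start** validation and an **independent split** (both
drop DIPA/DIPF, leaving 9 + 2 matrices), eight metrics (ACC, weighted
and macro F1, Cohen's κ, multiclass MCC, macro precision/recall, macro
AUPR), and a KDE/maximum-likelihood converter that turns the continuous
outputs of regression baselines into classes for fair comparison.

The network runs on a small numpy reverse-mode autodiff core
(`mssf.autograd`), validated against finite differences in the test
suite; no deep-learning framework is required.

## Worked example

Generate a planted-signal dataset, build all 15 similarity matrices and
run one cross-validation fold:

```python
import numpy as np, mssf
from mssf import pipeline
from mssf.config import RunConfig

dsa, raw = mssf.generate(mssf.FixtureSpec(seed=1))   # 40 drugs x 50 side effects
bank = mssf.build_bank(dsa, raw)                     # 11 + 4 similarity matrices
print(len(dsa.known_pairs))                          # 600 known pairs

cfg = RunConfig.desk_scale(seed=1)
plan = pipeline.make_pairwise_folds(dsa, k=10, seed=1)
report, pairs, scores = pipeline.run_fold(bank, dsa, plan, 0, cfg)
print({k: round(v, 3) for k, v in report.items()})
```

which prints

```
600
{'acc': 0.883, 'weighted_f1': 0.884, 'macro_f1': 0.87, 'kappa': 0.848,
 'mcc': 0.849, 'macro_precision': 0.897, 'macro_recall': 0.855,
 'macro_aupr': 0.819}
```

The fold's 60 held-out pairs are scored at 88% accuracy against a 29%
majority-class rate: the model recovers the planted cluster structure
from the fused similarities alone.  `scores` holds the five per-class
sigmoid scores for each test pair.

The same workflows are available from the shell:

```sh
mssf simulate --n-drugs 40 --n-side-effects 50 --seed 1 --out data/
mssf build-similarities --data data/ --out sims/
mssf cross-validate --data data/ --out results/ --seed 1
mssf cold-start --data data/ --out results-cold/ --seed 1
```

See `docs/methods.md` for the model, its assumptions, all tunable
parameters and the design choices.

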