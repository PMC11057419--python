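# pbac

Pathway-based attention-convolution prediction of drug-treatment response
from gene expression.

Predicting which patients (or cell lines) will respond to a chemotherapy or
immunotherapy agent from transcriptomics is a core problem in precision
oncology. Black-box classifiers do it without saying *why*; `pbac`
implements an interpretable architecture whose connectivity is constrained
by known gene-set membership, so that its learned attention weights read
directly as pathway-importance scores. It is aimed at computational
biologists who have an expression matrix, a GMT gene-set collection, and
response labels (clinical responder/non-responder calls or IC50 values
binarised at the drug's maximum screening concentration).

## The model

For a sample with (z-scored) expression vector **x** over *n* genes and a
binary pathway-membership matrix **M** (*P* × *n*):

1. **Gene–pathway mask** — X<sub>m</sub> = x·Mᵀ / |pathway| : the mean of
   each pathway's member genes. Genes outside every pathway have exactly
   zero influence on the output.
2. **Attention** — W<sub>a</sub> = softmax(W₂ᵀ tanh(W₁ᵀ X<sub>m</sub>)),
   X<sub>a</sub> = X<sub>m</sub> ⊙ W<sub>a</sub> : a per-sample probability
   vector over pathways (rows sum to 1) that reweights pathway features and
   doubles as the interpretability output.
3. **Convolution** — X<sub>c</sub> = Conv(X<sub>a</sub>) : a 1-D
   convolution along the pathway axis (kernel 3, stride 1, padding 1, *C*
   channels; output length stays *P*).
4. **Head** — Y = softmax(W<sub>f</sub> X<sub>c</sub> + b) for binary
   classification, or a single linear output for continuous IC50 regression.

Everything is plain NumPy with hand-derived gradients and Adam; gradients
are verified against finite differences in the test suite. Two ablation
variants ship with the model: `no_mask` (the fixed mask replaced by a
learned dense layer of the same shape) and `no_attention` (attention frozen
at the uniform 1/P).

Evaluation follows the field's conventions: AUROC (midrank Mann–Whitney),
AUPRC (step-wise average precision), and for regression-head runs the
effect size — the difference in mean z-scored predicted IC50 between
responders and non-responders — with a two-sided Wilcoxon rank-sum p-value.

A bundled generator produces pathway-structured synthetic cohorts with
planted driver pathways and a consistent IC50 model, so the whole pipeline
is testable without downloading any cohort.

## Worked example

`examples/rank_driver_pathways.py` trains the model on a synthetic cohort
with two planted driver pathways and ranks all 40 pathways by mean
attention:

```
true drivers: ['DRIVER_000', 'DRIVER_001']
top 5 pathways by mean attention (uniform would be 1/40 = 0.025):
   pathway  mean_attention  mean_attention_responder  mean_attention_non_responder  rank
DRIVER_001        0.035249                  0.064354                      0.015846     1
   PW_0002        0.027165                  0.030445                      0.024979     2
   PW_0021        0.027092                  0.034778                      0.021969     3
   PW_0020        0.026600                  0.029066                      0.024956     4
DRIVER_000        0.026163                  0.034801                      0.020404     5
```

Both planted drivers are in the top 5, and their attention is concentrated
in responder samples — the signal-carrying class. The other examples cover
cross-validation (`simulate_and_crossvalidate.py`, mean 5-fold AUROC 0.883
on a 120-sample cohort), the ablation comparison (`ablation_study.py`), and
IC50 labeling plus effect size (`ic50_labels_and_effect_size.py`, effect
−1.41, Wilcoxon p ≈ 1.5e−19 on a cohort with strong planted signal).

There is also a thin CLI:

```bash
pbac simulate --seed 1 --out data/            # write a synthetic cohort
pbac cv --expression data/synth_expression.tsv --gmt data/synth_pathways.gmt \
        --labels data/synth_labels.tsv --seed 1 --out results/
pbac train ... ; pbac rank --checkpoint results/checkpoint ...
```

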