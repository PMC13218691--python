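# genopotential

Manifold-regularized, uncertainty-aware prediction of athletic
potential from genotype dosages.

## The problem

Cohort studies that pair array genotyping with standardized physical
testing (running speed, endurance capacity, muscular strength) make it
possible to ask how much of general athletic capability is predictable
from inherited markers — and, just as importantly, how confident each
individual prediction is. Plain tabular regressors ignore two things
such data offer: genotype similarity between individuals (nearby
points on the genomic manifold should behave similarly) and
individual-level noise heterogeneity (some people's measurements are
simply noisier). This package implements a predictor that uses both,
for biostatisticians and sports-science researchers who want a tested,
reproducible reference pipeline. Because real cohorts of this kind are
managed-access, the package includes a synthetic cohort simulator with
controlled linkage disequilibrium, heritability, and noise structure;
every result below is computed on simulated data.

## The model

Individuals carry dosage vectors x ∈ {0,1,2}^p, min–max normalized to
[0,1]. The target y is the standardized mean of the three z-scored
capability indicators. The network is three stages,

    encoder    x → Z          (128-dim embed, then 256/128/64 blocks of
                               linear → layer-norm → ReLU → dropout)
    planner    Z → A ∈ R^3    (two-layer MLP; A tracks the standardized
                               indicators through a reward penalty)
    forecaster A → (μ, σ²)    (shared trunk, dual heads; σ² = exp·clamp)

trained end-to-end on the composite objective

    L = 1/n Σᵢ [ (yᵢ−μᵢ)²/2σᵢ² + ½ log σᵢ² ]          Gaussian NLL
      + λ_m · Σ_{i,j} C_ij ‖Z_i−Z_j‖² / |E|            manifold penalty
      + λ_r · mean ‖A_i − y3_i‖²                        reward (planner)
      + λ_c · Σ_{i,j} C_ij (μ_i−μ_j)² / Σ C_ij          output smoothness

with λ_m = λ_r = λ_c = 0.1. C_ij is a Gaussian-kernel k-nearest-neighbor
graph (k = 10, median bandwidth) on normalized genotypes. Predictive
uncertainty comes from T = 20 Monte-Carlo dropout passes:
aleatoric = mean σ², epistemic = variance of per-pass means,
total = their sum. Training is Adam (lr 0.001, weight decay 1e-4,
batch 64, cosine annealing, 120 epochs, seed 42), returning the best
validation-NLL checkpoint. See `docs/methods.md` for assumptions,
normalization details and known limitations.

## Worked example

The packaged benchmark simulates 2,000 individuals with 200 markers in
20 LD blocks at heritability 0.5, heteroscedastic noise, and a
rank-one epistatic component carrying 25% of the genetic variance:

```python
import genopotential as gp

ds, graph, _ = gp.prepare_benchmark(seed=42)
spec = gp.ModelSpec(input_dim=ds.X.shape[1])
params, log = gp.train(ds, spec, gp.LossWeights(),
                       gp.TrainConfig(epochs=120, seed=42), graph)
report = gp.full_report(params, spec, ds, T=20, seed=42)
```

This prints (via the accessors shown in the docstrings):

```
test Pearson  0.733
test RMSE     0.686
test R^2      0.514
OLS RMSE      0.728
calibration   0.018
                  n   rmse    mae
setting
all             197  0.686  0.531
low              98  0.610  0.464
high             99  0.753  0.597
excluded_top10  178  0.672  0.514
          n  true_score_mean
group
top      39             1.29
middle  119            -0.20
bottom   39            -0.63
```

Reading these numbers: the network recovers a test-set Pearson of 0.73
against a ceiling of ≈ 0.87 set by the target's effective heritability,
and beats the ordinary-least-squares reference (RMSE 0.686 vs 0.728)
because the linear model cannot capture the epistatic component and
ignores noise heterogeneity. The calibration error of 0.018 means
nominal central predictive intervals cover at almost exactly their
advertised rates. The triage table shows the estimated uncertainty is
informative: the low-uncertainty half of the test set has RMSE 0.610
versus 0.753 for the high half, and dropping the 10% most uncertain
individuals lowers overall RMSE from 0.686 to 0.672. The
stratification table shows the top-20% group by predicted score has a
far higher mean true score (+1.29) than the bottom-20% group (−0.63).

## Command line

Every stage is a subcommand over the same YAML config
(`genopotential print-config` shows all defaults):

```
genopotential run-all --out runs/demo --seed 42
genopotential simulate   --config cfg.yaml --out runs/cohort
genopotential preprocess --cohort-dir runs/cohort --out runs/proc
genopotential train      --dataset-dir runs/proc --graph-dir runs/graph --out runs/model
genopotential evaluate   --dataset-dir runs/proc --checkpoint runs/model/checkpoint.npz --out runs/eval
```

plus `graph`, `predict`, `triage`, `stratify`, `ablate` and
`sensitivity`. Flag overrides beat config values, which beat defaults.

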