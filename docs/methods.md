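# Methods

`genopotential` predicts a continuous athletic-potential score from
genotype dosages with a manifold-regularized, heteroscedastic neural
regression model, and quantifies predictive uncertainty with
Monte-Carlo dropout. Because the cohort resources this kind of study
draws on (paired genotyping and standardized physical testing) are
managed-access, the package ships a synthetic cohort simulator whose
defaults define the study conditions; everything downstream is tested
against it.

## Data model

### Synthetic cohort

Genotypes are dosage markers in {0,1,2}. Linkage disequilibrium is
emulated by partitioning the `p` markers into contiguous blocks; within
a block, latent Gaussians share an equicorrelation `within_block_rho`
(default 0.6) and each marker's latent value is thresholded at the
Hardy–Weinberg quantiles of its own allele frequency, drawn uniformly
from `maf_range` (default 0.05–0.5). This is the simplest structure
that gives both testable marginal frequencies (every marker is
Binomial(2, f) by construction) and realistic inter-marker correlation
decaying across block boundaries. It deliberately omits population
structure, admixture, relatedness and genotyping error.

Phenotypes are three standardized indicators (speed, endurance,
strength). A common additive genetic factor is built from `n_causal`
markers (default 100, spread uniformly across blocks) with N(0,1)
effects. `shared_factor_loading` mixes this common factor with an
indicator-specific additive factor on the variance scale; the default
is 1.0 — a single "general athleticism" genetic factor — which makes
the stored ground-truth genetic value exactly each indicator's genetic
component, so heritability is directly auditable (regressing any
indicator on the stored genetic value recovers h² at large n). Each
indicator is scaled so Var(genetic)/Var(total) equals `heritability`
(default 0.5).

Noise is optionally heteroscedastic: SD_i = base_sd · (1 +
`hetero_coeff` · z_i), with z_i a min–max-scaled dosage score on the
last ten markers, and base_sd chosen so the mean noise variance stays
(1 − h²). `historical_noise_sd` (default 0.5) produces earlier, noisier
measurements of each indicator; these are the historical features, kept
distinct from the assessment-time indicators that define the target so
the target is never built from its own features.

`epistasis_frac` (default 0.0) adds a rank-one pairwise-epistatic
component: the square of the additive score, with the additive
direction projected out before mixing, carries that fraction of the
genetic variance. The projection matters — epistatic variance is by
definition the genetic variance orthogonal to the additive component,
and without it the nominal fraction overstates the nonlinearity
(dosage products are strongly collinear with dosages). The rank-one
form was chosen over random-sign product interactions because the
latter are statistically unlearnable at cohort sizes of a few thousand
for every model class compared here, which would make any
linear-vs-nonlinear benchmark vacuous.

Defect injection (duplicated rows, missing cells with an `NA`
sentinel, values planted at mean + 10·SD) exists to exercise the
cleaning pipeline and returns a complete manifest of what was planted.

### Target

The potential score is the mean of the three z-scored assessment-time
indicators, re-standardized to train-split mean 0 and SD 1. Note a
consequence: averaging three indicators with independent noise raises
the target's effective heritability to h²/(h² + (1−h²)/3) — 0.75 when
each indicator has h² = 0.5 — so the prediction ceiling on the default
cohort is Pearson ≈ 0.87 from genotypes alone, not √h².

## Preprocessing

Cleaning runs in a fixed order: duplicate IDs (first occurrence kept),
then rows with any missing genotype or phenotype cell (historical
included, since those columns are features), then a single-pass
three-standard-deviation rule per assessment indicator using sample SD
computed once over the surviving rows. Iterating the outlier rule
would change counts on heavy-tailed data; one pass is what is applied.
On a Gaussian cohort the 3-SD rule removes ≈ 0.8% of rows — that is
expected behavior, not a defect.

Splits are 8:1:1 at the individual level: a seeded uniform permutation,
first ⌊0.8n⌋ train, next ⌊0.1n⌋ validation, remainder test.
Normalization parameters (genotype min–max to [0,1]; indicator
z-scores; target mean/SD) are fitted on the train partition only;
out-of-range test values are not clipped, and a train-constant genotype
column maps to 0. Feature matrices default to genotypes + historical
indicators (`--features genotype-only` drops the latter; the packaged
benchmark uses genotype-only so results reflect genomic signal).

## Similarity graph

Biological similarity C_ij is a k-nearest-neighbor graph (k = 10) on
normalized genotype features with Gaussian-kernel weights
w = exp(−d²/2h²), h = median kNN distance (falling back to the smallest
positive distance if the median is zero), symmetrized by
max(w_ij, w_ji). Sums over pairs are ordered (both (i,j) and (j,i)),
diagonal excluded. The manifold penalty is the edge-normalized sum of
w·‖Z_i − Z_j‖²; the output-smoothness penalty is the weighted mean of
w·(ŷ_i − ŷ_j)², which is invariant to rescaling all weights.

Two adjustments apply when these penalties enter mini-batch training:

1. **Expected-count normalization.** The subgraph induced by a 64-row
   batch may contain only a handful of edges; dividing by the realized
   edge count makes per-edge gradients blow up as 1/E_batch. Batch
   penalties are instead divided by the expected edge count (full-graph
   totals × the probability both endpoints land in the batch), an
   unbiased estimator of the full-graph penalty that reduces to the
   plain definition when the batch is the whole graph.
2. **Scale invariance of the manifold term.** The raw penalty has a
   trivial global optimum at a collapsed (constant) embedding, and
   under Adam its persistent shrink direction can dominate the
   likelihood pull — in early experiments the embedding SD fell to
   1e-3 within one epoch. The training-time manifold term is therefore
   divided by the batch embedding variance (a quotient whose gradient
   has no pure-scale component), the same normalization Laplacian
   eigenmaps impose through their unit-variance constraint. The
   stand-alone `manifold_loss` function keeps the plain definition.

## Model

The network (NumPy, hand-written backpropagation checked against
finite differences at 1e-4 relative) is three stages:

* **Encoder** — linear embedding to 128, then three blocks of linear →
  layer-norm → ReLU → dropout with widths 256/128/64, giving the
  embedding Z on which the manifold penalty acts.
* **Planner** — a two-layer MLP 64 → 128 → m (m = 3) producing an
  action matrix A trained, through the reward term, to track the three
  standardized indicators. This gives the forecaster a low-dimensional,
  semantically anchored representation.
* **Forecaster** — a shared ReLU trunk (width 64) on A with two linear
  heads: predictive mean and log-variance, σ² = exp(log σ²) clamped to
  [1e-6, 1e6]. Dropout (p = 0.1) sits after every encoder/planner ReLU
  and nowhere in the forecaster, so MC variation flows through the
  representation.

Uncertainty is decomposed by T = 20 dropout-active forward passes:
aleatoric = mean predicted σ², epistemic = population variance of the
per-pass means, total = their sum (law of total variance). With
dropout off all passes coincide and the epistemic term is exactly
zero.

## Objective and training

L_total = NLL + 0.1·manifold + 0.1·reward + 0.1·smoothness, with
NLL = (1/n) Σ [(y−ŷ)²/2σ² + ½ log σ²]. A bare Σσ² penalty is never
used as an objective — minimized alone it drives σ² to the floor; the
NLL's ½ log σ² term provides the calibrated version of that pressure.
The reward term is the mean squared gap between A and the standardized
indicators (reward maximization recast as loss minimization).

Training: Adam (lr 0.001, weight decay 1e-4 folded into the gradient),
batch size 64, cosine annealing to zero over the epoch budget (120 by
default), fixed seed 42. Validation is evaluated after each epoch and
the returned parameters are those of the best validation-RMSE epoch,
followed by **post-hoc variance recalibration**: every σ² is scaled by
s² = mean(validation residual²/σ²), the closed-form single-temperature
minimizer of the validation NLL. The recalibration is necessary
because at benchmark scale the network memorizes the training set and
the variance head tracks the shrinking train residuals — the selected
checkpoint would otherwise be severely overconfident (validation NLL
rising from 0.34 to 5.3 over training while RMSE still inches down).
Scalar scaling restores calibration (coverage-gap error ≈ 0.01 on the
benchmark test split) without touching the mean predictions or the
per-individual uncertainty ranking that triage relies on. Selecting
the checkpoint by validation NLL instead was tried and rejected: it
sacrifices mean accuracy for variance quality, which makes RMSE
comparisons against the variance-free ablation variant (necessarily
selected by validation MSE) uneven.

Multi-seed runs use seeds base..base+n−1 (default 10 runs) and report
mean ± sample SD; the paired t-test on per-seed metrics uses the
closed-form statistic with n−1 degrees of freedom and refuses
zero-variance differences rather than reporting p = 0.

## Evaluation

Metrics are Pearson r, RMSE, R² (about the mean of y) and MAE; Pearson
is reported as undefined (NaN, with a warning) when either vector is
constant. Calibration error discretizes the CDF-distance idea into the
mean absolute central-interval coverage gap over nominal levels 0.05
to 0.95 in steps of 0.05 — the estimable surrogate given one draw per
individual. Stratification ranks by predicted score (descending,
stable ties) into top 20% / middle 60% / bottom 20% and reports
per-group means ± SD of the true score and indicators. Triage splits
at the median total variance, and additionally reports errors after
excluding the ⌊10%⌋ most-uncertain samples. The OLS reference baseline
is ordinary least squares (ridge 1e-6 when d ≥ n) fitted on the train
split.

Ablations retrain structurally edited models with shared seeds:
`no_manifold` (λ_manifold = 0, encoder reduced to embedding + one
64-unit block), `no_planner` (Z fed straight to the forecaster,
λ_reward = 0), `no_uncertainty` (mean head only, squared-error loss, no
MC), `no_constraint` (λ_constraint = 0). The ablation harness uses the
full 120-epoch schedule: at 25–60 epochs the squared-error variant
transiently looks better simply because NLL training converges more
slowly, which misrepresents the converged comparison. The sensitivity
harness varies embedding dimension {64,128,256}, encoder depth {2,3,4},
λ_manifold {0.01,0.1,1.0} and injected genotype feature noise SD
{0, 0.05, 0.1}.

## The packaged benchmark

`prepare_benchmark()` fixes the conditions used by the acceptance
script and the deeper tests: n = 2000, p = 200 markers in 20 blocks,
h² = 0.5, hetero_coeff = 1.0, epistasis_frac = 0.25, genotype-only
features, k = 10 graph. The sizes were chosen so a full multi-seed
ablation finishes in minutes on one CPU; the epistatic and
heteroscedastic components are enabled precisely so that a linear
baseline is beatable in principle and uncertainty triage has real
signal to find.

## What passing tests do and do not show

The simulator draws i.i.d. individuals with block-LD, a single shared
genetic factor and additive(+rank-one epistatic) architecture. Passing
tests demonstrate the pipeline's correctness and the model's behavior
under those assumptions; they say nothing about confounding by
population structure, relatedness (twin cohorts!), genotyping batch
effects, indicator measurement drift, or genetic architectures
dominated by rare variants or diffuse epistasis — all absent from the
generator. The uncertainty decomposition inherits MC dropout's known
limitations as a posterior approximation; the epistemic term is a
lower bound of honest model uncertainty.

## Numerical choices

Sample SD (ddof = 1) everywhere a cohort SD is needed; layer-norm
epsilon 1e-5; variance clamp [1e-6, 1e6] with zero gradient outside;
duplicate-free kNN bandwidth fallback to the smallest positive
distance (or 1.0 if all points coincide); exact-zero epistemic variance
when all MC passes agree (guarding mean-subtraction roundoff);
remainder rows of the 8:1:1 floor split go to test.
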