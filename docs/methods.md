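# Methods

## The problem

A survival model trained on one group of hospitals often degrades on
hospitals it never saw, and the cause of the degradation is usually
unknown: it may be acquisition differences, population differences, or
both at once.  `causalsurv` implements a causal-reasoning treatment of
this situation for recurrence-free survival prediction from quantitative
histopathology features.  The working hypothesis is *latent shift*: an
unobserved discrete subgroup variable `U` drives the features `X`, the
tumor stage `C`, the treating site `W`, and the outcome `Y`, and the
source and target populations differ **only** in the marginal
distribution of `U`.  Under that assumption the target-domain predictor
is identifiable from source data in which `C` and `W` are observed, plus
unlabeled target features.

## The model

Three components are trained in sequence on the source cohort.

**A. Discrete-latent autoencoder.**  A single affine encoder maps the 15
standardized features to `k_u` logits (default `k_u = 10`).  Sampling the
latent through the Gumbel-softmax relaxation,

    u = softmax((logits + g) / tau),   g ~ Gumbel(0, 1),

with the temperature `tau` annealed exponentially from 1.0 to 0.1 over
1000 gradient steps, drives the latent toward a one-hot code while
remaining differentiable.  A single affine decoder reconstructs the
features from `u`, and two affine heads predict stage and site from `u`.
The objective is

    L = beta_x * MSE(X, X_hat) + beta_c * CE(C, C_hat)
        + beta_w * CE(W, W_hat) + beta_kl * KL(u_bar || Uniform(k_u)),

with all four weights defaulting to 1.0.  The KL term is computed on the
batch-mean latent distribution `u_bar` (a per-sample variant is available
via `kld_mode`); penalizing the aggregate distribution directly targets
prior collapse, which is the term's purpose.  At inference the latent is
deterministic: `softmax(logits / 0.1)`, hardened by argmax with the
lowest index winning exact ties.

**B. Latent estimator.**  A 15 -> 32 -> 32 -> `k_u` ReLU network is
trained with per-dimension sigmoid binary cross-entropy against the
frozen autoencoder's one-hot labels.  Its outputs, renormalized to the
simplex, provide the posterior `P(U = i | X)` (BCE trains a multi-label
surface; renormalization reconciles it with the distribution the
adjustment needs — a softmax head is available via `posterior_mode`).
Averaging posteriors over the source cohort gives `P(U)`; over any
target cohort, `Q(U)`.

**C. Shift-adjusted hazard model.**  A (15 + `k_u`) -> 32 -> 32 -> 1
ReLU network outputs a log hazard ratio and is trained by minimizing the
Cox negative log partial likelihood (Breslow convention for tied event
times) on minibatches, with the latent input taken from the autoencoder.
The baseline cumulative hazard `H0(t)` is the Breslow estimator on the
training risk scores.  The model is then fine-tuned on the source data
with the latent input replaced by the estimator's hard labels (what will
actually be available at deployment), at one tenth the learning rate.
For a cohort to be scored, the hazard ratio is the posterior-weighted
mixture rescaled by the estimated prevalence ratio:

    r_Q(x) = sum_i HR(x, U=i) * P(U=i | x) * Q(U=i) / max(P(U=i), 1e-6),

and the predicted survival curve is `S(t | x) = exp(-H0(t) * r_Q(x))`.
The sum runs over the `k_u` latent classes.  By default the weights
`P(U=i|x) * ratio_i` are **not** renormalized per patient; setting
`normalize_adjusted_posterior` renormalizes them, which is the exact
change-of-prior posterior update and a statistically coherent variant.
At inference the model estimates the shift of whatever cohort it scores,
treating that cohort as a single target domain; on source-distributed
data the estimated ratio is close to one and the adjustment is close to
the identity.

All networks train with Adam (learning rate 0.01), batch size 256, and
early stopping on a validation loss with patience 10.  The hazard nets
additionally use decoupled L2 weight decay (1e-3) and dropout (0.2) on
hidden activations: with only a few hundred events, an unregularized MLP
overfits the partial likelihood within a few epochs, and these are the
standard remedies for MLP survival nets.  Features are standardized by
the training-cohort mean and standard deviation before every network;
the scaler is stored in each checkpoint.

## Evaluation

* **Concordance.**  Harrell's C over admissible pairs, with tied risk
  scores counting one half; an optional horizon (default 60 months)
  first censors administratively at that month.  A pair is admissible
  when one patient's event is observed strictly before the other's time,
  or at the same recorded time as the other's censoring.  Inputs with no
  admissible pairs return 0.5 with a warning.  No IPCW weighting is
  applied.
* **AUC over time.**  Cumulative/dynamic AUC on months 2-58: at month
  `t`, cases are patients with an observed event by `t`, controls those
  still at risk after `t`; patients censored by `t` are excluded.
  Months with no cases or no controls are reported as missing, never
  interpolated.
* **Bootstrap.**  Percentile intervals from 100 full-size resamples with
  replacement.  The resample indices are a function of the seed and the
  sample size only, so every model is evaluated on the same resamples —
  the comparisons are paired.  A subsample-without-replacement mode
  exists behind `method="subsample"`.
* **Log-rank.**  Standard two-group chi-square (1 df) over shared event
  times; the per-site report uses the largest site as the reference by
  default.
* **Disparity.**  Max minus min of the per-site C-indices, the summary
  used to judge cross-site equalization.

## The synthetic cohort generator

No suitable multi-site recurrence cohort is publicly available, so the
package ships a generator that realizes the same causal graph the model
assumes: `U ~ Categorical(pi_domain)`; `X | U` Gaussian per class,
truncated to valid ranges (percentages to [0, 100], TIL density to
nonnegative); `C | U` and `W | U` categorical; event times Weibull
proportional hazards with log hazard
`b_x . x_std + b_u[U] + b_stage[C]`, and uniform administrative
censoring on [0, 60] months.  Source and target share every structural
distribution except `pi`; the hazard standardizes features with the
analytic source-mixture moments in both domains so the structural model
is domain-invariant.  Hidden columns (true class, true linear predictor,
uncensored time) are emitted for testing only.

Two presets are provided.

* `default_multisite_config`: the cohort-shape preset — 2,411 source
  patients over five sites (60/10/30 train/validation/test), 938 target
  patients over three sites, three latent subgroups with prevalence
  (0.5, 0.3, 0.2) shifting to (0.2, 0.3, 0.5), a stage mix of roughly
  20/40/40, subgroup centroids about one within-class standard deviation
  apart, and subgroup log hazard ratios (-0.8, 0.1, 0.9).  The centroid
  spacing is deliberate: the framework is about subgroups that are
  informative but *not* identifiable from the features with certainty.
  If classes are separable, the latent posterior is one-hot for every
  patient and the adjustment degenerates to a per-class rescaling with
  nothing to correct.
* `two_class_shift_config`: two subgroups mixed 80/20 in the source and
  20/80 in the target, with a configurable centroid separation
  (default 2 within-class standard deviations; the ratio-recovery tests
  use 6, i.e. effectively separable classes) and the hazard carried
  entirely by the subgroup (class log-HR -0.8 / +0.8).

What the generator does **not** emulate: realistic covariance among
histopathology features (classes are axis-aligned Gaussians), informative
censoring, site-specific measurement noise or staining effects on `X`
beyond what the subgroup induces, and any violation of proportional
hazards.  Passing tests on this generator therefore show that the
implementation behaves as the theory predicts when the latent-shift
assumption holds exactly; they do not show that the assumption holds in
any particular real cohort.

## What the adjustment can and cannot do here

Two structural facts shape the test expectations and are worth stating
plainly.

1. **Two-class scenarios are rank-degenerate.**  With two latent classes
   and a proportional-hazards generator, both the adjusted and the
   unadjusted mixture scores are increasing functions of the same
   posterior probability, so their patient *rankings* — and hence
   C-indices — coincide up to fitting noise.  The adjustment's ranking
   benefit needs at least three classes; the two-class preset is used
   where its simplicity helps (ratio recovery, no-shift parity), the
   three-class preset for the debiasing properties.
2. **The measured effects are small.**  On the three-class preset the
   adjustment's average effect across ten seeds is on the order of
   +0.003 external and -0.001 internal C-index.  An oracle computation
   with the true posteriors and true prevalence ratios bounds the
   achievable effect at roughly +0.01 under this geometry, and the
   estimator's nearly-hard posteriors (it predicts a deterministic label)
   capture only part of it.  The debiasing tests therefore assert the
   direction of mean/median effects over ten seeds, not magnitudes.

## Numerical and degenerate-input conventions

* Prevalence denominators are floored at `epsilon_prevalence = 1e-6`.
* Argmax ties harden to the lowest index everywhere.
* A training cohort with a single site (or stage) label disables the
  corresponding auxiliary head with a warning.
* A latent class absent from the training cohort is retained with its
  floored prevalence and a warning.
* Cohorts with zero events are rejected for hazard fitting; all-censored
  evaluation inputs yield C = 0.5 with a warning; log-rank with no
  events returns (0, 1) with a warning.
* Every stage derives its seed from the experiment seed via
  `crc32(stage_name)`, so runs are bit-reproducible end to end and any
  stage can be re-run from cached upstream artifacts.

## Problem sizes in the test suite

The suite exercises the full pipeline at the preset cohort sizes
(2,411 / 938) for ten seeds, ratio recovery at 5,000 / 5,000 for five
seeds, and unit properties on small fixtures; the complete run takes
under a minute on one CPU.  Checkpoints are JSON documents (the networks
are small), which keeps artifacts diffable and portable.

## Known limitations

* The latent estimator is trained toward a deterministic label, so its
  posterior sharpens as it converges; genuinely soft subgroup
  uncertainty is represented only near decision boundaries.  This bounds
  how much of the oracle adjustment the pipeline can realize.
* The KL-toward-uniform term biases latent usage toward balance; when
  the true subgroup mix is far from uniform this shifts the learned
  boundary and compresses estimated prevalence ratios toward one.
* Baselines consume features only; whether stage should be included as a
  baseline covariate is left to the user (it is available in the table).
* Single target domain per adjustment call; per-site adjustment is done
  by calling the shift estimation per site.
* No competing risks, time-varying covariates, or stratified baselines.
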