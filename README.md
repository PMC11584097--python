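# causalsurv

Survival prediction that holds up across hospitals, when the cause of
cross-site bias is unknown.

`causalsurv` is for biostatisticians and ML researchers working with
multi-site clinical cohorts — the motivating case is recurrence-free
survival of colorectal-cancer patients described by 15 quantitative
histopathology features — who observe that a model trained at some sites
degrades, unevenly, at others.  The package treats this as *latent
shift*: an unobserved discrete subgroup `U` drives the features `X`, the
tumor stage `C` (a concept variable), the treating site `W` (a proxy
variable), and the outcome `Y`, and external sites differ from internal
ones only in the mix of `U`.

## The model

Three components, trained on the source cohort:

* **A** — a discrete-latent autoencoder: a single affine encoder into
  `k_u` Gumbel-softmax logits with annealed temperature, an affine
  decoder, and auxiliary stage/site heads, trained with

  `L = β_X·MSE(X, X̂) + β_C·CE(C, Ĉ) + β_W·CE(W, Ŵ) + β_kl·KL(Û ‖ Ũ)`

  where `Ũ` is the uniform prior over the `k_u` classes.
* **B** — a latent estimator: a small MLP predicting the frozen
  autoencoder's latent label from `X` alone, yielding `P(U=i|X)` and the
  prevalences `P(U)`, `Q(U)`.
* **C** — a hazard model over `(X, one-hot U)` trained by Cox partial
  likelihood with a Breslow baseline `H₀(t)`.  For new data the hazard
  ratio is rescaled by the estimated latent shift:

  `HR_Q(t, x) = H₀(t) · Σᵢ HR_P(x, U=i) · P(U=i|x) · Q(U=i)/P(U=i)`

Evaluation follows the survival-analysis standards: Harrell's C-index at
a 60-month horizon with seeded paired-bootstrap confidence intervals,
cumulative/dynamic AUC over months 2–58, per-site breakdowns with a
disparity summary, and log-rank comparisons against a reference site.

Because the motivating registry data are not public, the package
includes a first-class synthetic cohort generator that realizes the same
causal graph with known ground truth (subgroup labels, true risk,
uncensored times), so every stage of the pipeline is verifiable.

## Worked example

```python
import causalsurv as cs

cfg = cs.default_multisite_config(seed=7)     # 2,411 source / 938 target
source = cs.simulate_domain(cfg, "P")         # internal cohort, 5 sites
target = cs.simulate_domain(cfg, "Q")         # external cohort, 3 sites

training = cs.TrainingConfig(seed=7, max_epochs=150)
model = cs.fit_pipeline(source.table, target.table, training, "full")

external = target.table
internal = source.table.subset("internal-test")
for name, cohort in (("internal", internal), ("external", external)):
    adj = model.risk_scores(cohort)                    # shift-adjusted
    un = model.risk_scores(cohort, adjusted=False)     # ratio ≡ 1
    ca = cs.concordance_index(cohort.time, cohort.event, adj, horizon=60)
    cu = cs.concordance_index(cohort.time, cohort.event, un, horizon=60)
    print(f"{name}: C-index adjusted {ca:.4f} | unadjusted {cu:.4f}")
print("target latent prevalence ratio Q(U)/P(U):",
      [float(round(r, 2)) for r in model.shift.ratio])
```

prints

```
internal: C-index adjusted 0.7559 | unadjusted 0.7588
external: C-index adjusted 0.7169 | unadjusted 0.7171
target latent prevalence ratio Q(U)/P(U): [0.44, 2.05, 1.09, 0.79, 1.17, 0.77, 2.9, 0.47, 0.4, 0.34]
```

The ratio vector is the estimated target-versus-source prevalence of the
ten latent classes: values far from 1 (here 0.34–2.9) are the detected
subgroup shift.  Discrimination is in the 0.70–0.76 range on both
cohorts; the adjustment's per-seed effect on the C-index is small (here
−0.003 internal, −0.000 external for this seed), which is why its
direction — a small external gain bought with a small internal loss —
is assessed as an average over seeds in the test suite rather than from
a single run.  See `docs/methods.md` for the analysis of when and why
the effect is bounded.

The same pipeline is scriptable from a shell:

```bash
causalsurv simulate --preset multisite --seed 7 --out-prefix data/cohort
causalsurv run --preset multisite --seed 7 --out runs/full
causalsurv ablate --preset multisite --seed 7 --out runs/ablation
```

`run` writes checkpoints (`ae.json`, `estimator.json`, `risk.json`),
the shift estimate, and per-domain site reports; `ablate` produces a
four-row table (full model, no shift adjustment, latent-only,
features-only) with internal/external C-indices and bootstrap CIs.
Individual stages (`train-ae`, `train-estimator`, `estimate-shift`,
`train-risk`, `adapt`, `predict`, `train-baseline`, `evaluate`) are also
exposed.

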