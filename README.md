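# bedsidebn

A Bayesian-network analysis pipeline for clinicians' bedside estimates of
cardiac function in ICU patients. It covers the full chain:

- **cohort_model** — variable specs, cohort CSV I/O, discretization of raw
  clinical measurements (configurable cutoffs, boundary values fall in the
  lower bin), and Cramér's V association screening.
- **structure_learning** — Max-Min Hill-Climbing: MMPC candidate
  restriction with G² conditional-independence tests, then greedy search
  under the BDeu score with black/whitelists.
- **consensus** — nonparametric bootstrap of the learner, per-arc strength
  and direction coefficients, the L1-optimal significance threshold with a
  0.700 strength floor, the 0.666 direction rule, and expert orientation
  of edges left undirected.
- **inference** — CPT fitting, exact posteriors by variable elimination,
  sequential query trees, ancestral sampling, and Markov-blanket
  prediction of the estimate.
- **synthetic_cohort** — a generative ground-truth network calibrated so
  exact forward inference reproduces the published marginal prevalences
  (noradrenaline 49%, mechanical ventilation 59%, ...) and the four
  ventilation/noradrenaline-conditioned probabilities of a
  reasonable-or-good estimate (0.63 / 0.91 / 0.67 / 0.93). The study
  cohort itself is not publicly deposited; this module is the stand-in.
- **diagnostics** — dichotomization (estimate poor/moderate vs
  reasonable/good; cardiac index at 2.2 L/min/m²), 2×2 tables, accuracy
  metrics with Wilson and log-method CIs, exhaustive reconstruction of the
  published pooled 2×2 table from its printed summaries, and 10-fold
  cross-validated prediction scored by tie-corrected AUROC.

## CLI

Each stage is independently invocable and fully seeded:

```sh
bedsidebn simulate  --seed 1 --n 1073 --out out/        # synthetic cohort
bedsidebn learn     --seed 1 --out out/                 # single MMHC fit
bedsidebn consensus --seed 1 --replicates 2000 --out out/
bedsidebn query     --out out/ -e mechanical_ventilation=yes -e noradrenaline=yes
bedsidebn tree      --out out/                          # sequential query tree
bedsidebn evaluate  --seed 1 --out out/                 # dx metrics + 10-fold CV
bedsidebn reproduce --seed 1 --out out/                 # the whole chain
```

Defaults (discretization cutoffs, calibration targets, thresholds) live in
`src/bedsidebn/data/defaults.yaml`; pass `--config my.yaml` to override
learning parameters. Every artifact is stamped with the seed and a hash of
the effective configuration.

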