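# choicelab

Simulation and cross-laboratory analysis of a standardized two-alternative
forced-choice (2AFC) visual wheel task for head-fixed mice.

The package provides, end to end and without any external data:

- **`choicelab.task`** — the task protocol itself: staged contrast
  introduction, 20:80 / 80:20 block schedules with truncated-geometric
  lengths, debiasing repeat trials, quiescence sampling, and session-ending
  rules.
- **`choicelab.cohort`** — a generative simulator of mice, labs, and full
  training histories. Choices follow a logistic trial-history model (visual
  evidence, previous rewarded/unrewarded choice, bias, block prior); learning
  is a saturating-exponential scaling of the visual weights. Lab identity
  affects only learning speed; trained behavior is drawn from one cross-lab
  distribution.
- **`choicelab.psychometrics`** — the four-parameter erf psychometric model
  (left/right lapse rates, bias, contrast threshold): evaluation, multistart
  binomial maximum-likelihood fitting, and block-wise bias shifts.
- **`choicelab.status`** — the automated training-proficiency criteria
  (basic-task versions 1a/1b and full-task), plus cohort learning summaries
  with a Kaplan-Meier cumulative-proportion-trained curve.
- **`choicelab.glm`** — the trial-history logistic choice GLM: design-matrix
  construction, penalized ML fitting, condition-number and
  predictive-accuracy diagnostics, and Laplace-approximation confidence
  bands.
- **`choicelab.reproducibility`** — the cross-lab assessment: per-mouse
  featurization, subsampled leave-one-out lab-membership classification with
  a shuffle null and a timezone positive control, cross-lab statistical
  tests with FDR control, and a slow-learner predictor.
- **`choicelab.io`** — the trials-table CSV schema with strict validation,
  YAML config handling, and the CLI.

## CLI

All subcommands accept `--seed`, `--config`, `--out-dir`, `--log-level`.

```sh
# simulate a 2-lab synthetic cohort (trained-state sessions)
choicelab simulate --seed 1 --labs 2 --mice-per-lab 2 --out-dir out/

# fit psychometric curves and the choice GLM per mouse
choicelab fit-psychometric --trials out/trials.csv --out-dir out/
choicelab fit-glm --trials out/trials.csv --variant basic --out-dir out/

# evaluate proficiency criteria
choicelab assess-status --trials out/trials.csv --version 1a --out-dir out/

# lab-membership classification from a per-mouse feature CSV
choicelab classify-labs --features features.csv --classifier naive_bayes \
    --repeats 2000 --mode data --seed 1 --out-dir out/
```

## Reproducibility

Every source of randomness flows through a single seeded
`numpy.random.Generator`; identical seeds give byte-identical outputs.
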