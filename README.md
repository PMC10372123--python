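# spanlearn

Hierarchical Bayesian modelling of learning in visual working-memory span
tasks.

Per-item accuracy in a 6-alternative span task is described by a Weibull
(Quick) psychometric function of memory set size, anchored at 100% accuracy
for set size 0, a 1/6 guessing floor for very large set sizes, and exactly
50% at its threshold parameter.  The threshold evolves over trials as a
saturating exponential (start value, asymptote, half-time in trials), fitted
hierarchically across participants and between-subject conditions.  The
package provides:

- **`spanlearn.core_model`** — the closed-form psychometric function,
  exponential threshold trajectory, monotone cross-block parameter schedule,
  capacity conversion (threshold / 2), and the disaggregated Bernoulli
  log-likelihood.
- **`spanlearn.synthetic_data`** — seeded generators reproducing the task
  design: 4 blocks x 30 trials, set sizes 2-6 (six occurrences each per
  block, first five trials ascending 2-6), six stimulus rotations 28 degrees
  apart per block, and constant / per-block / per-trial-random
  stimulus-to-button mappings across five conditions.
- **`spanlearn.fit`** — static per-participant maximum-likelihood Weibull
  fits feeding the capacity >= 1 exclusion filter, plus the hierarchical
  time-evolving model.  Sampling is done by a self-contained No-U-Turn
  sampler (multinomial trees, dual-averaging step size, dense metric from
  the Laplace covariance at the mode) with analytic gradients, or by a
  Laplace approximation at the posterior mode (fast mode for calibration
  studies); random effects support per-parameter centered / non-centered
  parameterization.  Convergence is summarized by split r-hat and tail
  effective sample size via ArviZ.
- **`spanlearn.inference`** — draw-wise posterior contrasts with the
  "95% credible interval excludes zero" reliability rule and a standard
  battery (within-condition learning magnitude, between-condition offsets,
  block-1 vs block-4 differences).
- **`spanlearn.model_compare`** — item-level pointwise log-likelihoods and
  PSIS-LOO comparison of full versus reduced (one-flexible-parameter)
  cross-block models.
- **`spanlearn.io` / `spanlearn.cli`** — CSV/JSON file formats, schema
  validation, and the end-to-end pipeline.

Two model timescales are supported: threshold as a function of the overall
trial number 1-120 (`timescale="overall_1_120"`), and within-block trials
1-30 with monotone cross-block changes in start / rate / asymptote
(`timescale="within_block_1_30"`, `cross_block="full"` or a reduced
one-parameter variant).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form
anchors, likelihood oracle, exclusion filter, parameter recovery, null
calibration, LOO structure recovery, and the NUTS convergence contract);
the convergence contract alone runs a full 4-chain production fit and takes
a few minutes on one CPU.

## CLI

```bash
# simulate a five-condition cohort (defaults mirror the study design)
spanlearn simulate --seed 1 --out runs/sim

# static fits + capacity >= 1 exclusion filter
spanlearn exclude runs/sim/trials.csv --out runs/ex

# fit the hierarchical learning model (draws CSV + diagnostics JSON)
spanlearn fit runs/ex/trials_retained.csv --method nuts --out runs/fit

# contrast battery and Markdown report
spanlearn contrast runs/fit --out runs/contrast

# PSIS-LOO comparison of several fits of the same table
spanlearn compare runs/ex/trials_retained.csv runs/fitA runs/fitB --out runs/cmp

# everything end to end, with an artifact manifest
spanlearn pipeline --seed 1 --out runs/full
```

All file indices are 1-based (trials 1-120); `correct` and `dual_task` are
0/1 integers.

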