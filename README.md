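# lamsim

Simulation-based benchmarking of superficial-bias correction metrics for
laminar gradient-echo BOLD fMRI.

High-resolution GE-BOLD signal amplitudes increase toward the cortical
surface, confounding comparisons of task effects across cortical layers.
`lamsim` implements a generative model of laminar fMRI data from a blocked
visual-attention paradigm — layer-dependent attentional gain on voxel neural
populations, HRF convolution, a multiplicative superficial bias, low-rank
physiological noise that scales with the bias and additive Rician thermal
noise that does not — together with seven candidate bias-correction metrics
and a Monte-Carlo harness that scores how well each metric recovers the
ground-truth laminar attention profile.

## Metrics

| metric | input | idea |
|---|---|---|
| voxel ratio | contrasts | mean of per-voxel TaskD+/TaskD− ratios |
| ROI ratio | contrasts | ratio of layer-summed contrasts |
| Deming regression | contrasts | orthogonal (errors-in-variables) slope of TaskD+ on TaskD− |
| z-scoring | timeseries | temporally z-score each run before the GLM |
| L2 normalization | betas | normalize each voxel's condition betas to unit norm |
| SVM | per-block betas | leave-one-run-out linear SVM (C=1) decoding accuracy |
| LDC | betas + residuals | cross-validated, noise-whitened linear discriminant contrast |

A raw layer-mean contrast profile is always computed as the uncorrected
baseline, and every profile is summarized by two scores: a superficial-bias
score (dot product of the mean-normalized profile with [1, 0, −1]) and an
attentional-modulation score (with [0.5, −1, 0.5]).

## Usage

```python
from lamsim import experiment

scenario = experiment.make_scenario("selective")          # defaults: 2500 voxels,
summary = experiment.run_monte_carlo(scenario,            # a=[3,2,3], sigma_p=11,
                                     n_iterations=200,    # sigma_t=15
                                     base_seed=0)
print(summary.summary_frame())
print(summary.median_scores("deming"))                    # (bias, attention)
```

Named scenarios: `selective` (defaults), `no_preference` (folded-normal
counts, no region-mean category preference), `high_noise`
(sigma_p=20, sigma_t=30) and `noiseless`.

### CLI

```bash
lamsim run --scenario selective --n-iter 200 --seed 0 --n-voxels 2500 --out results/
lamsim sweep --config sweep.yaml --out sweep.csv
lamsim metrics --contrasts contrasts.csv            # real-data entry point
```

`lamsim run` writes `iterations.csv`, `summary.csv`, `summary.json` and
`metadata.json`. `lamsim metrics` consumes a tidy CSV with columns
`voxel_id, layer, taskdplus, taskdminus` (layers: superficial/middle/deep)
and computes the univariate metrics.

## Layout

- `lamsim.design` — block-design schedules on a TR-aligned grid
- `lamsim.neural_model` — voxel populations, attentional gain, true contrasts
- `lamsim.bold_sim` — HRF convolution, noise model, superficial bias
- `lamsim.glm` — per-run OLS fits, detrending, contrast estimates, t-stats
- `lamsim.metrics` — the seven metrics + contribution scores
- `lamsim.experiment` — scenarios, Monte-Carlo harness, sweeps, CLI backend
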