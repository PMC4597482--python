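# lgnpool

Pooling-model analysis linking lateral geniculate nucleus (LGN) neural
responses to two-alternative forced-choice (2AFC) contrast-detection
behavior.

In a 2AFC contrast-detection task, single LGN parvocellular (P) and
magnocellular (M) neurons are far less sensitive than the observer (mean
single-neuron threshold ~54% contrast against a behavioral threshold of
~5.8%), yet their trial-to-trial fluctuations covary weakly with the
observer's choices (choice probability ~0.54 on blank trials). `lgnpool`
asks how a downstream decision stage could pool such neurons to produce the
observed behavior: how many cells, integrated over which time window, read
out with which weighting scheme?

The package provides, for researchers in systems neuroscience and
psychophysics:

- **Synthetic populations** of P/M cells calibrated to the published summary
  statistics of an 89-neuron awake-macaque LGN dataset (composition
  41 ON-P / 27 OFF-P / 19 ON-M / 2 OFF-M; threshold, Fano factor, and
  d′-distribution shape per class), since the original recordings are not
  public. Each cell is a baseline rate plus Naka–Rushton contrast drive with
  a two-phase temporal profile (M cells faster and more transient than P).
- **Signal-detection measurement tools** that also work on user-supplied
  per-trial spike-count tables: criterion-sweep ROC curves and areas,
  neurometric functions, blank-trial choice probability with the standard
  inclusion rules (choice ratio in (0.25, 4), ≥10 trials per side),
  permutation tests, d′, interquartile range and skewness index.
- **The Weibull 2AFC performance function** `P(c) = 1 − 0.5·exp(−(c/α)^β)`,
  with threshold α (the 82%-correct contrast) and slope β, fitted by
  deterministic bounded least squares.
- **A decision-pool simulator**: pools of `n_p + n_m` cells sampled with
  replacement, correlated Gaussian spike counts (within-class correlation
  `r`, P–M correlation, Fano factor `f`), a weighted-sum readout
  `X_pooled = Σ wᵢxᵢ` under six schemes (uniform, amplitude-per-trial, mean
  amplitude or d′ with per-class or joint normalization), downstream pooling
  noise `p`, and choice by comparing test- vs reference-side pooled
  activity. Each experiment yields a simulated psychophysical threshold and
  per-member choice probabilities.
- **Evaluation**: a goodness-of-fit index
  `GoF = (1 − ⅓(|ΔT|/T + |ΔCP_P|/CP_P + |ΔCP_M|/CP_M))·100%` against the
  measured behavior, plus sweep and scheme-comparison machinery over pool
  size × window × scheme grids.

## Worked example

```python
import lgnpool as lp

population = lp.default_population(seed=1)
summary = lp.population_summary(population, window=150, seed=1)
print(f"neurons: {summary.n_neurons}")
print(f"mean neurometric threshold: {summary.threshold_mean:.1f}% contrast")

cfg = lp.PoolConfig(n_p=512, n_m=512, scheme="uniform", n_reps=50, seed=2)
result = lp.run_experiment(population, cfg)
print(f"simulated threshold: {result.mean_threshold:.2f} ± {result.sem_threshold:.2f}% contrast")
print(f"P choice probability: {result.cp_mean('P'):.3f}")
print(f"M choice probability: {result.cp_mean('M'):.3f}")
print(f"GoF: {lp.gof_of_result(result, lp.ReferenceTargets()):.1f}%")
```

prints

```
neurons: 89
mean neurometric threshold: 54.4% contrast
simulated threshold: 2.46 ± 0.06% contrast
P choice probability: 0.539
M choice probability: 0.546
GoF: 80.5%
```

The generated population reproduces the measured mean single-neuron
threshold (54.4% contrast in the 0–150 ms window). Pooling 512 P and 512 M
cells uniformly at the measured noise parameters (`f = 1.03`, `r = 0.028`,
P–M correlation 0.01, `p = 2.0`) yields member choice probabilities near
0.54, matching the recordings — but a simulated behavioral threshold of
~2.5% contrast, well below the measured 5.76%: a pool this large overshoots
the observer, which is why the GoF stays at ~80% and peaks instead at
intermediate pool sizes.

The same analyses are scriptable from the shell:

```bash
lgnpool generate --seed 1 --out runs/population
lgnpool simulate runs/population/population.csv --scheme dprime_separate --out runs/sim
lgnpool sweep runs/population/population.csv --sizes 16,64,256 --windows 50,150 \
    --schemes uniform,dprime_separate --reps 20 --out runs/sweep
lgnpool report runs/sweep/sweep_summary.csv --out runs/report
```

## Layout

- `src/lgnpool/synthetic_population.py` — population generator, response
  model, session simulator, serialization
- `src/lgnpool/psychometrics.py` — Weibull evaluation and fitting
- `src/lgnpool/signal_detection.py` — ROC/AUC, choice probability,
  permutation tests, d′, distribution descriptors
- `src/lgnpool/pooling_model.py` — pool sampling, readout weighting, trial
  simulation, experiments
- `src/lgnpool/evaluation.py` — GoF, sweeps, scheme comparison, heatmaps
- `src/lgnpool/cli.py` — `lgnpool generate | simulate | sweep | report`
- `docs/methods.md` — model assumptions, calibration and numerical choices
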