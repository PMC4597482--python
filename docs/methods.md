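# Methods

## The model in brief

The package implements a bottom-up pooling account of 2AFC contrast
detection. On each simulated trial, every neuron in a decision pool emits a
Gaussian spike count whose mean and variance come from its contrast-response
model; the pool's weighted sum is computed once for the test side (stimulus
contrast) and once for the reference side (0% contrast), each corrupted by
downstream pooling noise, and the model chooses the side with the larger
value. Percent correct across contrasts is fitted with the Weibull 2AFC
performance function to give a simulated psychophysical threshold, and the
covariation between each member's blank-trial counts and the model's
blank-trial choices gives that member's choice probability (CP). Simulations
are scored against the measured behavior (threshold 5.76% contrast, P and M
choice probabilities 0.54) with a relative-error goodness-of-fit index.

## Synthetic populations

The original recordings are not available, so populations are generated to
emulate their published summary statistics. Each cell has

- a baseline rate `b` (spikes/s, lognormal per class),
- a Naka–Rushton contrast drive `r_max·c^h/(c^h + c50^h)` with lognormal
  semisaturation contrast `c50` (wide for P, median 30%; narrow for M,
  median 9%) and a fixed per-class Hill exponent (P 1.2, M 2.2),
- a two-phase temporal profile: a fraction `transience` of the full
  0–200 ms response is emitted between the response latency and 50 ms, the
  rest between 50 and 200 ms. M cells are faster (latency 15 ms vs 40 ms)
  and more transient (mean 0.62 vs 0.30) than P cells.

The spike-count mean in a 0–t ms window is (baseline + drive) × 0.2 s × the
profile fraction accrued by t; the variance is Fano × mean, with the Fano
factor a window-level scalar (1.40 at 25 ms declining to 0.80 at 200 ms,
1.03 at 150 ms, matching the measured 0.8–1.4 range).

**Sensitivity-targeted sampling.** The decisive property of the dataset is
the shape of the per-class d′ distributions at 0–150 ms (P: mean 1.70,
median 1.40, IQR 2.05, skewness 0.73; M: mean 1.69, median 1.69, IQR 1.25,
skewness 0.12). No lognormal parameterization of `r_max`/`c50` can produce
these shapes: a lognormal wide enough for the P IQR implies a skewness near
5, and M's wide-but-symmetric distribution is inconsistent with any
lognormal. Each cell's d′ at the calibration conditions (0–150 ms window,
Fano 1.03, 99% contrast vs blank) is therefore drawn directly from a
per-class skew-normal — P: shape 1.29, loc 0.33, scale 1.98; M: shape
−0.96, loc 2.29, scale 1.12, floored at 0.05 — and `r_max` is solved in
closed form so the cell realizes exactly that d′. The M parameters
reproduce all four printed descriptors; the P targets are jointly
infeasible for a three-parameter family, so mean/IQR/skewness are matched
exactly and the median comes out at 1.52 rather than 1.40. Sampling is
stratified (quantile midpoints in seed-shuffled order), so every generated
population matches the calibrated marginals rather than matching them only
in expectation.

**Calibration.** With d′ pinned, the free `c50` medians were set by a
coarse search so the population's mean neurometric threshold at 0–150 ms
(nine characterization contrasts 0–99%, 50 simulated trials per side per
contrast, criterion-sweep ROC + Weibull fit) reproduces the measured
54.4 ± 4.78%; the shipped defaults give 54.5 ± 0.9% across 20 generation
seeds. Calibration search drivers live under `scratch/` and are not re-run
at test time.

**Threshold ceiling.** A threshold is a contrast, so the Weibull fit bounds
α at 100%: cells (or pools) that never reach 82%-correct ROC area within
the physical contrast range are reported at the ceiling and flagged
unconverged but still enter population averages. This convention matters:
about 40% of P cells have d′ below the 1.27 needed to ever reach the
82%-correct criterion under the Gaussian ROC identity, and their ceiling
values are what bring the population mean to ~54%. An unbounded or
higher-bounded fit would push the mean far above the measured value while
leaving every individual cell's sensitivity unchanged.

**What the generator does not emulate.** Counts are truncated Gaussians,
not point-process counts; there is no adaptation, no eye-movement or
attentional state, no session-to-session nonstationarity, and OFF cells are
treated identically to ON cells in count space (the stimulus is assumed
optimal-sign per cell). Within-class parameter correlations are absent
(independent quantile pairing). Tests passing on this population show that
the analysis machinery behaves correctly under the published summary
statistics, not that real LGN data would yield the same numbers.

## Measurement conventions

- **ROC area**: trapezoidal area over all observed-count criteria; exactly
  the pairwise-comparison (Mann–Whitney) statistic with ties credited 0.5.
- **Choice probability**: blank trials only, grouped by choice; estimates
  are only made when the choice-in/choice-out ratio lies strictly in
  (0.25, 4) and both sides have ≥10 trials, otherwise the neuron/repetition
  is excluded outright. Per-contrast CP is available but never aggregated
  into a grand CP.
- **Permutation test**: one-sided (area > 0.5), 2,000 shuffles by default,
  with the +1 small-sample correction in numerator and denominator.
- **d′**: `(x̄ − x̄₀)/√((s² + s₀²)/2)` between the highest available
  contrast ≥80% and blank; signs are preserved. A cell silent in a window
  has d′ = 0 by continuity.
- **IQR**: linear-interpolation quartiles (the numpy default); stated
  because quartile conventions change small-sample IQRs.
- **Skewness index**: population moments (1/n in both numerator and
  variance), no bias correction.
- **Weibull fitting**: least squares on proportions over a fixed log-spaced
  grid (α in [0.5, 100], β in [0.3, 8]) followed by bounded trust-region
  refinement — deterministic by construction. Blank points are dropped (the
  function is pinned at 0.5 there); data never rising meaningfully above
  chance yield an unconverged flag, never an exception, so sweeps tolerate
  insensitive pools. Binomial maximum likelihood would be the main
  alternative; least squares was chosen for robustness at 50 trials per
  point and to match the classical procedure for this task.

## Pooling simulator choices

- **Reference side**: an independent same-pool draw at 0% per trial (a
  two-interval observer). A shared draw would make blank trials degenerate
  and CP undefined.
- **Correlated counts**: a three-factor construction (private,
  class-shared, global) yields exact block correlations `r_within` within
  P and within M and `r_between` across; it requires
  `r_between ≤ r_within`, validated at configuration time. Defaults are the
  measured 0.028 / 0.01.
- **Clipping**: Gaussian draws are clipped at zero (counts are
  non-negative). Clipping slightly attenuates low-mean variances — the
  empirical Fano of simulated blank counts is ~0.93 for a nominal 1.03 —
  and an unclipped variant is available via `PoolConfig(clip_negative=False)`
  (used by the analytic-oracle tests).
- **Pooling noise**: added once per side with variance `p × max(pooled, 0)`,
  `p` defaulting to 2.0 (the Fano factor of the downstream stage).
- **Weights**: uniform = 1.0 exactly; mean-amplitude and d′ schemes
  normalize so the best member of the normalization group (per class, or
  the whole pool) carries exactly 1.0; amplitude-per-trial computes weights
  at trial time (`wᵢ ∝ xᵢ`, per side, best member at 1.0). Negative d′
  members keep signed weights by default (`clip_negative_weights` clips
  them); a class silent in a window gets weight 0 under per-class
  normalization.
- **Trials and contrasts**: 50 trials per contrast over
  {0, 2, 4, 8, 16}% (five levels, log-spaced around the behavioral
  threshold; the original per-session levels are not published) and 200
  pool resamplings by default. Blank trials enter only CP, never the
  percent-correct fit.
- **CP summaries**: repetition-mean-then-mean (`how="by_rep"`) and pooled
  over all member-repetitions (`how="pooled"`) are both available, since
  either summary of the 200 repetitions is defensible; they agree to ~1e-3
  at default sizes.
- **Seeding**: every stage takes an explicit seed; sweeps spawn one child
  seed per grid cell in grid order, so identical calls are bit-identical
  and cached cells (keyed by a hash of the full cell configuration) can be
  reused on resume. Characterization noise is keyed to (seed, cell
  parameters) rather than list position, so identical cells measure
  identically.

## Problem sizes in the shipped checks

The test suite and the acceptance script use scaled-down repetition counts
chosen as the smallest sizes at which the checked quantities are stable:
50 pool resamplings for the choice-probability reproductions (stable to
±0.002 across master seeds), 20 generation seeds for calibration, and
4-repetition experiments across 20 seeds with sign tests for the parametric
trends. Full-scale runs (200 repetitions, 1–512 cells per class, six
windows) are available through the same interfaces.

## Known limitations

- The short-window (25–50 ms) absolute thresholds depend on the assumed
  latencies and transience values more than any published statistic
  constrains them; only the qualitative orderings (M-heavy pools better at
  short windows, d′ weighting beating uniform there) should be compared.
- Member-level d′–CP correlations at 512 cells per class are positive but
  very small in this architecture, since a single member's share of the
  decision variable scales as 1/n; they are demonstrated at moderate pool
  sizes.
- The GoF index is not clamped: very poor fits go negative.
- No differential (information-limiting) correlations, feedback, or
  attention terms are modeled.
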