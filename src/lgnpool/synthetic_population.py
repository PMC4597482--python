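"""Synthetic LGN parvocellular/magnocellular populations.

Real recordings from the detection task are not public, so the package
ships a generator whose populations emulate the printed summary statistics
of the recorded dataset: 89 cells (41 ON-P, 27 OFF-P, 19 ON-M, 2 OFF-M), a
mean neurometric threshold of ~54.4% contrast at 0–150 ms against a
behavioral threshold of 5.76%, window-resolved Fano factors near 1, a wide
and positively skewed P d-prime distribution against a narrow, symmetric M
distribution, and M temporal profiles faster and more transient than P.

Each neuron is a baseline rate plus a Naka-Rushton contrast drive
``r_max * c**h / (c**h + c50**h)``, spread over time by a two-phase
piecewise-constant profile: a fraction ``transience`` of the full 0–200 ms
response is emitted between ``latency_ms`` and 50 ms, the rest between 50
and 200 ms. Spike-count variance is Fano × mean, with the Fano factor a
window-level configuration scalar.

Per-class parameters are drawn by stratified (quantile-midpoint) sampling
with seed-dependent pairing, so every generated population matches the
calibrated marginal distributions rather than matching them only in
expectation; the seed shuffles which cell gets which quantile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, skewnorm

from .config import (
    DEFAULT_FANO_BY_WINDOW,
    TaskConfig,
    ReferenceTargets,
    logger,
    validate_window,
)
from .psychometrics import WeibullFit, weibull_eval
from .signal_detection import (
    DPrimeInputs,
    dprime,
    iqr,
    neurometric_function,
    skewness_index,
)

#: Stimulus presentation time (ms); the full response window.
STIMULUS_MS = 200.0
#: Boundary between the early (transient) and late (sustained) response phase.
EARLY_PHASE_END_MS = 50.0


@dataclass(frozen=True)
class NeuronProfile:
    """One synthetic LGN cell (see module docstring for the response model)."""

    neuron_id: str
    cell_class: str  # "P" or "M"
    polarity: str  # "ON" or "OFF"
    baseline_rate: float  # spikes/s
    r_max: float  # spikes/s
    c50: float  # % contrast
    hill_exponent: float
    transience: float  # fraction of the 0-200 ms response in [latency, 50 ms]
    latency_ms: float

    def __post_init__(self) -> None:
        if self.cell_class not in ("P", "M"):
            raise ValueError("cell_class must be 'P' or 'M'")
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")
        if self.baseline_rate < 0 or self.r_max <= 0:
            raise ValueError("rates must be non-negative (r_max positive)")
        if not 0 < self.c50 <= 100:
            raise ValueError("c50 must lie in (0, 100]")
        if self.hill_exponent <= 0:
            raise ValueError("hill_exponent must be positive")
        if not 0 <= self.transience <= 1:
            raise ValueError("transience must lie in [0, 1]")
        if not 0 <= self.latency_ms < EARLY_PHASE_END_MS:
            raise ValueError("latency_ms must lie in [0, 50)")


#: Conditions under which the per-class sensitivity (d-prime) distributions
#: are defined: the 0-150 ms window, its Fano factor, and the high contrast
#: used for the d-prime numerator.
CALIBRATION_WINDOW = 150
CALIBRATION_FANO = 1.03
CALIBRATION_CONTRAST = 99.0
#: Floor for sampled target d-primes (a cell must respond at least weakly).
DPRIME_FLOOR = 0.05


@dataclass(frozen=True)
class ClassParams:
    """Sampling distributions for one cell class.

    Baseline rate and semisaturation contrast are lognormal (median +
    log-sd); transience is a clipped normal; latency and the Hill exponent
    are fixed per class. Each cell's contrast sensitivity is pinned by a
    target d-prime drawn from a skew-normal (shape/loc/scale) defined at
    the calibration conditions (0-150 ms, Fano 1.03, 99% contrast); the
    Naka-Rushton amplitude r_max is then solved in closed form so the cell
    realizes exactly that d-prime. This gives direct control over the
    population's sensitivity distribution — its spread and skewness differ
    sharply between P and M cells — while c50 and the temporal profile
    govern how sensitivity translates into thresholds and window effects.
    """

    baseline_median: float
    baseline_sigma: float
    dprime_shape: float
    dprime_loc: float
    dprime_scale: float
    c50_median: float
    c50_sigma: float
    hill: float
    transience_mean: float
    transience_sd: float
    latency_ms: float

    def __post_init__(self) -> None:
        for name in ("baseline_median", "c50_median", "hill", "dprime_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("baseline_sigma", "c50_sigma", "transience_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# Calibrated once against the printed dataset statistics (per-class d-prime
# mean/median/IQR/skewness and the 54.4% mean neurometric threshold at
# 0-150 ms) by coarse search; see scratch/calibrate*.py for the drivers.
# Not re-fit at run time.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "P": ClassParams(
        baseline_median=15.0,
        baseline_sigma=0.45,
        dprime_shape=1.2928,
        dprime_loc=0.3312,
        dprime_scale=1.9811,
        c50_median=30.0,
        c50_sigma=0.80,
        hill=1.2,
        transience_mean=0.30,
        transience_sd=0.06,
        latency_ms=40.0,
    ),
    "M": ClassParams(
        baseline_median=20.0,
        baseline_sigma=0.35,
        dprime_shape=-0.9612,
        dprime_loc=2.2895,
        dprime_scale=1.1181,
        c50_median=9.0,
        c50_sigma=0.30,
        hill=2.2,
        transience_mean=0.62,
        transience_sd=0.07,
        latency_ms=15.0,
    ),
}


@dataclass(frozen=True)
class PopulationConfig:
    """Composition, sensitivity spread and seed of a synthetic population."""

    n_on_p: int = 41
    n_off_p: int = 27
    n_on_m: int = 19
    n_off_m: int = 2
    sensitivity_spread: Mapping[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    fano_by_window: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FANO_BY_WINDOW)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_on_p, self.n_off_p, self.n_on_m, self.n_off_m):
            if n < 0:
                raise ValueError("neuron counts must be non-negative")
        for w, f in self.fano_by_window.items():
            validate_window(int(w))
            if not 0.25 <= f <= 3.0:
                raise ValueError(f"fano {f} for window {w} outside [0.25, 3.0]")


# ---------------------------------------------------------------------------
# Response model
# ---------------------------------------------------------------------------

def _response_fraction_raw(t_ms: float, lat: float, tr: float) -> float:
    if t_ms <= lat:
        return 0.0
    if t_ms <= EARLY_PHASE_END_MS:
        return tr * (t_ms - lat) / (EARLY_PHASE_END_MS - lat)
    late = (t_ms - EARLY_PHASE_END_MS) / (STIMULUS_MS - EARLY_PHASE_END_MS)
    return tr + (1.0 - tr) * min(late, 1.0)


def _response_fraction(profile: NeuronProfile, t_ms: float) -> float:
    """Fraction of the full 0-200 ms response accrued by t_ms."""
    return _response_fraction_raw(t_ms, profile.latency_ms, profile.transience)


def contrast_drive(profile: NeuronProfile, contrast: float) -> float:
    """Naka-Rushton contrast drive in spikes/s (0 at blank, r_max asymptote)."""
    if contrast == 0:
        return 0.0
    ch = contrast**profile.hill_exponent
    return profile.r_max * ch / (ch + profile.c50**profile.hill_exponent)


def response_stats(
    neuron: NeuronProfile, contrast: float, window: int, fano: float
) -> tuple[float, float]:
    """Mean and variance of the spike count in the 0-``window`` ms window.

    Mean = (baseline + contrast drive) x stimulus duration x the fraction
    of the temporal profile falling in [latency, window]; variance is
    Fano x mean. Monotone in both contrast and window length.
    """
    validate_window(window)
    if not 0 <= contrast <= 100:
        raise ValueError("contrast must lie in [0, 100]")
    rate = neuron.baseline_rate + contrast_drive(neuron, contrast)
    mean = rate * (STIMULUS_MS / 1000.0) * _response_fraction(neuron, window)
    return mean, fano * mean


def response_moments(
    population: list[NeuronProfile], contrast: float, window: int, fano: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vector of (means, sds) over a population at one contrast/window."""
    stats = [response_stats(n, contrast, window, fano) for n in population]
    means = np.array([m for m, _ in stats])
    sds = np.sqrt([v for _, v in stats])
    return means, np.asarray(sds)


def neuron_dprime(
    neuron: NeuronProfile, window: int, fano: float, high_contrast: float
) -> float:
    """High-contrast-vs-blank d-prime from the analytic response moments.

    A cell silent in the window (e.g. its latency exceeds the window) has
    no signal and no variance; its d-prime is 0 by continuity.
    """
    m1, v1 = response_stats(neuron, high_contrast, window, fano)
    m0, v0 = response_stats(neuron, 0.0, window, fano)
    if v1 + v0 == 0:
        return 0.0
    return dprime(DPrimeInputs(m1, m0, np.sqrt(v1), np.sqrt(v0)))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _stratified_quantiles(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quantile midpoints (i + 0.5)/n in a seed-dependent random order."""
    return rng.permutation((np.arange(n) + 0.5) / n)


def _rmax_for_dprime(
    d: np.ndarray,
    baseline: np.ndarray,
    c50: np.ndarray,
    hill: float,
    transience: np.ndarray,
    latency: float,
) -> np.ndarray:
    """Naka-Rushton amplitude realizing a target d-prime at the calibration
    conditions. With blank mean m0 and stimulus-driven increment D (counts),
    d = D / sqrt(f (D + 2 m0) / 2) solves to
    D = (q + sqrt(q^2 + 8 q m0)) / 2 with q = d^2 f / 2."""
    frac = np.array(
        [
            _response_fraction_raw(CALIBRATION_WINDOW, latency, t)
            for t in np.atleast_1d(transience)
        ]
    )
    area = (STIMULUS_MS / 1000.0) * frac  # effective seconds at 150 ms
    m0 = baseline * area
    q = d**2 * CALIBRATION_FANO / 2.0
    delta = (q + np.sqrt(q**2 + 8.0 * q * m0)) / 2.0
    ch = CALIBRATION_CONTRAST**hill
    drive_frac = ch / (ch + c50**hill)
    return delta / (area * drive_frac)


def _draw_class(
    cls: str, n: int, params: ClassParams, rng: np.random.Generator
) -> list[dict]:
    if n == 0:
        return []
    z_b = norm.ppf(_stratified_quantiles(n, rng))
    z_c = norm.ppf(_stratified_quantiles(n, rng))
    z_t = norm.ppf(_stratified_quantiles(n, rng))
    q_d = _stratified_quantiles(n, rng)
    baseline = params.baseline_median * np.exp(params.baseline_sigma * z_b)
    c50 = np.clip(params.c50_median * np.exp(params.c50_sigma * z_c), 0.5, 100.0)
    trans = np.clip(
        params.transience_mean + params.transience_sd * z_t, 0.02, 0.98
    )
    d_target = np.clip(
        skewnorm.ppf(
            q_d, params.dprime_shape,
            loc=params.dprime_loc, scale=params.dprime_scale,
        ),
        DPRIME_FLOOR,
        None,
    )
    rmax = _rmax_for_dprime(
        d_target, baseline, c50, params.hill, trans, params.latency_ms
    )
    return [
        dict(
            cell_class=cls,
            baseline_rate=float(baseline[i]),
            r_max=float(rmax[i]),
            c50=float(c50[i]),
            hill_exponent=params.hill,
            transience=float(trans[i]),
            latency_ms=params.latency_ms,
        )
        for i in range(n)
    ]


def generate_population(config: PopulationConfig | None = None) -> list[NeuronProfile]:
    """Generate a synthetic population; deterministic given ``config.seed``."""
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(cfg.seed)
    spread = cfg.sensitivity_spread
    records = _draw_class("P", cfg.n_on_p + cfg.n_off_p, spread["P"], rng)
    records += _draw_class("M", cfg.n_on_m + cfg.n_off_m, spread["M"], rng)
    polarity = (
        ["ON"] * cfg.n_on_p + ["OFF"] * cfg.n_off_p
        + ["ON"] * cfg.n_on_m + ["OFF"] * cfg.n_off_m
    )
    return [
        NeuronProfile(
            neuron_id=f"{rec['cell_class']}{i:03d}", polarity=pol, **rec
        )
        for i, (rec, pol) in enumerate(zip(records, polarity), start=1)
    ]


# ---------------------------------------------------------------------------
# Characterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSummary:
    """Calibration-facing summary of one generated population."""

    n_neurons: int
    window: int
    threshold_mean: float
    threshold_sem: float
    dprime_stats: dict[str, dict[str, float]]
    mean_fano: float
    thresholds: np.ndarray
    converged_fraction: float


def _simulated_counts(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    return np.clip(mean + sd * rng.standard_normal(n), 0.0, None)


def _neuron_rng(neuron: NeuronProfile, seed: int) -> np.random.Generator:
    """Measurement noise tied to the cell's parameters, not its position:
    identical cells characterized under the same seed see identical trials."""
    import hashlib

    key = hashlib.md5(
        repr(
            (
                neuron.baseline_rate, neuron.r_max, neuron.c50,
                neuron.hill_exponent, neuron.transience, neuron.latency_ms,
            )
        ).encode()
    ).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed, int.from_bytes(key[:8], "little")])
    )


def neuron_trial_counts(
    neuron: NeuronProfile, task: TaskConfig, rng: np.random.Generator
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Simulated inside/outside spike counts per contrast for one neuron."""
    fano = task.fano_resolved
    out = {}
    m0, v0 = response_stats(neuron, 0.0, task.window, fano)
    for c in task.contrasts:
        m, v = response_stats(neuron, c, task.window, fano)
        inside = _simulated_counts(m, np.sqrt(v), task.trials_per_contrast, rng)
        outside = _simulated_counts(m0, np.sqrt(v0), task.trials_per_contrast, rng)
        out[float(c)] = (inside, outside)
    return out


def population_summary(
    population: list[NeuronProfile],
    window: int = 150,
    task: TaskConfig | None = None,
    seed: int = 0,
) -> PopulationSummary:
    """Neurometric thresholds, d-prime shape and Fano factor of a population.

    Every neuron's inside/outside counts are simulated at the
    characterization contrasts, per-contrast ROC areas are fitted with the
    Weibull performance function, and the fitted thresholds are averaged.
    Thresholds of insensitive cells sit at the fit's upper bound (their
    fits are flagged unconverged but still enter the average). The d-prime
    descriptors use the analytic response moments at the high contrast.
    """
    if not population:
        raise ValueError("population is empty")
    task = task or TaskConfig(window=window)
    if task.window != window:
        task = TaskConfig(
            contrasts=task.contrasts,
            trials_per_contrast=task.trials_per_contrast,
            window=window,
            fano=task.fano,
        )
    fano = task.fano_resolved
    thresholds, converged, fanos = [], [], []
    for neuron in population:
        counts = neuron_trial_counts(neuron, task, _neuron_rng(neuron, seed))
        _, fit = neurometric_function(counts)
        thresholds.append(fit.alpha)
        converged.append(fit.converged)
        for inside, _ in counts.values():
            if inside.mean() > 0:
                fanos.append(inside.var() / inside.mean())
    thresholds = np.asarray(thresholds)

    dstats: dict[str, dict[str, float]] = {}
    for cls in ("P", "M"):
        dvals = np.array(
            [
                neuron_dprime(n, window, fano, task.high_contrast)
                for n in population
                if n.cell_class == cls
            ]
        )
        if dvals.size >= 4:
            dstats[cls] = {
                "mean": float(dvals.mean()),
                "median": float(np.median(dvals)),
                "iqr": iqr(dvals),
                # degenerate (zero-spread) distributions have no shape
                "skewness": (
                    skewness_index(dvals) if dvals.std() > 0 else float("nan")
                ),
            }
    sem = float(thresholds.std(ddof=1) / np.sqrt(len(thresholds))) if len(
        thresholds
    ) > 1 else 0.0
    return PopulationSummary(
        n_neurons=len(population),
        window=window,
        threshold_mean=float(thresholds.mean()),
        threshold_sem=sem,
        dprime_stats=dstats,
        mean_fano=float(np.mean(fanos)),
        thresholds=thresholds,
        converged_fraction=float(np.mean(converged)),
    )


# ---------------------------------------------------------------------------
# Session simulation (fixture generator for the measurement toolkit)
# ---------------------------------------------------------------------------

def cp_from_coupling(coupling: float) -> float:
    """Exact blank-trial choice probability for a given noise-decision
    correlation, under the bivariate-normal model:
    CP = 1/2 + (2/pi) * arcsin(rho / sqrt(2))."""
    return 0.5 + (2.0 / np.pi) * np.arcsin(coupling / np.sqrt(2.0))


def coupling_for_cp(cp: float) -> float:
    """Inverse of :func:`cp_from_coupling`."""
    return float(np.sqrt(2.0) * np.sin(np.pi * (cp - 0.5) / 2.0))


def simulate_session(
    neuron: NeuronProfile,
    coupling: float,
    task: TaskConfig | None = None,
    seed: int = 0,
    behavioral_threshold: float = 5.76,
    behavioral_slope: float = 1.5,
) -> pd.DataFrame:
    """Simulate a 2AFC session for one neuron with a controllable choice link.

    Each trial draws the stimulus side at random, the neuron's count from
    its Gaussian response model (the stimulus drives the cell only when it
    falls in the receptive field), and a latent Gaussian decision variable
    correlated at ``coupling`` with the neuron's count noise. On stimulus
    trials the decision variable carries a signal scaled so the simulated
    observer's percent correct follows a Weibull with the given behavioral
    threshold and slope; blank-trial choices therefore have probability 0.5
    of either side, and the blank-trial choice probability increases with
    ``coupling`` following :func:`cp_from_coupling`.
    """
    if not 0 <= coupling < 1:
        raise ValueError("coupling must lie in [0, 1)")
    task = task or TaskConfig()
    rng = np.random.default_rng(seed)
    fano = task.fano_resolved
    ref = WeibullFit(behavioral_threshold, behavioral_slope, 0.0)
    rows = []
    trial = 0
    for c in task.contrasts:
        k = norm.ppf(weibull_eval(ref, c)) if c > 0 else 0.0
        for _ in range(task.trials_per_contrast):
            stim_in = bool(rng.integers(2))
            m, v = response_stats(neuron, c if stim_in else 0.0, task.window, fano)
            z = rng.standard_normal()
            count = max(m + np.sqrt(v) * z, 0.0)
            noise = coupling * z + np.sqrt(1 - coupling**2) * rng.standard_normal()
            decision = noise + (k if stim_in else -k)
            rows.append(
                dict(
                    trial_id=trial,
                    contrast_pct=float(c),
                    stim_side="in_rf" if stim_in else "out_rf",
                    choice_side="in_rf" if decision > 0 else "out_rf",
                    spike_count=count,
                )
            )
            trial += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "neuron_id", "cell_class", "polarity", "baseline_rate", "r_max",
    "c50", "hill_exponent", "transience", "latency_ms",
]


def save_population(
    population: list[NeuronProfile],
    config: PopulationConfig,
    out_dir: str | Path,
    stem: str = "population",
) -> tuple[Path, Path]:
    """Write the population CSV and its JSON config sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    pd.DataFrame([asdict(n) for n in population])[_CSV_COLUMNS].to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    cfg = asdict(config)
    cfg["sensitivity_spread"] = {
        k: asdict(v) if isinstance(v, ClassParams) else dict(v)
        for k, v in config.sensitivity_spread.items()
    }
    cfg["fano_by_window"] = {int(k): v for k, v in config.fano_by_window.items()}
    json_path.write_text(json.dumps(cfg, indent=2))
    logger.info("wrote %d neurons to %s", len(population), csv_path)
    return csv_path, json_path


def load_population(csv_path: str | Path) -> list[NeuronProfile]:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    return [
        NeuronProfile(
            neuron_id=str(r.neuron_id),
            cell_class=str(r.cell_class),
            polarity=str(r.polarity),
            baseline_rate=float(r.baseline_rate),
            r_max=float(r.r_max),
            c50=float(r.c50),
            hill_exponent=float(r.hill_exponent),
            transience=float(r.transience),
            latency_ms=float(r.latency_ms),
        )
        for r in df.itertuples()
    ]


def default_population(seed: int = 0) -> list[NeuronProfile]:
    """The default calibrated 89-neuron population for a given seed."""
    return generate_population(PopulationConfig(seed=seed))


def calibration_report(
    seeds: range | list[int] = range(20),
    window: int = 150,
    refs: ReferenceTargets | None = None,
) -> pd.DataFrame:
    """Per-seed summary statistics against the reference targets."""
    refs = refs or ReferenceTargets()
    rows = []
    for s in seeds:
        pop = default_population(seed=s)
        summ = population_summary(pop, window=window, seed=s)
        rows.append(
            dict(
                seed=s,
                threshold_mean=summ.threshold_mean,
                p_dprime_mean=summ.dprime_stats["P"]["mean"],
                m_dprime_mean=summ.dprime_stats["M"]["mean"],
                p_iqr=summ.dprime_stats["P"]["iqr"],
                m_iqr=summ.dprime_stats["M"]["iqr"],
                p_skew=summ.dprime_stats["P"]["skewness"],
                m_skew=summ.dprime_stats["M"]["skewness"],
            )
        )
    return pd.DataFrame(rows)
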