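"""Decision-pool simulator.

A pool of n_p + n_m neurons is sampled with replacement from a population.
On every trial two correlated Gaussian response vectors are drawn — the
test side at the trial contrast and the reference side at 0% — with each
member's mean and variance given by its response model, block noise
correlations (r_within inside a cell class, r_between across classes), and
counts clipped at zero. The pooled signal is a weighted sum (one of six
readout schemes), each side is corrupted by downstream pooling noise of
variance p x pooled mean, and the model chooses the side with the larger
noisy signal. Percent correct over contrasts yields a simulated
psychophysical threshold via the Weibull fit; blank-trial responses and
choices yield per-member choice probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PoolConfig, logger
from .psychometrics import fit_weibull
from .signal_detection import choice_probability_matrix
from .synthetic_population import (
    NeuronProfile,
    neuron_dprime,
    response_moments,
)

_STATIC_SCHEMES = (
    "uniform", "mean_amp_separate", "mean_amp_joint",
    "dprime_separate", "dprime_joint",
)


@dataclass(frozen=True)
class PoolSample:
    """Pool membership: profiles (with-replacement duplicates kept distinct)."""

    members: list[NeuronProfile]
    indices: np.ndarray  # positions in the source population
    classes: np.ndarray  # "P"/"M" per member

    def __len__(self) -> int:
        return len(self.members)


def sample_pool(
    population: list[NeuronProfile], n_p: int, n_m: int, rng: np.random.Generator
) -> PoolSample:
    """Sample n_p P cells and n_m M cells with replacement, within class."""
    idx_by_class = {
        cls: np.flatnonzero([n.cell_class == cls for n in population])
        for cls in ("P", "M")
    }
    parts = []
    for cls, n in (("P", n_p), ("M", n_m)):
        if n == 0:
            continue
        if idx_by_class[cls].size == 0:
            raise ValueError(f"population has no {cls} cells but n_{cls.lower()}={n}")
        parts.append(rng.choice(idx_by_class[cls], size=n, replace=True))
    indices = np.concatenate(parts) if parts else np.array([], dtype=int)
    members = [population[i] for i in indices]
    classes = np.array([m.cell_class for m in members])
    return PoolSample(members=members, indices=indices, classes=classes)


def assign_weights(
    sample: PoolSample,
    scheme: str,
    window: int,
    fano: float,
    high_contrast: float = 99.0,
    clip_negative: bool = False,
) -> np.ndarray | None:
    """Readout weights for a pool under one of the six schemes.

    uniform: all weights exactly 1. mean_amp_*: proportional to the mean
    response at the high contrast; dprime_*: proportional to the member's
    d-prime (high contrast vs blank). The *_separate variants normalize so
    the best member of each cell class carries weight 1.0; the *_joint
    variants normalize the whole pool to one maximum. amp_per_trial defers
    weighting to trial time (per-trial weights proportional to the
    member's response that trial) and returns None here. Negative d-primes
    keep their sign unless ``clip_negative`` is set.
    """
    n = len(sample)
    if scheme == "uniform":
        return np.ones(n)
    if scheme == "amp_per_trial":
        return None
    if scheme.startswith("mean_amp"):
        raw, _ = response_moments(sample.members, high_contrast, window, fano)
    elif scheme.startswith("dprime"):
        raw = np.array(
            [neuron_dprime(m, window, fano, high_contrast) for m in sample.members]
        )
        if clip_negative:
            raw = np.clip(raw, 0.0, None)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if np.all(raw == 0):
        raise ValueError("all-zero reference quantities for the pool")
    weights = np.empty(n)
    if scheme.endswith("_separate"):
        for cls in np.unique(sample.classes):
            mask = sample.classes == cls
            ref = np.abs(raw[mask]).max()
            if ref == 0:
                # a class silent in this window contributes nothing
                weights[mask] = 0.0
            else:
                weights[mask] = raw[mask] / ref
    else:  # joint
        weights = raw / np.abs(raw).max()
    return weights


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def _class_index(classes: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(classes, return_inverse=True)
    return inv, len(uniq)


def _draw_correlated(
    mu: np.ndarray,
    sd: np.ndarray,
    class_inv: np.ndarray,
    n_classes: int,
    r_within: float,
    r_between: float,
    n_trials: int,
    rng: np.random.Generator,
    clip: bool,
) -> np.ndarray:
    """(n_members, n_trials) Gaussian draws with exact block correlations.

    Three-factor construction: private + class-shared + global standard
    normal factors with loadings sqrt(1-r_w), sqrt(r_w-r_b), sqrt(r_b),
    giving Var = sd^2, within-class correlation r_w, cross-class r_b.
    """
    a = np.sqrt(1.0 - r_within)
    b = np.sqrt(r_within - r_between)
    g = np.sqrt(r_between)
    z = a * rng.standard_normal((mu.size, n_trials))
    if b > 0:
        z += b * rng.standard_normal((n_classes, n_trials))[class_inv]
    if g > 0:
        z += g * rng.standard_normal(n_trials)
    x = mu[:, None] + sd[:, None] * z
    if clip:
        np.clip(x, 0.0, None, out=x)
    return x


def _pool_signal(x: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    """Weighted pooled signal per trial; None weights = amplitude-per-trial."""
    if weights is not None:
        return weights @ x
    peak = x.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(peak > 0, (x * x).sum(axis=0) / peak, 0.0)
    return pooled


def _noisy(pooled: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    if p == 0:
        return pooled
    var = p * np.clip(pooled, 0.0, None)
    return pooled + np.sqrt(var) * rng.standard_normal(pooled.shape)


def simulate_trials(
    mu_test: np.ndarray,
    sd_test: np.ndarray,
    mu_ref: np.ndarray,
    sd_ref: np.ndarray,
    classes: np.ndarray,
    weights: np.ndarray | None,
    cfg: PoolConfig,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a block of 2AFC trials for one pool at one contrast.

    Returns (choices, test_side_responses): choices is a boolean array
    (True = "in_rf", the test side) and test_side_responses the
    (n_members, n_trials) member response matrix used for choice-
    probability bookkeeping.
    """
    class_inv, n_classes = _class_index(classes)
    x_test = _draw_correlated(
        mu_test, sd_test, class_inv, n_classes,
        cfg.r_within, cfg.r_between, n_trials, rng, cfg.clip_negative,
    )
    x_ref = _draw_correlated(
        mu_ref, sd_ref, class_inv, n_classes,
        cfg.r_within, cfg.r_between, n_trials, rng, cfg.clip_negative,
    )
    s_test = _noisy(_pool_signal(x_test, weights), cfg.pooling_noise, rng)
    s_ref = _noisy(_pool_signal(x_ref, weights), cfg.pooling_noise, rng)
    choices = s_test > s_ref
    ties = s_test == s_ref
    if ties.any():
        choices = choices.copy()
        choices[ties] = rng.integers(2, size=int(ties.sum())).astype(bool)
    return choices, x_test


def simulate_trial(
    sample: PoolSample,
    weights: np.ndarray | None,
    contrast: float,
    cfg: PoolConfig,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray]:
    """One trial at one contrast; returns (choice, member responses)."""
    if contrast not in cfg.contrasts:
        raise ValueError(f"contrast {contrast} not in configured levels")
    mu_t, sd_t = response_moments(sample.members, contrast, cfg.window, cfg.fano)
    mu_r, sd_r = response_moments(sample.members, 0.0, cfg.window, cfg.fano)
    choices, x = simulate_trials(
        mu_t, sd_t, mu_r, sd_r, sample.classes, weights, cfg, 1, rng
    )
    return ("in_rf" if choices[0] else "out_rf"), x[:, 0]


# ---------------------------------------------------------------------------
# Experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Per-repetition thresholds and per-member bookkeeping of one run."""

    config: PoolConfig
    thresholds: np.ndarray
    slopes: np.ndarray
    converged: np.ndarray
    member_records: pd.DataFrame = field(repr=False)

    @property
    def mean_threshold(self) -> float:
        return float(self.thresholds.mean())

    @property
    def sem_threshold(self) -> float:
        if self.thresholds.size < 2:
            return 0.0
        return float(self.thresholds.std(ddof=1) / np.sqrt(self.thresholds.size))

    def cp_mean(self, cell_class: str, how: str = "by_rep") -> float:
        """Mean blank-trial CP over included members of one class.

        ``how="by_rep"`` averages members within each repetition first and
        then across repetitions; ``how="pooled"`` averages all included
        member-repetition values at once.
        """
        rec = self.member_records
        sel = rec[(rec.cell_class == cell_class) & (~rec.excluded)]
        if sel.empty:
            return float("nan")
        if how == "by_rep":
            return float(sel.groupby("rep")["cp"].mean().mean())
        if how == "pooled":
            return float(sel["cp"].mean())
        raise ValueError("how must be 'by_rep' or 'pooled'")

    def dprime_values(self, cell_class: str) -> np.ndarray:
        rec = self.member_records
        return rec.loc[rec.cell_class == cell_class, "dprime"].to_numpy()

    def weight_values(self, cell_class: str) -> np.ndarray:
        rec = self.member_records
        return rec.loc[rec.cell_class == cell_class, "weight"].to_numpy()

    def save(self, out_dir, stem: str = "simulation") -> None:
        from pathlib import Path
        import json
        from dataclasses import asdict as _asdict

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            dict(
                rep=np.arange(self.thresholds.size),
                threshold=self.thresholds,
                slope=self.slopes,
                converged=self.converged,
            )
        ).to_csv(out / f"{stem}_thresholds.csv", index=False)
        self.member_records.to_csv(out / f"{stem}_members.csv", index=False)
        (out / f"{stem}_config.json").write_text(
            json.dumps(_asdict(self.config), indent=2)
        )


def run_experiment(
    population: list[NeuronProfile], cfg: PoolConfig
) -> SimulationResult:
    """Run the full pooling experiment: n_reps independent pool samplings,
    each with trials_per_contrast trials at every configured contrast,
    Weibull-fitted percent correct, and blank-trial member CPs (the
    ratio and >=10-per-side inclusion rules applied per repetition)."""
    rng = np.random.default_rng(cfg.seed)
    pop_mu = {}
    pop_sd = {}
    for c in cfg.contrasts:
        pop_mu[c], pop_sd[c] = response_moments(
            population, c, cfg.window, cfg.fano
        )
    pop_dprime = np.array(
        [
            neuron_dprime(n, cfg.window, cfg.fano, cfg.high_contrast)
            for n in population
        ]
    )
    nonzero = sorted(c for c in cfg.contrasts if c > 0)
    thresholds, slopes, converged, rec_frames = [], [], [], []
    for rep in range(cfg.n_reps):
        sample = sample_pool(population, cfg.n_p, cfg.n_m, rng)
        weights = assign_weights(
            sample, cfg.scheme, cfg.window, cfg.fano,
            cfg.high_contrast, cfg.clip_negative_weights,
        )
        pc = []
        cps = None
        for c in cfg.contrasts:
            choices, x_test = simulate_trials(
                pop_mu[c][sample.indices], pop_sd[c][sample.indices],
                pop_mu[0.0][sample.indices], pop_sd[0.0][sample.indices],
                sample.classes, weights, cfg, cfg.trials_per_contrast, rng,
            )
            if c == 0:
                labels = np.where(choices, "in_rf", "out_rf")
                cps = choice_probability_matrix(x_test, labels)
            else:
                pc.append(choices.mean())
        fit = fit_weibull(nonzero, pc)
        thresholds.append(fit.alpha)
        slopes.append(fit.beta)
        converged.append(fit.converged)
        n = len(sample)
        rec_frames.append(
            pd.DataFrame(
                dict(
                    rep=np.full(n, rep),
                    member=np.arange(n),
                    neuron_id=[m.neuron_id for m in sample.members],
                    cell_class=sample.classes,
                    weight=np.full(n, np.nan) if weights is None else weights,
                    dprime=pop_dprime[sample.indices],
                    cp=np.full(n, np.nan) if cps is None else cps,
                    excluded=np.full(n, cps is None),
                )
            )
        )
    logger.debug(
        "run_experiment: scheme=%s n_p=%d n_m=%d t=%d reps=%d",
        cfg.scheme, cfg.n_p, cfg.n_m, cfg.window, cfg.n_reps,
    )
    return SimulationResult(
        config=cfg,
        thresholds=np.asarray(thresholds),
        slopes=np.asarray(slopes),
        converged=np.asarray(converged),
        member_records=pd.concat(rec_frames, ignore_index=True),
    )
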