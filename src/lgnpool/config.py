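"""Shared configuration objects, constants and defaults.

The defaults encode the study conditions: a 2AFC contrast-detection task,
spike counts integrated in cumulative windows 0–t ms from stimulus onset,
and a downstream pooling stage parameterized by a Fano factor, interneuronal
noise correlations and pooling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

logger = logging.getLogger("lgnpool")

#: Valid cumulative integration windows (0–t ms).
WINDOWS_MS: tuple[int, ...] = (25, 50, 75, 100, 150, 200)

#: The six pooling/readout schemes.
SCHEMES: tuple[str, ...] = (
    "uniform",
    "amp_per_trial",
    "mean_amp_separate",
    "mean_amp_joint",
    "dprime_separate",
    "dprime_joint",
)

#: Contrast levels used in a simulated behavioral session (percent contrast,
#: 0 = blank). Five levels, log-spaced around the behavioral threshold.
DEFAULT_CONTRASTS: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 16.0)

#: Contrast levels used when characterizing single neurons (neurometric
#: functions, d-primes). Nine levels including blank, spanning up to 99%.
CHARACTERIZATION_CONTRASTS: tuple[float, ...] = (
    0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 99.0,
)

#: Window-resolved spike-count Fano factors (variance/mean). Short windows
#: are more variable; the 0–150 ms value is 1.03.
DEFAULT_FANO_BY_WINDOW: dict[int, float] = {
    25: 1.40, 50: 1.25, 75: 1.15, 100: 1.08, 150: 1.03, 200: 0.80,
}

#: Default noise correlations and pooling noise for simulations.
DEFAULT_R_WITHIN = 0.028
DEFAULT_R_BETWEEN = 0.01
DEFAULT_POOLING_NOISE = 2.0

#: Operational definition of "high contrast (80–99%)": the highest
#: characterization contrast at or above this level is used for mean-amplitude
#: and d-prime weighting.
HIGH_CONTRAST_MIN = 80.0


def resolve_high_contrast(contrasts: Sequence[float]) -> float:
    """Highest available contrast >= HIGH_CONTRAST_MIN, else the maximum."""
    cs = [c for c in contrasts if c >= HIGH_CONTRAST_MIN]
    return max(cs) if cs else max(contrasts)


def validate_window(window: int) -> int:
    if window not in WINDOWS_MS:
        raise ValueError(
            f"unknown integration window {window!r}; valid windows (ms): {WINDOWS_MS}"
        )
    return window


@dataclass(frozen=True)
class ReferenceTargets:
    """Measured quantities the model is evaluated against.

    ``psychometric_threshold`` is the monkeys' 82%-correct contrast;
    ``measured_cp_p``/``measured_cp_m`` are average blank-trial choice
    probabilities of P and M neurons; ``neurometric_mean`` is the average
    single-neuron threshold at 0–150 ms; ``dprime_stats`` holds per-class
    descriptors (mean, median, IQR, skewness index) of the pooled d-prime
    distributions at 0–150 ms.
    """

    psychometric_threshold: float = 5.76
    psychometric_threshold_sem: float = 0.72
    measured_cp_p: float = 0.54
    measured_cp_m: float = 0.54
    neurometric_mean: float = 54.4
    neurometric_sem: float = 4.78
    dprime_stats: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "P": {"mean": 1.70, "median": 1.40, "iqr": 2.05, "skewness": 0.73},
            "M": {"mean": 1.69, "median": 1.69, "iqr": 1.25, "skewness": 0.12},
        }
    )

    def __post_init__(self) -> None:
        for p in (self.measured_cp_p, self.measured_cp_m):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"choice probability {p} outside [0, 1]")
        for t in (self.psychometric_threshold, self.neurometric_mean):
            if not 0.0 < t <= 100.0:
                raise ValueError(f"threshold {t} outside (0, 100]")


@dataclass(frozen=True)
class TaskConfig:
    """Single-neuron characterization task: contrasts, trials and window."""

    contrasts: tuple[float, ...] = CHARACTERIZATION_CONTRASTS
    trials_per_contrast: int = 50
    window: int = 150
    fano: float | None = None  # None -> DEFAULT_FANO_BY_WINDOW[window]

    def __post_init__(self) -> None:
        validate_window(self.window)
        if self.trials_per_contrast < 1:
            raise ValueError("trials_per_contrast must be >= 1")

    @property
    def fano_resolved(self) -> float:
        return DEFAULT_FANO_BY_WINDOW[self.window] if self.fano is None else self.fano

    @property
    def high_contrast(self) -> float:
        return resolve_high_contrast(self.contrasts)


@dataclass(frozen=True)
class PoolConfig:
    """Parameters of one pooling-model experiment.

    ``n_p``/``n_m`` are pool sizes per cell class (sampled with replacement),
    ``window`` the integration window 0–t ms, ``fano`` the spike-count Fano
    factor f, ``r_within``/``r_between`` the within-class and P–M noise
    correlations, ``pooling_noise`` the downstream Fano factor p, ``scheme``
    one of the six readout schemes, and ``n_reps`` the number of independent
    pool resamplings.
    """

    n_p: int = 512
    n_m: int = 512
    window: int = 150
    fano: float = 1.03
    r_within: float = DEFAULT_R_WITHIN
    r_between: float = DEFAULT_R_BETWEEN
    pooling_noise: float = DEFAULT_POOLING_NOISE
    scheme: str = "uniform"
    contrasts: tuple[float, ...] = DEFAULT_CONTRASTS
    trials_per_contrast: int = 50
    n_reps: int = 200
    seed: int = 0
    clip_negative: bool = True
    clip_negative_weights: bool = False
    high_contrast: float = 99.0

    def __post_init__(self) -> None:
        validate_window(self.window)
        if self.scheme not in SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; valid schemes: {SCHEMES}"
            )
        if self.n_p < 0 or self.n_m < 0 or self.n_p + self.n_m == 0:
            raise ValueError("pool sizes must be >= 0 and not both 0")
        if not 0.25 <= self.fano <= 3.0:
            raise ValueError("fano must lie in [0.25, 3.0]")
        if not 0.0 <= self.r_within < 1.0 or not 0.0 <= self.r_between < 1.0:
            raise ValueError("correlations must lie in [0, 1)")
        if self.r_between > self.r_within:
            raise ValueError(
                "r_between must not exceed r_within (block-noise construction)"
            )
        if not 0.0 <= self.pooling_noise <= 4.0:
            raise ValueError("pooling_noise must lie in [0, 4.0]")
        if 0.0 not in self.contrasts:
            raise ValueError("contrasts must include the 0% (blank) level")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
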