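"""ROC analysis of spike counts: neurometric functions, choice probability,
d-prime and distribution descriptors.

All ROC areas sweep every observed spike count as a detection criterion and
integrate the (false-alarm, hit) curve by trapezoids, which coincides with
the pairwise-comparison (Mann-Whitney) statistic with ties credited 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .config import logger
from .psychometrics import WeibullFit, fit_weibull

#: Inclusion criteria for choice-probability estimates: the ratio of
#: choice-in to choice-out trials must lie strictly inside (0.25, 4) and both
#: sides need at least 10 trials.
CP_RATIO_BOUNDS = (0.25, 4.0)
CP_MIN_TRIALS = 10


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve over spike-count criteria and its area."""

    criteria: np.ndarray
    hit_rates: np.ndarray
    false_alarm_rates: np.ndarray
    auc: float


def roc_auc(pos_counts, neg_counts) -> RocCurve:
    """ROC curve for ``pos_counts`` (signal) against ``neg_counts`` (noise).

    Criteria are all distinct observed counts plus a sentinel below the
    minimum; hit and false-alarm rates are the fractions of trials strictly
    exceeding each criterion. The trapezoidal area equals the probability
    that a random positive exceeds a random negative, ties counting 0.5.
    """
    pos = np.asarray(pos_counts, dtype=float)
    neg = np.asarray(neg_counts, dtype=float)
    if pos.size == 0:
        raise ValueError("pos_counts is empty")
    if neg.size == 0:
        raise ValueError("neg_counts is empty")
    values = np.unique(np.concatenate([pos, neg]))
    criteria = np.concatenate([[values[0] - 1.0], values])
    # P(count > criterion) for each side; non-increasing in the criterion
    hit = (pos[None, :] > criteria[:, None]).mean(axis=1)
    fa = (neg[None, :] > criteria[:, None]).mean(axis=1)
    # walk the curve from the strictest criterion (0, 0) to the laxest
    # (1, 1); vertical runs at tied FA contribute zero width
    auc = float(np.trapezoid(hit[::-1], fa[::-1]))
    return RocCurve(criteria=criteria, hit_rates=hit, false_alarm_rates=fa, auc=auc)


def neurometric_function(
    per_contrast_counts: Mapping[float, tuple[Sequence[float], Sequence[float]]],
) -> tuple[dict[float, float], WeibullFit]:
    """Per-contrast ROC areas and the Weibull fit through them.

    ``per_contrast_counts`` maps contrast (%) to a pair of count lists:
    stimulus-inside-receptive-field trials and stimulus-outside trials. The
    area under each ROC curve is plotted against contrast and fitted with
    the Weibull performance function; the fitted alpha is the neurometric
    threshold. Unconverged fits are flagged, never raised.
    """
    aucs = {
        float(c): roc_auc(inside, outside).auc
        for c, (inside, outside) in per_contrast_counts.items()
    }
    nz = sorted(c for c in aucs if c > 0)
    if len(nz) < 3:
        raise ValueError("need >= 3 non-zero contrasts with trials on both sides")
    fit = fit_weibull(nz, [aucs[c] for c in nz])
    return aucs, fit


def choice_probability(blank_counts, choices) -> float | None:
    """Blank-trial choice probability, or None if the inclusion rules fail.

    Counts are grouped by the behavioral choice (``"in_rf"`` vs ``"out_rf"``)
    and the ROC area of choice-in against choice-out counts is returned.
    Estimates are only made when the choice-in/choice-out trial ratio lies
    strictly between 0.25 and 4 and each side has at least 10 trials;
    otherwise the neuron is excluded (None), never given a number.
    """
    counts = np.asarray(blank_counts, dtype=float)
    ch = np.asarray(choices)
    if counts.shape[0] != ch.shape[0]:
        raise ValueError("blank_counts and choices must have the same length")
    in_mask = ch == "in_rf"
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < CP_MIN_TRIALS or n_out < CP_MIN_TRIALS:
        return None
    ratio = n_in / n_out
    if not CP_RATIO_BOUNDS[0] < ratio < CP_RATIO_BOUNDS[1]:
        return None
    return roc_auc(counts[in_mask], counts[~in_mask]).auc


def choice_probability_matrix(count_matrix, choices) -> np.ndarray | None:
    """Vectorized blank-trial CP for many neurons sharing one choice vector.

    ``count_matrix`` is (n_neurons, n_trials). Returns a vector of ROC
    areas, or None if the trial-level inclusion rules fail (they depend only
    on the shared choices, so exclusion is all-or-none here). Uses midranks,
    equivalent to per-neuron :func:`roc_auc`.
    """
    X = np.asarray(count_matrix, dtype=float)
    ch = np.asarray(choices)
    in_mask = ch == "in_rf"
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < CP_MIN_TRIALS or n_out < CP_MIN_TRIALS:
        return None
    if not CP_RATIO_BOUNDS[0] < n_in / n_out < CP_RATIO_BOUNDS[1]:
        return None
    ranks = rankdata(X, axis=1)
    u = ranks[:, in_mask].sum(axis=1) - n_in * (n_in + 1) / 2.0
    return u / (n_in * n_out)


def permutation_test(values, labels, n_perm: int = 2000, seed: int = 0) -> float:
    """One-sided permutation p-value for an ROC area above 0.5.

    ``labels`` splits ``values`` into the positive and negative group (the
    positive group is the one whose label sorts last, e.g. "in_rf" over
    "out_rf"). The p-value is the fraction of label shuffles whose area
    reaches the observed one, with the +1 correction in numerator and
    denominator so p is never exactly 0.
    """
    vals = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("labels must contain exactly two groups")
    if n_perm < 100:
        logger.warning("permutation_test with n_perm=%d (<100) is unreliable", n_perm)
    pos_label = groups[-1]
    pos_mask = lab == pos_label
    n_pos = int(pos_mask.sum())
    rng = np.random.default_rng(seed)
    ranks_all = rankdata(vals)
    # rank-sum formulation: at fixed group sizes the ROC area is a strictly
    # increasing function of the positive-group midrank sum
    u_obs = ranks_all[pos_mask].sum()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(vals.size)[:n_pos]
        if ranks_all[perm].sum() >= u_obs - 1e-9:
            count += 1
    return (count + 1) / (n_perm + 1)


@dataclass(frozen=True)
class DPrimeInputs:
    """Response moments entering the d-prime: high-contrast vs blank."""

    x_bar: float
    x0_bar: float
    s: float
    s0: float

    def __post_init__(self) -> None:
        if self.s < 0 or self.s0 < 0:
            raise ValueError("standard deviations must be non-negative")


def dprime(inputs: DPrimeInputs) -> float:
    """Signal-to-noise separation (x̄ − x̄0) / sqrt((s² + s0²) / 2).

    The sign is preserved: a neuron suppressed by the stimulus has a
    negative d-prime.
    """
    pooled = (inputs.s**2 + inputs.s0**2) / 2.0
    if pooled <= 0:
        raise ValueError("zero pooled variance: d-prime undefined")
    return (inputs.x_bar - inputs.x0_bar) / np.sqrt(pooled)


def iqr(values) -> float:
    """Interquartile range Q3 − Q1 with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for an interquartile range")
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


def skewness_index(values) -> float:
    """Population-moment skewness: m3 / m2^(3/2), both moments with 1/n."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for a skewness index")
    d = v - v.mean()
    m2 = (d**2).mean()
    if m2 == 0:
        raise ValueError("zero variance: skewness undefined")
    return float((d**3).mean() / m2**1.5)
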