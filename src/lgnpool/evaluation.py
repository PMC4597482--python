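"""Goodness-of-fit index and sweep/report machinery.

The GoF index scores a simulation against the measured reference values by
averaging the relative errors of the simulated threshold and the P and M
choice probabilities:

    GoF = (1 - (|dT|/T + |dCP_P|/CP_P + |dCP_M|/CP_M) / 3) * 100

100% is a perfect match; the index is deliberately not clamped, so very
poor fits can go negative.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PoolConfig, ReferenceTargets, logger
from .pooling_model import SimulationResult, run_experiment
from .synthetic_population import NeuronProfile


@dataclass(frozen=True)
class GoFInputs:
    """Simulated quantities scored against the reference targets."""

    sim_threshold: float
    sim_cp_p: float
    sim_cp_m: float
    refs: ReferenceTargets


def gof(inputs: GoFInputs) -> float:
    """Goodness-of-Fit index in percent (may be negative; never clamped)."""
    refs = inputs.refs
    for name, val in (
        ("psychometric_threshold", refs.psychometric_threshold),
        ("measured_cp_p", refs.measured_cp_p),
        ("measured_cp_m", refs.measured_cp_m),
    ):
        if val == 0:
            raise ValueError(f"reference {name} is zero; GoF undefined")
    rel = (
        abs(inputs.sim_threshold - refs.psychometric_threshold)
        / refs.psychometric_threshold
        + abs(inputs.sim_cp_p - refs.measured_cp_p) / refs.measured_cp_p
        + abs(inputs.sim_cp_m - refs.measured_cp_m) / refs.measured_cp_m
    )
    return (1.0 - rel / 3.0) * 100.0


def gof_of_result(result: SimulationResult, refs: ReferenceTargets) -> float:
    return gof(
        GoFInputs(
            sim_threshold=result.mean_threshold,
            sim_cp_p=result.cp_mean("P"),
            sim_cp_m=result.cp_mean("M"),
            refs=refs,
        )
    )


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _cell_hash(cfg: PoolConfig) -> str:
    return hashlib.md5(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def sweep(
    population: list[NeuronProfile],
    pool_sizes: Sequence[tuple[int, int]],
    windows: Iterable[int],
    schemes: Iterable[str],
    base_config: PoolConfig | None = None,
    seed: int = 0,
    refs: ReferenceTargets | None = None,
    cache_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pooling experiment over a (pool size x window x scheme) grid.

    Returns (summary, per_rep): the summary has one row per grid cell with
    mean/SEM threshold, per-class mean CP, the GoF against the reference
    targets and the repetition count; per_rep holds every repetition's
    threshold for downstream bootstrap comparisons. Each cell gets a child
    seed spawned from ``seed`` in grid order, so an identical call is
    bit-reproducible. With ``cache_dir`` set, finished cells are cached on
    disk (keyed by a hash of their full config) and reused on resume.
    """
    base = base_config or PoolConfig()
    refs = refs or ReferenceTargets()
    cells = [
        (n_p, n_m, int(t), s)
        for s in schemes
        for t in windows
        for (n_p, n_m) in pool_sizes
    ]
    if not cells:
        raise ValueError("empty sweep grid")
    children = np.random.SeedSequence(seed).spawn(len(cells))
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    summary_rows, per_rep_rows = [], []
    for (n_p, n_m, t, scheme), child in zip(cells, children):
        cfg = replace(
            base,
            n_p=n_p,
            n_m=n_m,
            window=t,
            scheme=scheme,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        key = _cell_hash(cfg)
        cached = cache / f"cell_{key}.json" if cache else None
        if cached and cached.exists():
            payload = json.loads(cached.read_text())
        else:
            res = run_experiment(population, cfg)
            payload = dict(
                mean_threshold=res.mean_threshold,
                sem_threshold=res.sem_threshold,
                cp_p=res.cp_mean("P"),
                cp_m=res.cp_mean("M"),
                thresholds=res.thresholds.tolist(),
                n_reps=cfg.n_reps,
            )
            if cached:
                cached.write_text(json.dumps(payload))
        g = gof(
            GoFInputs(
                payload["mean_threshold"], payload["cp_p"], payload["cp_m"], refs
            )
        )
        summary_rows.append(
            dict(
                n_p=n_p, n_m=n_m, t_ms=t, scheme=scheme,
                f=base.fano, r=base.r_within, p=base.pooling_noise,
                mean_threshold=payload["mean_threshold"],
                sem_threshold=payload["sem_threshold"],
                cp_p=payload["cp_p"], cp_m=payload["cp_m"],
                gof=g, n_reps=payload["n_reps"], seed=seed,
            )
        )
        per_rep_rows.extend(
            dict(n_p=n_p, n_m=n_m, t_ms=t, scheme=scheme, rep=i, threshold=th)
            for i, th in enumerate(payload["thresholds"])
        )
        logger.info(
            "sweep cell n_p=%d n_m=%d t=%d scheme=%s: threshold=%.2f gof=%.1f",
            n_p, n_m, t, scheme, payload["mean_threshold"], g,
        )
    return pd.DataFrame(summary_rows), pd.DataFrame(per_rep_rows)


def compare_schemes(
    tables: dict[str, pd.DataFrame],
    per_rep: pd.DataFrame | None = None,
    baseline: str = "uniform",
    n_boot: int = 1000,
    seed: int = 0,
    gof_target: float = 90.0,
) -> dict[str, pd.DataFrame]:
    """Differences of each scheme against the uniform baseline.

    ``tables`` maps scheme name to its sweep summary (all on an identical
    (n_p, n_m, t) grid). Returns per-cell threshold/GoF differences,
    per-window marginal mean differences with bootstrap CIs over grid cells
    (and over repetitions when ``per_rep`` is given), and per-(window,
    scheme) records of the best GoF and the smallest pool achieving
    ``gof_target``.
    """
    if baseline not in tables:
        raise ValueError(f"baseline scheme {baseline!r} missing from tables")
    keys = ["n_p", "n_m", "t_ms"]
    base = tables[baseline].sort_values(keys).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    cell_rows, marginal_rows, best_rows = [], [], []
    for scheme, tab in tables.items():
        tab = tab.sort_values(keys).reset_index(drop=True)
        if not tab[keys].equals(base[keys]):
            raise ValueError(f"grid of scheme {scheme!r} does not match baseline")
        d_thr = tab.mean_threshold.to_numpy() - base.mean_threshold.to_numpy()
        d_gof = tab.gof.to_numpy() - base.gof.to_numpy()
        for i, row in tab.iterrows():
            cell_rows.append(
                dict(
                    scheme=scheme, n_p=row.n_p, n_m=row.n_m, t_ms=row.t_ms,
                    d_threshold=d_thr[i], d_gof=d_gof[i],
                )
            )
        for t in sorted(tab.t_ms.unique()):
            mask = (tab.t_ms == t).to_numpy()
            dt, dg = d_thr[mask], d_gof[mask]
            boots = np.array(
                [
                    dt[rng.integers(0, dt.size, dt.size)].mean()
                    for _ in range(n_boot)
                ]
            )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            marginal_rows.append(
                dict(
                    scheme=scheme, t_ms=int(t),
                    d_threshold_mean=dt.mean(), d_threshold_lo=lo,
                    d_threshold_hi=hi, d_gof_mean=dg.mean(),
                )
            )
            sub = tab[mask]
            good = sub[sub.gof > gof_target]
            best_rows.append(
                dict(
                    scheme=scheme, t_ms=int(t),
                    max_gof=float(sub.gof.max()),
                    min_n_good=(
                        int((good.n_p + good.n_m).min()) if not good.empty else None
                    ),
                )
            )
    return dict(
        cells=pd.DataFrame(cell_rows),
        marginals=pd.DataFrame(marginal_rows),
        best=pd.DataFrame(best_rows),
    )


def render_heatmap(
    summary: pd.DataFrame,
    value: str,
    out_path: str | Path,
    scheme: str | None = None,
) -> Path:
    """Render per-window (n_p x n_m) grids of a sweep quantity to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = summary if scheme is None else summary[summary.scheme == scheme]
    if tab.empty:
        raise ValueError("no sweep rows to render")
    windows = sorted(tab.t_ms.unique())
    fig, axes = plt.subplots(
        1, len(windows), figsize=(4 * len(windows), 3.4), squeeze=False
    )
    for ax, t in zip(axes[0], windows):
        pivot = tab[tab.t_ms == t].pivot_table(
            index="n_m", columns="n_p", values=value
        )
        im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns)
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        ax.set_xlabel("n P cells")
        ax.set_ylabel("n M cells")
        ax.set_title(f"{value}, 0–{t} ms")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
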