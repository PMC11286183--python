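"""Simulation protocols built on the urn and memory models.

Parameter sweeps over the encoding parameter L and the domain-similarity
parameter Sim, simulation-based grid fitting of L to an observed
citation distribution, quantile-median aggregation of repeated runs,
citation-probability trajectories by final-count quantile, and the
uncited/skew summaries the sweeps report.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .base import CitationCounts, RunResult, as_counts
from .errors import (
    DegenerateSampleError,
    InsufficientDataError,
    MissingTrajectoryError,
    ParameterError,
    ShapeError,
)
from .memory import MemoryParams, run_memory
from .stats import a_statistic, adjusted_overlap, overlap_index, upper_bound

__all__ = [
    "DEFAULT_L_LEVELS",
    "DEFAULT_SIM_LEVELS",
    "DEFAULT_QUANTILES",
    "SweepResult",
    "LFitResult",
    "skewness",
    "uncited_proportion",
    "aggregate_quantile_median",
    "sweep_L",
    "sweep_Sim",
    "fit_L",
    "trajectories",
]

#: Encoding levels of the demonstration L sweep (Sim held at 0.1).
DEFAULT_L_LEVELS = (0.35, 0.55, 0.75, 0.95)
#: Similarity levels of the demonstration Sim sweep (L held at 0.5).
DEFAULT_SIM_LEVELS = (0.1, 0.25, 0.50, 0.75)
#: Final-count quantiles tracked in trajectory plots.
DEFAULT_QUANTILES = (
    1.0, 0.99, 0.95, 0.90, 0.80, 0.70, 0.60, 0.50,
    0.40, 0.30, 0.20, 0.10, 0.05, 0.01, 0.00,
)


def skewness(counts) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) of a count vector.

    Positive values indicate the right-tailed shape characteristic of
    citation distributions (few highly cited articles, many poorly
    cited ones).  Needs at least three values and nonzero variance.
    """
    x = np.asarray(as_counts(counts).counts, dtype=np.float64)
    if x.size < 3:
        raise InsufficientDataError("skewness needs at least 3 values")
    if np.var(x) == 0:
        raise DegenerateSampleError("skewness undefined for a zero-variance sample")
    return float(scipy.stats.skew(x, bias=True))


def uncited_proportion(counts) -> float:
    """Fraction of articles with zero citations at the end of a run."""
    c = as_counts(counts).counts
    return float(np.mean(c == 0))


def aggregate_quantile_median(runs: Sequence) -> np.ndarray:
    """Median-of-quantiles aggregate of repeated runs.

    Each run's counts are sorted ascending and the elementwise median
    across runs is taken, giving a single predicted distribution whose
    k-th order statistic is the median k-th order statistic of the runs.
    The output is a nondecreasing vector of length R.
    """
    arrays = [np.sort(as_counts(r).counts) for r in runs]
    if not arrays:
        raise InsufficientDataError("aggregate_quantile_median needs at least one run")
    R = arrays[0].size
    if any(a.size != R for a in arrays):
        raise ShapeError("all runs must have the same number of articles")
    return np.median(np.vstack(arrays), axis=0)


@dataclass(frozen=True)
class SweepResult:
    """One row per (parameter level, replicate), plus the raw counts."""

    parameter: str
    table: pd.DataFrame
    counts: dict  # (level, replicate) -> np.ndarray of final counts


def _sweep(parameter, levels, base_params, R, C, reps, seed, track_every):
    if len(levels) == 0:
        raise ParameterError("levels must be nonempty")
    rows = []
    counts: dict = {}
    for level in levels:
        params = replace(base_params, **{parameter: float(level)})
        for rep in range(reps):
            rep_seed = int(seed) + rep
            result = run_memory(R, C, params=params, seed=rep_seed, track_every=track_every)
            c = result.counts.counts
            counts[(float(level), rep)] = c
            rows.append(
                {
                    parameter: float(level),
                    "replicate": rep,
                    "seed": rep_seed,
                    "skewness": skewness(c),
                    "prop_uncited": uncited_proportion(c),
                    "max_count": int(c.max()),
                }
            )
    return SweepResult(parameter=parameter, table=pd.DataFrame(rows), counts=counts)


def sweep_L(
    levels: Sequence[float] = DEFAULT_L_LEVELS,
    Sim_fixed: float = 0.1,
    R: int = 739,
    C: int = 57310,
    params: MemoryParams | None = None,
    reps: int = 1,
    seed: int = 0,
    track_every: int | None = None,
) -> SweepResult:
    """Run the memory model across encoding levels at fixed similarity.

    Lower L (greater information loss) is expected to raise the skew of
    the final count distribution: poorly encoded memories leave more
    room for a few articles to gain a chance retrieval advantage.
    """
    base = replace(params or MemoryParams(), Sim=float(Sim_fixed))
    return _sweep("L", levels, base, R, C, reps, seed, track_every)


def sweep_Sim(
    levels: Sequence[float] = DEFAULT_SIM_LEVELS,
    L_fixed: float = 0.5,
    R: int = 739,
    C: int = 57310,
    params: MemoryParams | None = None,
    reps: int = 1,
    seed: int = 0,
    track_every: int | None = None,
) -> SweepResult:
    """Run the memory model across similarity levels at fixed encoding.

    Higher Sim (more conceptual overlap in the domain) is expected to
    raise both the skew and the number of uncited articles.
    """
    base = replace(params or MemoryParams(), L=float(L_fixed))
    return _sweep("Sim", levels, base, R, C, reps, seed, track_every)


@dataclass(frozen=True)
class LFitResult:
    """Grid-fit of the encoding parameter L to an observed distribution."""

    grid: np.ndarray
    mean_A: np.ndarray
    mean_OV: np.ndarray
    mean_OV_adj: np.ndarray
    best_L: float
    reps: int
    table: pd.DataFrame


def fit_L(
    observed,
    grid: Sequence[float] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    reps: int = 10,
    seed: int = 0,
    Sim: float = 0.1,
    n_features: int = 20,
    max_probe_retries: int = 10,
) -> LFitResult:
    """Fit L by simulation: grid search scored by mean adjusted overlap.

    The ecology is taken from the observed counts (R = number of
    articles, C = their sum).  For each grid value of L the memory model
    is run ``reps`` times; each run is scored against the observed
    counts with the A statistic and the overlapping index, the runs'
    pairwise overlap gives the sample-size upper bound, and the level's
    score is the mean chance-corrected overlap.  ``best_L`` maximizes
    mean OV_adj; ties are broken by smaller |mean A - 0.5|, then by the
    smaller L.
    """
    obs = as_counts(observed)
    if obs.R < 2 or np.unique(obs.counts).size < 2:
        raise InsufficientDataError(
            "observed counts are degenerate; need >= 2 articles with spread"
        )
    grid_arr = np.asarray(list(grid), dtype=np.float64)
    if grid_arr.size == 0:
        raise ParameterError("grid must be nonempty")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    R, C = obs.R, obs.C

    rows = []
    mean_A = np.empty(grid_arr.size)
    mean_OV = np.empty(grid_arr.size)
    mean_OV_adj = np.empty(grid_arr.size)
    for k, L in enumerate(grid_arr):
        params = MemoryParams(
            L=float(L), Sim=Sim, n_features=n_features, max_probe_retries=max_probe_retries
        )
        run_counts = [
            run_memory(R, C, params=params, seed=int(seed) + r).counts.counts
            for r in range(reps)
        ]
        a_vals = [a_statistic(obs.counts, rc).A for rc in run_counts]
        ov_vals = [overlap_index(obs.counts, rc) for rc in run_counts]
        if reps >= 2:
            ub, _ = upper_bound(run_counts)
        else:
            ub = 1.0
        adj_vals = [adjusted_overlap(ov, ub) for ov in ov_vals]
        mean_A[k] = np.mean(a_vals)
        mean_OV[k] = np.mean(ov_vals)
        mean_OV_adj[k] = np.mean(adj_vals)
        rows.append(
            {
                "L": float(L),
                "mean_A": mean_A[k],
                "mean_OV": mean_OV[k],
                "UB": ub,
                "mean_OV_adj": mean_OV_adj[k],
                "reps": reps,
            }
        )

    # best level: max mean OV_adj, then |mean A - 0.5|, then smaller L
    order = sorted(
        range(grid_arr.size),
        key=lambda k: (-mean_OV_adj[k], abs(mean_A[k] - 0.5), grid_arr[k]),
    )
    best = grid_arr[order[0]]
    return LFitResult(
        grid=grid_arr,
        mean_A=mean_A,
        mean_OV=mean_OV,
        mean_OV_adj=mean_OV_adj,
        best_L=float(best),
        reps=int(reps),
        table=pd.DataFrame(rows),
    )


def _nearest_rank_indices(counts: np.ndarray, quantiles: Sequence[float]) -> dict:
    """Article index at each nearest-rank quantile of final counts.

    Articles are ordered by (count, article index) ascending, so ties go
    to the lowest index.  Quantile q selects the smallest rank k with
    k / R >= q (k >= 1).
    """
    R = counts.size
    order = np.lexsort((np.arange(R), counts))
    out = {}
    for q in quantiles:
        if not 0.0 <= q <= 1.0:
            raise ParameterError(f"quantile {q} outside [0, 1]")
        k = max(int(np.ceil(q * R)), 1)
        out[float(q)] = int(order[k - 1])
    return out


def trajectories(
    run: RunResult,
    quantiles: Sequence[float] = DEFAULT_QUANTILES,
    smooth_window: int | None = None,
) -> pd.DataFrame:
    """Citation-probability trajectories of quantile-selected articles.

    From a tracked run, picks the article at each nearest-rank quantile
    of the *final* counts and returns its recorded probability series,
    one column per quantile label, indexed by epoch.  The epoch-0 row
    holds the 1/R starting-point probabilities.  ``smooth_window``
    (in epochs) applies a trailing moving average to soften the
    epoch-to-epoch noise of the realised probabilities.
    """
    if run.trajectory is None:
        raise MissingTrajectoryError(
            "run has no trajectory; simulate with track_every set"
        )
    counts = run.counts.counts
    sel = _nearest_rank_indices(counts, quantiles)
    traj = run.trajectory
    data = {f"{q:g}": traj.probabilities[:, idx] for q, idx in sel.items()}
    frame = pd.DataFrame(data, index=pd.Index(traj.epochs, name="epoch"))
    if smooth_window is not None:
        if smooth_window < 1:
            raise ParameterError("smooth_window must be a positive number of epochs")
        spacing = np.diff(traj.epochs)
        step = int(spacing.min()) if spacing.size else 1
        window = max(int(round(smooth_window / max(step, 1))), 1)
        frame = frame.rolling(window=window, min_periods=1).mean()
    return frame
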