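"""Stochastic-only exposure model: a cumulative-advantage urn process.

Every article in a reference class of size ``R`` starts with some units
``u`` of exposure (by default one unit each — a level playing field).
Each epoch one article is selected for citation with probability
``u_i / sum(u)``; the cited article's exposure is incremented by one,
so articles that are cited become more likely to be cited again (the
Matthew effect).  Running the process for ``C`` epochs distributes ``C``
citations over the ``R`` articles, producing the right-skewed count
distributions characteristic of real citation data without any notion
of article quality.  The process has no free parameters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .base import CitationCounts, RunResult, Trajectory
from .errors import (
    InvalidArticleError,
    InvalidEcologyError,
    InvalidUnitsError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureState",
    "init_state",
    "citation_probabilities",
    "record_citation",
    "run_urn",
]


@dataclass(frozen=True)
class ExposureState:
    """Exposure units per article plus the number of citations recorded.

    ``units[i]`` only ever grows, by +1 per citation of article ``i``;
    ``epoch`` equals the number of citation events recorded so far.
    """

    units: np.ndarray
    epoch: int = 0

    @property
    def R(self) -> int:
        return int(self.units.size)


def _validate_units(units, R: int) -> np.ndarray:
    u = np.asarray(units, dtype=np.float64)
    if u.ndim != 1 or u.size != R:
        raise InvalidUnitsError(
            f"initial_units must be a length-{R} vector, got shape {u.shape}"
        )
    if not np.all(np.isfinite(u)) or np.any(u <= 0):
        raise InvalidUnitsError("initial exposure units must all be positive")
    return u


def init_state(R: int, initial_units=None) -> ExposureState:
    """Create a fresh exposure state for ``R`` articles.

    By default every article starts with one exposure unit, so each has
    citation probability 1/R in the first epoch.  ``initial_units`` lets
    some articles start with an exposure advantage (an uneven playing
    field) without changing the process itself.
    """
    if int(R) != R or R < 1:
        raise InvalidEcologyError(f"reference class size R must be >= 1, got {R}")
    R = int(R)
    if initial_units is None:
        units = np.ones(R, dtype=np.float64)
    else:
        units = _validate_units(initial_units, R).copy()
    return ExposureState(units=units, epoch=0)


def citation_probabilities(state: ExposureState) -> np.ndarray:
    """Per-article citation probabilities ``u_i / sum(u)``."""
    u = state.units
    return u / u.sum()


def record_citation(state: ExposureState, article_index: int) -> ExposureState:
    """Return a new state with one citation credited to ``article_index``.

    The cited article's exposure units grow by 1 and the epoch counter
    advances; all other articles are untouched (their probabilities fall
    because the denominator grows).
    """
    idx = int(article_index)
    if idx < 0 or idx >= state.R:
        raise InvalidArticleError(
            f"article index {article_index} out of range [0, {state.R})"
        )
    units = state.units.copy()
    units[idx] += 1.0
    return ExposureState(units=units, epoch=state.epoch + 1)


def run_urn(
    R: int,
    C: int,
    seed: int,
    initial_units=None,
    exogenous_rate: float = 0.0,
    track_every: int | None = None,
) -> RunResult:
    """Simulate the urn process for ``C`` citation epochs.

    Each epoch one article is drawn with probability proportional to its
    current exposure units and credited one citation (+1 unit).  With
    ``exogenous_rate`` > 0, after each epoch one uniformly chosen article
    additionally gains an exposure unit with that probability, modelling
    non-citation exposure (talks, social media); citation counts track
    citations only.  ``track_every`` records the post-update probability
    vector every that many epochs (plus the epoch-0 starting point).

    Identical ``(R, C, seed, initial_units, exogenous_rate)`` give
    identical results.
    """
    state = init_state(R, initial_units)
    R = state.R
    if int(C) != C or C < 0:
        raise ParameterError(f"total citations C must be >= 0, got {C}")
    C = int(C)
    if not 0.0 <= exogenous_rate < 1.0:
        raise ParameterError("exogenous_rate must lie in [0, 1)")
    if track_every is not None and track_every < 1:
        raise ParameterError("track_every must be a positive integer")

    rng = np.random.default_rng(seed)
    u = state.units.copy()
    counts = np.zeros(R, dtype=np.int64)

    traj_epochs: list[int] = []
    traj_probs: list[np.ndarray] = []
    if track_every is not None:
        traj_epochs.append(0)
        traj_probs.append(u / u.sum())

    logger.info("urn run: R=%d C=%d seed=%s exogenous_rate=%g", R, C, seed, exogenous_rate)
    log_step = max(C // 10, 1)
    for epoch in range(1, C + 1):
        cum = np.cumsum(u)
        x = rng.random() * cum[-1]
        i = int(np.searchsorted(cum, x, side="right"))
        if i >= R:  # guard against floating-point edge at x ~= total
            i = R - 1
        counts[i] += 1
        u[i] += 1.0
        if exogenous_rate > 0.0 and rng.random() < exogenous_rate:
            u[int(rng.integers(R))] += 1.0
        if track_every is not None and epoch % track_every == 0:
            traj_epochs.append(epoch)
            traj_probs.append(u / u.sum())
        if epoch % log_step == 0:
            logger.debug("urn run: epoch %d/%d", epoch, C)

    trajectory = None
    if track_every is not None:
        trajectory = Trajectory(np.array(traj_epochs), np.array(traj_probs))
    return RunResult(
        counts=CitationCounts(counts),
        trajectory=trajectory,
        seed=int(seed),
        meta={"model": "urn", "R": R, "C": C, "exogenous_rate": exogenous_rate},
    )
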