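"""Shared result containers for the exposure-model simulators.

Both the stochastic urn process and the memory-theoretic model emit the
same artefacts: a vector of per-article citation counts that sums to the
number of citation epochs ``C``, and (optionally) a tracked trajectory of
per-article citation probabilities across epochs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError


@dataclass(frozen=True)
class CitationCounts:
    """Per-article nonnegative integer citation counts.

    ``R`` is the number of articles in the reference class and ``C`` the
    total number of citations (= number of epochs simulated).
    """

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 1 or arr.size < 1:
            raise ShapeError("counts must be a nonempty 1-d vector")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ShapeError("counts must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ShapeError("counts must be nonnegative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def R(self) -> int:
        return int(self.counts.size)

    @property
    def C(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.R


@dataclass(frozen=True)
class Trajectory:
    """Per-article citation probabilities sampled across epochs.

    Row 0 always holds the epoch-0 (starting point) probabilities, which
    are 1/R for a level playing field.  ``probabilities[k]`` is the
    probability vector associated with ``epochs[k]``.
    """

    epochs: np.ndarray          # shape (K,), nondecreasing, epochs[0] == 0
    probabilities: np.ndarray   # shape (K, R), rows sum to 1

    def __post_init__(self):
        ep = np.asarray(self.epochs, dtype=np.int64)
        pr = np.asarray(self.probabilities, dtype=np.float64)
        if pr.ndim != 2 or ep.ndim != 1 or ep.size != pr.shape[0]:
            raise ShapeError("epochs and probabilities rows must align")
        object.__setattr__(self, "epochs", ep)
        object.__setattr__(self, "probabilities", pr)

    @property
    def R(self) -> int:
        return int(self.probabilities.shape[1])


@dataclass(frozen=True)
class RunResult:
    """Output of one simulator run."""

    counts: CitationCounts
    trajectory: Trajectory | None = None
    seed: int | None = None
    n_fallback_events: int = 0
    meta: dict = field(default_factory=dict)


def as_counts(x) -> CitationCounts:
    """Coerce an array-like, CitationCounts or RunResult to CitationCounts."""
    if isinstance(x, RunResult):
        return x.counts
    if isinstance(x, CitationCounts):
        return x
    return CitationCounts(np.asarray(x))
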