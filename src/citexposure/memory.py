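"""Memory-theoretic exposure model of citation propagation.

Articles are represented as prototype vectors of ``n_features`` binary
features (+1/-1); a fraction ``Sim`` of the feature positions carries a
pattern common to every article, modelling the conceptual overlap of a
research domain.  Episodic memory holds lossy *traces* of articles: each
feature of an encoded event survives independently with probability
``L`` (the encoding / retention parameter) and is otherwise lost (set to
0).  Memory starts with one trace per article.

Each citation epoch:

1. a probe representing the citing context is built — a fresh lossy
   encoding (retention ``L``) of a uniformly chosen article's prototype;
2. the probe is matched against every trace in memory; each trace's
   activation is the cube of its similarity to the probe;
3. one trace with positive activation is sampled by Luce's choice rule
   (probability proportional to activation) and its article is credited
   one citation;
4. a new lossy trace of the cited article's prototype is appended.

Memory therefore grows by one trace per epoch, ending with ``C + R``
traces.  Because cited articles deposit more traces, they gain retrieval
opportunities — cumulative advantage emerges from memory dynamics alone.
Lower ``L`` (more information loss) and higher ``Sim`` both increase the
skew of the resulting citation distribution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .base import CitationCounts, RunResult, Trajectory
from .errors import (
    EmptyChoiceError,
    InvalidEcologyError,
    ParameterError,
    ShapeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MemoryParams",
    "ArticleSpace",
    "TraceStore",
    "make_prototypes",
    "encode",
    "similarity",
    "activation",
    "luce_sample",
    "run_memory",
]


@dataclass(frozen=True)
class MemoryParams:
    """Tunable parameters of the memory-theoretic model.

    L
        Probability each feature of an event is retained in its trace
        (and in the probe); lower values mean greater information loss.
    Sim
        Fraction of feature positions shared by all article prototypes;
        0 gives statistically orthogonal articles, 1 identical ones.
    n_features
        Dimensionality of the feature vectors.
    max_probe_retries
        How many fresh probes to try in an epoch before falling back to
        citing a uniformly random article when no trace is activated.
    """

    L: float = 0.5
    Sim: float = 0.1
    n_features: int = 20
    max_probe_retries: int = 10

    def __post_init__(self):
        if not 0.0 <= self.L <= 1.0:
            raise ParameterError(f"L must lie in [0, 1], got {self.L}")
        if not 0.0 <= self.Sim <= 1.0:
            raise ParameterError(f"Sim must lie in [0, 1], got {self.Sim}")
        if int(self.n_features) != self.n_features or self.n_features < 1:
            raise ParameterError("n_features must be a positive integer")
        if int(self.max_probe_retries) != self.max_probe_retries or self.max_probe_retries < 1:
            raise ParameterError("max_probe_retries must be a positive integer")


@dataclass(frozen=True)
class ArticleSpace:
    """Prototype feature vectors for a reference class.

    ``prototypes`` is an R x n matrix over {-1, +1}.  The first
    ``len(shared_positions)`` columns hold one common pattern across all
    articles (the shared conceptual core of the domain); the remaining
    positions are independent fair coin flips per article.
    """

    prototypes: np.ndarray
    shared_positions: np.ndarray

    @property
    def R(self) -> int:
        return int(self.prototypes.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.prototypes.shape[1])


@dataclass
class TraceStore:
    """Growing pool of lossy traces, each tagged with its article index.

    Entries are in {-1, 0, +1}; 0 marks a lost feature.  A run of ``C``
    epochs starting from ``R`` initial traces ends with ``C + R`` traces.
    """

    traces: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    article_of_trace: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def T(self) -> int:
        return int(self.traces.shape[0])


def _shared_length(sim: float, n: int) -> int:
    # round half away from zero, so Sim sweeps hit reproducible lengths
    return int(np.floor(sim * n + 0.5))


def make_prototypes(R: int, n_features: int, Sim: float, rng: np.random.Generator) -> ArticleSpace:
    """Build R prototype vectors sharing ``round(Sim * n)`` feature positions.

    The shared segment holds a single random +-1 pattern copied into every
    article; unique positions are drawn independently per article.  With
    Sim=1 all prototypes are identical; with Sim=0 they are statistically
    orthogonal.
    """
    if int(R) != R or R < 1:
        raise InvalidEcologyError(f"reference class size R must be >= 1, got {R}")
    if int(n_features) != n_features or n_features < 1:
        raise ParameterError("n_features must be a positive integer")
    if not 0.0 <= Sim <= 1.0:
        raise ParameterError(f"Sim must lie in [0, 1], got {Sim}")
    R, n = int(R), int(n_features)
    n_shared = _shared_length(Sim, n)
    protos = rng.choice(np.array([-1, 1], dtype=np.int8), size=(R, n))
    if n_shared > 0:
        common = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_shared)
        protos[:, :n_shared] = common
    return ArticleSpace(prototypes=protos, shared_positions=np.arange(n_shared))


def encode(vector: np.ndarray, L: float, rng: np.random.Generator) -> np.ndarray:
    """Lossy-encode a +-1 feature vector: keep each feature w.p. ``L``.

    Lost features are set to 0.  The realised retention rate varies
    binomially around ``L`` from trace to trace — this natural encoding
    variability is what lets some articles become better represented in
    memory than others by chance alone.
    """
    v = np.asarray(vector)
    if not 0.0 <= L <= 1.0:
        raise ParameterError(f"L must lie in [0, 1], got {L}")
    keep = rng.random(v.shape) < L
    return np.where(keep, v, 0).astype(v.dtype)


def similarity(probe: np.ndarray, trace: np.ndarray) -> float:
    """Normalized match between a probe and a trace, in [-1, 1].

    ``S = sum(probe * trace) / N_R`` where ``N_R`` counts positions at
    which the probe *or* the trace is nonzero; ``S = 0`` when both
    vectors are entirely zero.  Matching features raise S, mismatching
    features lower it, and features lost on both sides are ignored.
    """
    p = np.asarray(probe, dtype=np.float64)
    t = np.asarray(trace, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1:
        raise ShapeError(f"probe and trace shapes differ: {p.shape} vs {t.shape}")
    n_r = int(np.count_nonzero((p != 0) | (t != 0)))
    if n_r == 0:
        return 0.0
    return float(p @ t) / n_r


def activation(S: float):
    """Activation of a trace: the cube of its similarity to the probe.

    Cubing sharpens the match signal (weak similarities are suppressed
    relative to strong ones) while preserving sign; only traces with
    positive activation enter the retrieval choice set.
    """
    return np.asarray(S, dtype=np.float64) ** 3


def luce_sample(activations: np.ndarray, rng: np.random.Generator) -> int:
    """Sample a trace index by Luce's choice rule over positive activations.

    Selection probability is ``a_i / sum(a_j for a_j > 0)``; traces with
    activation <= 0 are excluded.  Raises :class:`EmptyChoiceError` when
    no trace is positively activated, letting the caller retry with a
    fresh probe.
    """
    a = np.asarray(activations, dtype=np.float64)
    if a.ndim != 1 or a.size == 0:
        raise ShapeError("activations must be a nonempty 1-d vector")
    pos = np.nonzero(a > 0)[0]
    if pos.size == 0:
        raise EmptyChoiceError("no trace has positive activation")
    weights = a[pos]
    cum = np.cumsum(weights)
    x = rng.random() * cum[-1]
    j = int(np.searchsorted(cum, x, side="right"))
    if j >= pos.size:
        j = pos.size - 1
    return int(pos[j])


def _epoch_activations(traces, abs_traces, nnz, probe):
    """Vectorized activations of all traces against one probe.

    Equivalent to ``activation(similarity(probe, trace))`` per trace:
    dot products over the trace matrix, with the union-support
    denominator obtained from per-trace nonzero counts and the overlap
    of supports.
    """
    abs_probe = np.abs(probe)
    nnz_probe = abs_probe.sum()
    dots = traces @ probe
    overlap = abs_traces @ abs_probe
    n_r = nnz_probe + nnz - overlap
    sim = np.divide(dots, n_r, out=np.zeros_like(dots, dtype=np.float64), where=n_r > 0)
    return sim**3


@njit(cache=True)
def _memory_core(protosT, R, C, L, max_retries, track_every, rng,
                 counts, tracesT, nnz, article_of, traj):
    """Compiled epoch loop of the memory model.

    ``protosT``/``tracesT`` are feature-major (n x articles/traces)
    float64 matrices so the per-epoch match streams contiguously over
    traces.  Only positive similarities can be retrieved, so activations
    are computed for traces with a positive dot product.  Fills
    ``counts``, the trace store and (if ``track_every`` > 0) the
    per-article selection probabilities at each tracked epoch; returns
    (final trace count, number of uniform-fallback epochs).
    """
    n = protosT.shape[0]
    t_max = tracesT.shape[1]
    # initial traces: one lossy encoding per article
    for r in range(R):
        cnt = 0.0
        for i in range(n):
            if rng.random() < L:
                tracesT[i, r] = protosT[i, r]
                cnt += tracesT[i, r] * tracesT[i, r]
            else:
                tracesT[i, r] = 0.0
        nnz[r] = cnt
        article_of[r] = r
    T = R
    n_fallback = 0
    probe = np.empty(n, dtype=np.float64)
    dots = np.empty(t_max, dtype=np.float64)
    ovs = np.empty(t_max, dtype=np.float64)
    acts = np.empty(t_max, dtype=np.float64)
    trow = 0
    for epoch in range(1, C + 1):
        tot = 0.0
        for _attempt in range(max_retries):
            a = rng.integers(0, R)
            probe_nnz = 0.0
            for i in range(n):
                if rng.random() < L:
                    probe[i] = protosT[i, a]
                    probe_nnz += 1.0
                else:
                    probe[i] = 0.0
            for t in range(T):
                dots[t] = 0.0
                ovs[t] = 0.0
            for i in range(n):
                pi = probe[i]
                if pi != 0.0:
                    row = tracesT[i]
                    for t in range(T):
                        dots[t] += pi * row[t]
                        ovs[t] += row[t] * row[t]
            tot = 0.0
            for t in range(T):
                n_r = probe_nnz + nnz[t] - ovs[t]
                if n_r > 0.0 and dots[t] > 0.0:
                    v = dots[t] / n_r
                    acts[t] = v * v * v
                    tot += acts[t]
                else:
                    acts[t] = 0.0
            if tot > 0.0:
                break
        if tot > 0.0:
            x = rng.random() * tot
            cum = 0.0
            j = T - 1
            for t in range(T):
                cum += acts[t]
                if x < cum:
                    j = t
                    break
            chosen = int(article_of[j])
            if track_every > 0 and epoch % track_every == 0:
                for t in range(T):
                    if acts[t] > 0.0:
                        traj[trow, article_of[t]] += acts[t] / tot
                trow += 1
        else:
            chosen = int(rng.integers(0, R))
            n_fallback += 1
            if track_every > 0 and epoch % track_every == 0:
                for q in range(R):
                    traj[trow, q] = 1.0 / R
                trow += 1
        counts[chosen] += 1
        cnt = 0.0
        for i in range(n):
            if rng.random() < L:
                tracesT[i, T] = protosT[i, chosen]
                cnt += tracesT[i, T] * tracesT[i, T]
            else:
                tracesT[i, T] = 0.0
        nnz[T] = cnt
        article_of[T] = chosen
        T += 1
    return T, n_fallback


def run_memory(
    R: int,
    C: int,
    params: MemoryParams | None = None,
    seed: int = 0,
    track_every: int | None = None,
    return_traces: bool = False,
) -> RunResult:
    """Simulate the memory-theoretic exposure model for ``C`` epochs.

    Returns per-article citation counts (summing to ``C``); with
    ``track_every`` also a trajectory whose row for a tracked epoch holds
    the realised per-article selection probabilities under that epoch's
    probe (sum of positive normalized activations over each article's
    traces), with epoch 0 fixed at the 1/R starting point.  With
    ``return_traces`` the final :class:`TraceStore` is attached under
    ``meta['traces']``.

    If an epoch's probe activates no trace, a fresh probe is drawn up to
    ``params.max_probe_retries`` times; failing that, a uniformly random
    article is cited and the event is counted in ``n_fallback_events``.
    Either way the run emits exactly ``C`` citations and ends with
    ``C + R`` traces.
    """
    params, R, C, track = _validate_run_args(R, C, params, track_every)
    n, L = params.n_features, params.L

    rng = np.random.default_rng(seed)
    space = make_prototypes(R, n, params.Sim, rng)
    protosT = np.ascontiguousarray(space.prototypes.T.astype(np.float64))

    t_max = R + C
    tracesT = np.zeros((n, t_max), dtype=np.float64)
    article_of = np.zeros(t_max, dtype=np.int64)
    nnz = np.zeros(t_max, dtype=np.float64)
    counts = np.zeros(R, dtype=np.int64)
    n_rows = C // track if track > 0 else 0
    traj = np.zeros((n_rows, R), dtype=np.float64)

    logger.info(
        "memory run: R=%d C=%d n=%d L=%g Sim=%g seed=%s", R, C, n, L, params.Sim, seed
    )
    T, n_fallback = _memory_core(
        protosT, R, C, L, params.max_probe_retries, track, rng,
        counts, tracesT, nnz, article_of, traj,
    )
    if n_fallback:
        logger.warning("%d of %d epochs fell back to a uniform citation", n_fallback, C)
    return _package_result(
        counts, tracesT, article_of, T, R, C, params, seed, track, traj,
        n_fallback, return_traces,
    )


def _validate_run_args(R, C, params, track_every):
    if params is None:
        params = MemoryParams()
    if int(R) != R or R < 1:
        raise InvalidEcologyError(f"reference class size R must be >= 1, got {R}")
    if int(C) != C or C < 0:
        raise ParameterError(f"total citations C must be >= 0, got {C}")
    if track_every is not None and track_every < 1:
        raise ParameterError("track_every must be a positive integer")
    return params, int(R), int(C), 0 if track_every is None else int(track_every)


def _package_result(counts, tracesT, article_of, T, R, C, params, seed, track,
                    traj, n_fallback, return_traces):
    trajectory = None
    if track > 0:
        epochs = np.concatenate([[0], np.arange(track, C + 1, track)])
        probs = np.vstack([np.full((1, R), 1.0 / R), traj])
        trajectory = Trajectory(epochs, probs)
    meta: dict = {"model": "memory", "R": R, "C": C, "params": params}
    if return_traces:
        meta["traces"] = TraceStore(
            traces=np.ascontiguousarray(tracesT[:, :T].T).astype(np.int8),
            article_of_trace=article_of[:T].copy(),
        )
    return RunResult(
        counts=CitationCounts(counts),
        trajectory=trajectory,
        seed=int(seed),
        n_fallback_events=n_fallback,
        meta=meta,
    )


def _run_memory_reference(
    R: int,
    C: int,
    params: MemoryParams | None = None,
    seed: int = 0,
    track_every: int | None = None,
    return_traces: bool = False,
) -> RunResult:
    """Naive per-epoch recompute of the memory model (pure Python).

    Runs the identical process to :func:`run_memory` — same random draw
    sequence, same floating-point accumulation order — one trace at a
    time without the compiled kernel.  It exists so tests can assert
    that the optimized run is bit-identical to the naive recompute;
    only suitable for tiny problems.
    """
    params, R, C, track = _validate_run_args(R, C, params, track_every)
    n, L = params.n_features, params.L
    rng = np.random.default_rng(seed)
    space = make_prototypes(R, n, params.Sim, rng)
    protosT = space.prototypes.T.astype(np.float64)

    t_max = R + C
    tracesT = np.zeros((n, t_max), dtype=np.float64)
    article_of = np.zeros(t_max, dtype=np.int64)
    nnz = np.zeros(t_max, dtype=np.float64)
    counts = np.zeros(R, dtype=np.int64)
    n_rows = C // track if track > 0 else 0
    traj = np.zeros((n_rows, R), dtype=np.float64)

    def encode_column(col_target, article):
        cnt = 0.0
        for i in range(n):
            if rng.random() < L:
                tracesT[i, col_target] = protosT[i, article]
                cnt += tracesT[i, col_target] * tracesT[i, col_target]
            else:
                tracesT[i, col_target] = 0.0
        return cnt

    for r in range(R):
        nnz[r] = encode_column(r, r)
        article_of[r] = r
    T = R
    n_fallback = 0
    trow = 0
    for epoch in range(1, C + 1):
        tot = 0.0
        acts = [0.0] * t_max
        for _attempt in range(params.max_probe_retries):
            a = int(rng.integers(0, R))
            probe = [0.0] * n
            probe_nnz = 0.0
            for i in range(n):
                if rng.random() < L:
                    probe[i] = protosT[i, a]
                    probe_nnz += 1.0
                else:
                    probe[i] = 0.0
            dots = [0.0] * T
            ovs = [0.0] * T
            for i in range(n):
                pi = probe[i]
                if pi != 0.0:
                    for t in range(T):
                        dots[t] += pi * tracesT[i, t]
                        ovs[t] += tracesT[i, t] * tracesT[i, t]
            tot = 0.0
            for t in range(T):
                n_r = probe_nnz + nnz[t] - ovs[t]
                if n_r > 0.0 and dots[t] > 0.0:
                    v = dots[t] / n_r
                    acts[t] = v * v * v
                    tot += acts[t]
                else:
                    acts[t] = 0.0
            if tot > 0.0:
                break
        if tot > 0.0:
            x = rng.random() * tot
            cum = 0.0
            j = T - 1
            for t in range(T):
                cum += acts[t]
                if x < cum:
                    j = t
                    break
            chosen = int(article_of[j])
            if track > 0 and epoch % track == 0:
                for t in range(T):
                    if acts[t] > 0.0:
                        traj[trow, article_of[t]] += acts[t] / tot
                trow += 1
        else:
            chosen = int(rng.integers(0, R))
            n_fallback += 1
            if track > 0 and epoch % track == 0:
                for q in range(R):
                    traj[trow, q] = 1.0 / R
                trow += 1
        counts[chosen] += 1
        nnz[T] = encode_column(T, chosen)
        article_of[T] = chosen
        T += 1
    return _package_result(
        counts, tracesT, article_of, T, R, C, params, seed, track, traj,
        n_fallback, return_traces,
    )
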