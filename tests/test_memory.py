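"""Unit tests for the memory-theoretic exposure model."""
import numpy as np
import pytest
import scipy.stats

from citexposure import (
    MemoryParams,
    activation,
    encode,
    luce_sample,
    make_prototypes,
    run_memory,
    similarity,
)
from citexposure.errors import (
    EmptyChoiceError,
    InvalidEcologyError,
    ParameterError,
    ShapeError,
)
from citexposure.memory import _epoch_activations, _shared_length


class TestMakePrototypes:
    def test_sim_one_gives_identical_articles(self, rng):
        space = make_prototypes(8, 20, 1.0, rng)
        assert np.all(space.prototypes == space.prototypes[0])
        assert len(space.shared_positions) == 20

    def test_sim_zero_gives_statistical_orthogonality(self, rng):
        space = make_prototypes(10, 1024, 0.0, rng)
        assert len(space.shared_positions) == 0
        protos = space.prototypes.astype(float)
        dots = [
            protos[i] @ protos[j]
            for i in range(10) for j in range(i + 1, 10)
        ]
        # mean of 45 pairwise dots: sd ~ sqrt(n/45); allow 3 sigma
        assert abs(np.mean(dots)) < 3.0 * np.sqrt(1024 / 45)

    def test_half_similarity_shares_exactly_five_of_ten(self, rng):
        space = make_prototypes(2, 10, 0.5, rng)
        assert len(space.shared_positions) == 5
        np.testing.assert_array_equal(
            space.prototypes[0, :5], space.prototypes[1, :5]
        )

    @pytest.mark.parametrize(
        "sim,n,expected", [(0.5, 10, 5), (0.25, 10, 3), (0.75, 2, 2), (0.05, 10, 1)]
    )
    def test_shared_length_rounds_half_away_from_zero(self, sim, n, expected):
        assert _shared_length(sim, n) == expected

    def test_entries_are_plus_minus_one(self, rng):
        space = make_prototypes(5, 30, 0.3, rng)
        assert set(np.unique(space.prototypes)) <= {-1, 1}

    def test_parameter_errors(self, rng):
        with pytest.raises(InvalidEcologyError):
            make_prototypes(0, 10, 0.5, rng)
        with pytest.raises(ParameterError):
            make_prototypes(5, 10, 1.5, rng)


class TestEncode:
    def test_lossless(self, rng):
        v = rng.choice([-1, 1], size=50)
        np.testing.assert_array_equal(encode(v, 1.0, rng), v)

    def test_total_loss(self, rng):
        v = rng.choice([-1, 1], size=50)
        assert np.all(encode(v, 0.0, rng) == 0)

    def test_retention_rate_matches_l(self, rng):
        v = rng.choice([-1, 1], size=10_000)
        trace = encode(v, 0.35, rng)
        fraction = np.count_nonzero(trace) / v.size
        assert abs(fraction - 0.35) < 0.015  # 3 sigma binomial

    def test_retained_features_are_faithful(self, rng):
        v = rng.choice([-1, 1], size=500)
        trace = encode(v, 0.5, rng)
        kept = trace != 0
        np.testing.assert_array_equal(trace[kept], v[kept])


class TestSimilarityActivation:
    def test_self_match_is_one(self):
        v = np.array([1, -1, 1, 1])
        assert similarity(v, v) == 1.0

    def test_all_zero_trace_gives_zero(self):
        assert similarity(np.array([1, 1, -1]), np.zeros(3)) == 0.0

    def test_hand_computed_partial_match(self):
        probe = np.array([1, 1, 1, -1])
        trace = np.array([1, 1, 0, 1])
        # dot = 1, union support = 4
        assert similarity(probe, trace) == pytest.approx(0.25)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            similarity(np.ones(3), np.ones(4))

    def test_symmetry(self, rng):
        a = rng.choice([-1, 0, 1], size=30)
        b = rng.choice([-1, 0, 1], size=30)
        assert similarity(a, b) == pytest.approx(similarity(b, a))

    @pytest.mark.parametrize("s,expected", [(1.0, 1.0), (0.5, 0.125), (-0.5, -0.125), (0.0, 0.0)])
    def test_activation_is_cube(self, s, expected):
        assert activation(s) == pytest.approx(expected)


class TestLuceSample:
    def test_single_positive_always_chosen(self, rng):
        assert all(luce_sample(np.array([1.0, 0.0, 0.0]), rng) == 0 for _ in range(20))

    def test_choice_frequencies_match_normalized_activations(self, rng):
        a = np.array([2.0, 1.0, 1.0])
        draws = np.array([luce_sample(a, rng) for _ in range(20_000)])
        freq = np.bincount(draws, minlength=3)
        assert scipy.stats.chisquare(freq, 20_000 * np.array([0.5, 0.25, 0.25])).pvalue > 0.01

    def test_negative_activations_excluded(self, rng):
        # index 1 is negative: never sampled
        a = np.array([1.0, -5.0, 1.0])
        assert 1 not in {luce_sample(a, rng) for _ in range(200)}

    def test_empty_choice_condition(self, rng):
        with pytest.raises(EmptyChoiceError):
            luce_sample(np.array([-1.0, -1.0]), rng)


class TestRunMemory:
    def test_trace_count_and_conservation(self):
        result = run_memory(15, 40, MemoryParams(L=0.5, Sim=0.2, n_features=12),
                            seed=3, return_traces=True)
        store = result.meta["traces"]
        assert store.T == 40 + 15
        assert result.counts.C == 40
        assert result.counts.R == 15
        # each trace matches its article's prototype on retained positions
        assert set(np.unique(store.traces)) <= {-1, 0, 1}

    def test_determinism(self):
        params = MemoryParams(L=0.6, Sim=0.1, n_features=10)
        a = run_memory(20, 100, params, seed=9).counts.counts
        b = run_memory(20, 100, params, seed=9).counts.counts
        np.testing.assert_array_equal(a, b)

    def test_lossless_orthogonal_regime_is_uniform(self):
        """L=1, Sim=0, large n: probes only retrieve the probed article.

        The citation process then reduces to uniform sampling of
        articles, so final counts should look multinomial-uniform
        (chi-square at alpha=0.01 in a majority of seeds).
        """
        params = MemoryParams(L=1.0, Sim=0.0, n_features=1024)
        R, C = 20, 2000
        passed = 0
        for seed in range(20):
            counts = run_memory(R, C, params, seed=seed).counts.counts
            if scipy.stats.chisquare(counts).pvalue > 0.01:
                passed += 1
        assert passed > 10

    def test_zero_epochs(self):
        result = run_memory(5, 0, MemoryParams(), seed=0)
        assert result.counts.C == 0

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            MemoryParams(L=1.5)
        with pytest.raises(ParameterError):
            MemoryParams(Sim=-0.1)
        with pytest.raises(ParameterError):
            MemoryParams(n_features=0)
        with pytest.raises(InvalidEcologyError):
            run_memory(0, 10, MemoryParams(), seed=0)

    def test_trajectory_rows_are_distributions(self):
        result = run_memory(10, 60, MemoryParams(L=0.7), seed=2, track_every=20)
        traj = result.trajectory
        np.testing.assert_array_equal(traj.epochs, [0, 20, 40, 60])
        np.testing.assert_allclose(traj.probabilities[0], 0.1)
        np.testing.assert_allclose(traj.probabilities.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("track_every", [None, 10])
def test_optimized_run_is_bit_identical_to_naive_recompute(track_every):
    """The compiled run equals the per-epoch naive recompute exactly.

    Same seed, same draw sequence, same accumulation order: counts,
    trajectories and the final trace store must match bit for bit.
    """
    from citexposure.memory import _run_memory_reference

    params = MemoryParams(L=0.45, Sim=0.25, n_features=12)
    fast = run_memory(30, 120, params, seed=17, track_every=track_every,
                      return_traces=True)
    naive = _run_memory_reference(30, 120, params, seed=17, track_every=track_every,
                                  return_traces=True)
    np.testing.assert_array_equal(fast.counts.counts, naive.counts.counts)
    assert fast.n_fallback_events == naive.n_fallback_events
    np.testing.assert_array_equal(fast.meta["traces"].traces, naive.meta["traces"].traces)
    if track_every is not None:
        np.testing.assert_array_equal(
            fast.trajectory.probabilities, naive.trajectory.probabilities
        )


def test_vectorized_activations_match_scalar_definition(rng):
    """The run loop's batched matching equals trace-by-trace similarity^3."""
    protos = rng.choice([-1, 1], size=(6, 15)).astype(np.float32)
    traces = np.array([
        np.where(rng.random(15) < 0.5, protos[i % 6], 0) for i in range(25)
    ], dtype=np.float32)
    probe = np.where(rng.random(15) < 0.5, protos[0], 0).astype(np.float32)
    abs_traces = np.abs(traces)
    nnz = abs_traces.sum(axis=1)
    fast = _epoch_activations(traces, abs_traces, nnz, probe)
    slow = np.array([activation(similarity(probe, t)) for t in traces])
    np.testing.assert_allclose(fast, slow, atol=1e-6)
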