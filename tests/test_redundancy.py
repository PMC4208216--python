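"""Jeffrey divergence, Boolean correlation, accumulation, fusion, threshold
and the redundant-frame elimination loop."""

import math

import numpy as np
import pytest

from wcesum.frames import rgb_to_lab
from wcesum.redundancy import (
    BooleanSeries,
    ResourceContext,
    accumulate,
    adaptive_threshold,
    boolean_correlation,
    boolean_series,
    fuse,
    jeffrey_divergence,
    remove_redundant,
)
from wcesum.synthgen import SyntheticSpec, generate_sequence


def _jd_bruteforce(h1, h2):
    """Term-by-term expansion with the 0·log 0 convention."""
    total = 0.0
    for a, b in zip(h1, h2):
        if a > 0:
            total += a * math.log(2 * a / (a + b))
        if b > 0:
            total += b * math.log(2 * b / (a + b))
    return total


class TestJeffreyDivergence:
    def test_identity_is_zero(self, rng):
        h = rng.uniform(0, 1, 24)
        assert jeffrey_divergence(h, h) == pytest.approx(0.0)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(50):
            h1, h2 = rng.uniform(0, 1, 24), rng.uniform(0, 1, 24)
            assert jeffrey_divergence(h1, h2) == pytest.approx(jeffrey_divergence(h2, h1))

    def test_disjoint_toy_histograms_give_2log2(self):
        assert jeffrey_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2 * math.log(2))

    def test_matches_bruteforce_expansion(self, rng):
        for _ in range(20):
            h1, h2 = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
            h1[rng.integers(0, 10)] = 0.0  # exercise the zero convention
            assert jeffrey_divergence(h1, h2) == pytest.approx(_jd_bruteforce(h1, h2))

    def test_non_negative(self, rng):
        for _ in range(100):
            assert jeffrey_divergence(rng.uniform(0, 1, 24), rng.uniform(0, 1, 24)) >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            jeffrey_divergence([1.0, 0.0], [1.0, 0.0, 0.0])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            jeffrey_divergence([1.0, -0.1], [1.0, 0.0])


class TestBooleanSeries:
    def test_equal_frames_give_all_ones(self, rng):
        frame = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        lab = rgb_to_lab(frame)
        assert boolean_series(lab, lab).bits.all()

    def test_strictly_darker_gives_all_zeros(self):
        bright = rgb_to_lab(np.full((4, 4, 3), 200, dtype=np.uint8))
        dark = rgb_to_lab(np.full((4, 4, 3), 50, dtype=np.uint8))
        # only L is ordered for grays; compare channel 1 (L) explicitly
        assert not boolean_series(dark, bright).bits[0].any()

    def test_mixed_case_enumerated_by_hand(self):
        from wcesum.frames import LabFrame

        prev = LabFrame(L=np.array([[10.0, 20.0], [30.0, 40.0]]), a=np.zeros((2, 2)), b=np.zeros((2, 2)))
        curr = LabFrame(L=np.array([[10.0, 15.0], [35.0, 40.0]]), a=np.zeros((2, 2)), b=np.zeros((2, 2)))
        bits = boolean_series(curr, prev).bits
        np.testing.assert_array_equal(bits[0], [[True, False], [True, True]])
        assert bits[1].all() and bits[2].all()  # ties in a and b


class TestBooleanCorrelation:
    def test_identical_series_score_3(self, rng):
        bits = rng.integers(0, 2, size=(3, 8, 8)).astype(bool)
        bs = BooleanSeries(bits=bits)
        assert boolean_correlation(bs, bs) == pytest.approx(3.0)

    def test_complementary_series_score_0(self, rng):
        bits = rng.integers(0, 2, size=(3, 8, 8)).astype(bool)
        assert boolean_correlation(BooleanSeries(bits), BooleanSeries(~bits)) == pytest.approx(0.0)

    def test_half_agreement_scores_1_5(self):
        a = np.zeros((3, 2, 2), dtype=bool)
        b = np.zeros((3, 2, 2), dtype=bool)
        b[:, 0, :] = True  # half the pixels disagree in every channel
        assert boolean_correlation(BooleanSeries(a), BooleanSeries(b)) == pytest.approx(1.5)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            x = BooleanSeries(rng.integers(0, 2, size=(3, 4, 4)).astype(bool))
            y = BooleanSeries(rng.integers(0, 2, size=(3, 4, 4)).astype(bool))
            bc = boolean_correlation(x, y)
            assert 0.0 <= bc <= 3.0
            assert bc == pytest.approx(boolean_correlation(y, x))


class TestAccumulate:
    def test_constant_stream_full_history(self):
        v = 0.7
        assert accumulate([v] * 3, q=2) == pytest.approx(11 * v / 12)

    def test_single_value_passes_through(self):
        assert accumulate([0.42], q=4) == pytest.approx(0.42)

    def test_term_by_term_oracle(self):
        # stream [1, 0, 0] at the last position, q=2:
        # (1/2) * (0*1 + 0*(1/2) + 1*(1/3)) = 1/6
        assert accumulate([1.0, 0.0, 0.0], q=2) == pytest.approx(1 / 6)

    def test_warmup_divides_by_available_lags(self):
        # p=1, one lagged term available: (v1 + v0/2) / 1
        assert accumulate([0.5, 0.2], q=4) == pytest.approx(0.2 + 0.25)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accumulate([], q=2)


class TestFuse:
    def test_identical_frames_fuse_to_zero_in_coherent_mode(self):
        assert fuse(0.0, 3.0, mode="coherent") == pytest.approx(0.0)

    def test_coherent_arithmetic(self):
        assert fuse(0.4, 1.5, mode="coherent") == pytest.approx(0.9)

    def test_literal_sum_as_printed(self):
        assert fuse(0.4, 1.5, mode="literal") == pytest.approx(1.9)


class TestAdaptiveThreshold:
    def test_approaches_one_at_minimal_resources(self):
        tau = adaptive_threshold(ResourceContext(bw=1e-6, battery=1e-6, preference=1.0))
        assert tau == pytest.approx(1.0, abs=1e-6)

    def test_linear_in_user_preference(self):
        full = adaptive_threshold(ResourceContext(bw=0.7, battery=0.7, preference=1.0))
        half = adaptive_threshold(ResourceContext(bw=0.7, battery=0.7, preference=0.5))
        assert half == pytest.approx(full / 2)

    def test_maximal_resources_value(self):
        tau = adaptive_threshold(ResourceContext(bw=1.0, battery=1.0, preference=1.0))
        assert tau == pytest.approx(math.exp(-2), abs=1e-6)

    def test_out_of_range_context_rejected(self):
        with pytest.raises(ValueError, match="resource out of range"):
            ResourceContext(bw=0.0, battery=0.5, preference=0.5)
        with pytest.raises(ValueError, match="resource out of range"):
            ResourceContext(bw=0.5, battery=1.5, preference=0.5)


def _identical_sequence(n=6, value=120, size=16):
    from wcesum.frames import FrameSequence

    frame = np.full((size, size, 3), value, dtype=np.uint8)
    return FrameSequence(frames=[frame.copy() for _ in range(n)])


class TestRemoveRedundant:
    def test_identical_frames_keep_only_the_first(self):
        seq = _identical_sequence()
        selection, trace = remove_redundant(seq, tau=0.5, q=4)
        assert selection.kept_indices == [0]
        assert selection.dropped_indices == list(range(1, 6))
        assert max(trace.d) == pytest.approx(0.0)

    def test_alternating_frames_all_kept_at_small_tau(self):
        from wcesum.frames import FrameSequence

        black = np.zeros((16, 16, 3), dtype=np.uint8)
        white = np.full((16, 16, 3), 255, dtype=np.uint8)
        seq = FrameSequence(frames=[black, white, black, white, black])
        selection, _ = remove_redundant(seq, tau=0.01, q=2)
        assert selection.kept_indices == [0, 1, 2, 3, 4]

    def test_kept_set_shrinks_monotonically_in_tau(self, small_sequence):
        seq, _ = small_sequence
        sizes = []
        for tau in (0.05, 0.2, 0.4, 0.6, 0.8, 1.0):
            selection, _ = remove_redundant(seq, tau=tau, q=4)
            sizes.append(len(selection.kept_indices))
        assert sizes == sorted(sizes, reverse=True)

    def test_partition_into_kept_and_dropped(self, small_sequence):
        seq, _ = small_sequence
        selection, _ = remove_redundant(seq, tau=0.5, q=4)
        assert sorted(selection.kept_indices + selection.dropped_indices) == list(seq.indices)

    def test_planted_scenes_recovered_at_mid_range_tau(self, capsule_sequence):
        seq, truth = capsule_sequence
        ctx = ResourceContext(bw=0.3, battery=0.45, preference=0.9)
        selection, _ = remove_redundant(seq, ctx=ctx, q=4)
        kept = set(selection.kept_indices)
        scene_firsts = {t.index for t in truth if t.is_informative and not t.is_redundant_copy}
        assert scene_firsts <= kept
        redundant = {t.index for t in truth if t.is_redundant_copy}
        assert len(kept & redundant) / len(redundant) <= 0.2

    def test_last_kept_anchor_runs_and_keeps_first_frame(self, small_sequence):
        seq, _ = small_sequence
        selection, _ = remove_redundant(seq, tau=0.5, q=4, anchor="last_kept")
        assert selection.kept_indices[0] == 0

    def test_trace_rows_cover_every_transition(self, small_sequence):
        seq, _ = small_sequence
        _, trace = remove_redundant(seq, tau=0.5, q=4)
        assert trace.transitions == list(seq.indices)[1:]
        assert len(trace.dj) == len(seq) - 1
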