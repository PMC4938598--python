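"""Circular binary segmentation: statistic, permutation test, recursion,
smoothing and sd-undo pruning, checked against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import arc_t_oracle, perm_p_oracle, sd_undo_oracle
from cnvbpr.segmentation import (Segment, SegmentationParams,
                                 estimate_noise_sd, max_arc_statistic,
                                 permutation_pvalue, sd_undo,
                                 segment_chromosome, segment_sample,
                                 smooth_outliers)
from cnvbpr.io import ProbeMap


def _params(**kw):
    base = dict(alpha=0.001, n_perm=1000, min_width=4, undo_sd=0.5, seed=99)
    base.update(kw)
    return SegmentationParams(**base)


class TestNoiseSd:
    def test_constant_vector_hits_epsilon_floor(self):
        assert estimate_noise_sd(np.zeros(50)) == pytest.approx(1e-8)

    def test_alternating_vector_closed_form(self):
        c = 0.42
        x = np.tile([0.0, c], 25)
        assert estimate_noise_sd(x) == pytest.approx(c / (0.6745 * math.sqrt(2)))

    def test_consistent_for_gaussian_noise(self):
        x = np.random.default_rng(3).normal(0.0, 0.2, 10_000)
        assert estimate_noise_sd(x) == pytest.approx(0.2, rel=0.05)

    def test_robust_to_a_single_true_jump(self):
        x = np.concatenate([np.zeros(500), np.ones(500)])
        x += np.random.default_rng(4).normal(0.0, 0.1, 1000)
        assert estimate_noise_sd(x) == pytest.approx(0.1, rel=0.1)

    def test_too_few_markers(self):
        with pytest.raises(ValueError):
            estimate_noise_sd(np.array([1.0]))


class TestSmoothOutliers:
    def test_spike_is_shrunk_to_two_sd_of_neighbors(self):
        params = _params()
        x = np.zeros(21)
        x[10] = 10.0
        out = smooth_outliers(x, params, noise_sd=1.0)
        assert out[10] == pytest.approx(2.0)     # 0 + shrink_sd * sd, toward +10
        assert np.array_equal(out[:10], x[:10])

    def test_clean_data_unchanged(self, rng):
        params = _params()
        x = rng.normal(0.0, 0.1, 100)
        out = smooth_outliers(x, params, noise_sd=0.1)
        assert np.array_equal(out, x)

    def test_adjacent_twin_spikes_form_a_level_and_survive(self):
        # hand-traced 12-marker vector: markers 5 and 6 are a genuine
        # 2-marker level; each has a near neighbor (the other) -> retained
        params = _params()
        x = np.zeros(12)
        x[5] = x[6] = 8.0
        out = smooth_outliers(x, params, noise_sd=1.0)
        assert np.array_equal(out, x)

    def test_negative_spike_shrinks_downward(self):
        params = _params()
        x = np.zeros(21)
        x[10] = -9.0
        out = smooth_outliers(x, params, noise_sd=1.0)
        assert out[10] == pytest.approx(-2.0)


class TestMaxArcStatistic:
    def test_constant_vector_scores_zero(self):
        t, _ = max_arc_statistic(np.full(20, 3.3), 4)
        assert t == 0.0

    def test_symmetric_step_selects_a_level_block(self):
        t, arc = max_arc_statistic(np.array([0., 0, 0, 0, 1, 1, 1, 1]), 4)
        assert math.isinf(t)
        assert arc in [(0, 3), (4, 7)]
        # tie-break: smallest start index wins
        assert arc == (0, 3)

    def test_too_few_markers_returns_no_test(self):
        assert max_arc_statistic(np.arange(7.0), 4) is None

    @pytest.mark.parametrize("n", [8, 11, 14, 17, 21, 25, 30])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_arc_oracle(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        t, arc = max_arc_statistic(x, 4)
        t_o, arc_o = arc_t_oracle(x, 4)
        assert t == pytest.approx(t_o, rel=1e-9)
        assert arc == arc_o

    def test_matches_oracle_with_min_width_two(self):
        x = np.random.default_rng(12).normal(size=12)
        t, arc = max_arc_statistic(x, 2)
        t_o, arc_o = arc_t_oracle(x, 2)
        assert t == pytest.approx(t_o, rel=1e-9)
        assert arc == arc_o


class TestPermutationPvalue:
    def test_constant_vector_is_null(self):
        params = _params()
        x = np.full(10, 1.0)
        assert permutation_pvalue(x, 0.0, params) == 1.0

    @pytest.mark.parametrize("n,seed", [(6, 0), (6, 5), (7, 1)])
    def test_matches_full_enumeration_for_tiny_n(self, n, seed):
        params = _params(min_width=2, n_perm=10_000)
        x = np.random.default_rng(seed).normal(size=n)
        t_obs, _ = max_arc_statistic(x, 2)
        p = permutation_pvalue(x, t_obs, params)
        assert p == pytest.approx(perm_p_oracle(x, t_obs, 2), abs=0)

    def test_strong_step_is_highly_significant(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([np.zeros(20), np.full(20, 10.0)]) + rng.normal(0, 1, 40)
        t_obs, _ = max_arc_statistic(x, 4)
        p = permutation_pvalue(x, t_obs, _params(n_perm=1000), rng)
        assert p <= 0.001

    def test_null_data_early_exit_is_conservative(self):
        params = _params(n_perm=1000)
        x = np.random.default_rng(2).normal(size=40)
        t_obs, _ = max_arc_statistic(x, 4)
        p = permutation_pvalue(x, t_obs, params)
        assert p > params.alpha


class TestSdUndo:
    def _segments(self, means, size=10):
        segs, values, idx = [], [], 0
        for m in means:
            segs.append(Segment(1, idx, idx + size - 1, (idx + 1) * 1000,
                                (idx + size) * 1000, size, m))
            values.extend([m] * size)
            idx += size
        return segs, np.array(values)

    def test_small_gap_merged(self):
        segs, values = self._segments([0.0, 0.2])
        out = sd_undo(segs, values, undo_sd=0.5, noise_sd=1.0)
        assert len(out) == 1 and out[0].n_markers == 20
        assert out[0].mean == pytest.approx(0.1)

    def test_large_gap_kept(self):
        segs, values = self._segments([0.0, 0.8])
        out = sd_undo(segs, values, undo_sd=0.5, noise_sd=1.0)
        assert len(out) == 2

    def test_chain_weakest_first_matches_exhaustive_removal_oracle(self):
        segs, values = self._segments([0.0, 0.3, 0.9])
        out = sd_undo(segs, values, undo_sd=0.5, noise_sd=1.0)
        terminal = sd_undo_oracle([0.0, 0.3, 0.9], [10, 10, 10], 0.5)
        assert tuple(round(s.mean, 12) for s in out) in terminal
        assert len(terminal) == 1   # unique terminal state for this chain

    @given(st.lists(st.floats(-1.5, 1.5), min_size=1, max_size=5),
           st.integers(0, 2**31 - 1))
    def test_never_increases_count_and_guarantees_gap(self, means, seed):
        segs, values = self._segments(means)
        values += np.random.default_rng(seed).normal(0, 0.01, len(values))
        # recompute means from the noisy values so the invariant is honest
        for s in segs:
            s.mean = float(values[s.start_index: s.end_index + 1].mean())
        out = sd_undo(segs, values, undo_sd=0.5, noise_sd=0.4)
        assert len(out) <= len(segs)
        assert sum(s.n_markers for s in out) == len(values)
        for a, b in zip(out[:-1], out[1:]):
            assert abs(a.mean - b.mean) >= 0.5 * 0.4


class TestSegmentChromosome:
    def test_constant_vector_is_one_segment(self):
        pos = np.arange(1, 101) * 1000
        segs = segment_chromosome(np.zeros(100), pos, _params(), chrom=3)
        assert len(segs) == 1
        assert segs[0].n_markers == 100
        assert (segs[0].start_pos, segs[0].end_pos) == (1000, 100_000)

    def test_noise_free_step_boundary_exact(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        pos = np.arange(1, 41) * 1000
        segs = segment_chromosome(x, pos, _params(), chrom=1)
        assert [s.n_markers for s in segs] == [20, 20]
        assert segs[0].end_pos == 20_000 and segs[1].start_pos == 21_000
        assert segs[0].mean == 0.0 and segs[1].mean == 1.0

    def test_planted_jumps_recovered_with_noise(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([np.zeros(70), np.full(60, 1.0), np.full(70, 0.2)])
        x += rng.normal(0, 0.15, 200)
        pos = np.arange(1, 201) * 1000
        segs = segment_chromosome(x, pos, _params(), chrom=1,
                                  rng=np.random.default_rng(5))
        starts = [s.start_index for s in segs[1:]]
        assert len(starts) == 2
        assert abs(starts[0] - 70) <= 1 and abs(starts[1] - 130) <= 1

    def test_segments_tile_and_means_recomputable(self, rng):
        x = rng.normal(0, 0.2, 150)
        x[40:90] += 1.2
        pos = np.arange(1, 151) * 500
        segs = segment_chromosome(x, pos, _params(), chrom=2,
                                  rng=np.random.default_rng(0))
        assert sum(s.n_markers for s in segs) == 150
        edges = [0] + [s.start_index for s in segs[1:]] + [150]
        assert all(b - a == s.n_markers for a, b, s in
                   zip(edges[:-1], edges[1:], segs))
        for s in segs:
            assert s.mean == pytest.approx(x[s.start_index:s.end_index + 1].mean())
            assert s.n_markers >= 4   # min_width respected

    def test_raising_alpha_never_loses_changepoints(self):
        rng = np.random.default_rng(23)
        x = np.concatenate([np.zeros(50), np.ones(50), np.zeros(50)])
        x += rng.normal(0, 0.2, 150)
        pos = np.arange(1, 151) * 1000
        n_strict = len(segment_chromosome(x, pos, _params(alpha=0.001), chrom=1,
                                          rng=np.random.default_rng(3)))
        n_loose = len(segment_chromosome(x, pos, _params(alpha=0.05), chrom=1,
                                         rng=np.random.default_rng(3)))
        assert n_loose >= n_strict

    def test_short_stretch_kept_whole(self, caplog):
        with caplog.at_level("WARNING", logger="cnvbpr.segmentation"):
            segs = segment_chromosome(np.array([0.0, 5.0, 0.0]),
                                      np.array([10, 20, 30]), _params(), chrom=9)
        assert len(segs) == 1
        assert "min_width" in caplog.text

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            segment_chromosome(np.zeros(10), np.arange(10, 0, -1), _params())


class TestSegmentSample:
    def test_whole_sample_profile_tiles_every_chromosome(self):
        pm = ProbeMap.regular(2, 60)
        rng = np.random.default_rng(1)
        track = rng.normal(0, 0.1, 120)
        track[20:40] += 1.0     # event on chromosome 1
        profile = segment_sample("s1", track, pm, _params(),
                                 rng=np.random.default_rng(2))
        for chrom in (1, 2):
            assert sum(s.n_markers for s in profile.segments[chrom]) == 60
        assert len(profile.segments[1]) == 3
        assert len(profile.segments[2]) == 1
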