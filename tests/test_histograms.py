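import numpy as np
import pytest
from hypothesis import given, strategies as st

from smfretq.histograms import (
    FretHistogram,
    FretSeries,
    average_histograms,
    combine_movies_if_sparse,
    compute_fret,
    default_bin_edges,
    histogram_quartiles,
    movie_histogram,
)
from smfretq.traces import FluorTrace


def hist_from(fractions, bin_width=0.02, start=0.0):
    fr = np.asarray(fractions, float)
    edges = start + bin_width * np.arange(len(fr) + 1)
    return FretHistogram(bin_edges=edges, fractions=fr / fr.sum(), n_traces=1,
                         n_frames_counted=100)


class TestComputeFret:
    def test_symmetric_intensities(self):
        t = FluorTrace("t", np.full(10, 500.0), np.full(10, 500.0), 0.1)
        np.testing.assert_allclose(compute_fret(t, 10).efficiency, 0.5)

    def test_zero_acceptor(self):
        t = FluorTrace("t", np.full(10, 800.0), np.zeros(10), 0.1)
        np.testing.assert_allclose(compute_fret(t, 10).efficiency, 0.0)

    def test_seventy_thirty_split(self):
        t = FluorTrace("t", np.full(5, 300.0), np.full(5, 700.0), 0.1)
        np.testing.assert_allclose(compute_fret(t, 5).efficiency, 0.7)

    def test_restricted_to_fret_lifetime(self):
        t = FluorTrace("t", np.full(10, 500.0), np.full(10, 500.0), 0.1)
        assert len(compute_fret(t, 6)) == 6

    def test_nonpositive_total_yields_missing(self):
        t = FluorTrace("t", np.array([500.0, -10.0]), np.array([500.0, 5.0]), 0.1)
        e = compute_fret(t, 2).efficiency
        assert e[0] == 0.5 and np.isnan(e[1])

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        t1 = FluorTrace("t", np.array([300.0, 600.0]), np.array([700.0, 400.0]), 0.1)
        t2 = FluorTrace("t", c * t1.donor, c * t1.acceptor, 0.1)
        np.testing.assert_allclose(
            compute_fret(t1, 2).efficiency, compute_fret(t2, 2).efficiency, rtol=1e-12
        )


class TestMovieHistogram:
    def test_display_frame_cap(self):
        s = FretSeries("t", np.full(100, 0.5))
        h = movie_histogram([s])
        assert h.n_frames_counted == 50  # display uses the first 50 frames
        center_bin = np.argmax(h.fractions)
        assert abs(h.bin_centers[center_bin] - 0.5) <= 0.02

    def test_equal_mass_split(self):
        a = FretSeries("a", np.full(60, 0.3))
        b = FretSeries("b", np.full(60, 0.7))
        h = movie_histogram([a, b])
        idx3 = np.digitize(0.3, h.bin_edges) - 1
        idx7 = np.digitize(0.7, h.bin_edges) - 1
        assert h.fractions[idx3] == pytest.approx(0.5)
        assert h.fractions[idx7] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, rng):
        series = [FretSeries("t", rng.uniform(-0.2, 1.2, 30)) for _ in range(5)]
        h = movie_histogram(series)
        assert h.fractions.sum() == pytest.approx(1.0)

    def test_out_of_range_clipped_into_terminal_bins(self):
        s = FretSeries("t", np.array([-0.5, 1.5]))
        h = movie_histogram([s])
        assert h.fractions[0] == pytest.approx(0.5)
        assert h.fractions[-1] == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            movie_histogram([])

    def test_default_binning_matches_display_convention(self):
        edges = default_bin_edges()
        assert edges[0] == pytest.approx(-0.1)
        np.testing.assert_allclose(np.diff(edges), 0.02)


class TestCombineMovies:
    def test_identity_when_all_movies_dense(self):
        movies = [[0] * 30, [0] * 25, [0] * 60]
        assert combine_movies_if_sparse(movies, min_traces=20) == [[0], [1], [2]]

    def test_sparse_pair_merged_before_dense_movie(self):
        movies = [[0] * 10, [0] * 10, [0] * 60]
        assert combine_movies_if_sparse(movies, min_traces=50) == [[0, 1], [2]]

    def test_cap_at_three_movies(self):
        movies = [[0] * 5] * 4
        groups = combine_movies_if_sparse(movies, min_traces=50, max_combine=3)
        assert [len(g) for g in groups] == [3, 1]

    def test_group_closes_once_dense_enough(self):
        movies = [[0] * 10, [0] * 45, [0] * 10]
        assert combine_movies_if_sparse(movies, min_traces=50) == [[0, 1], [2]]


class TestAverageHistograms:
    def test_identical_histograms_zero_sem(self):
        h = hist_from([0.2, 0.5, 0.3])
        cond = average_histograms([h, h, h])
        np.testing.assert_allclose(cond.mean_fractions, h.fractions)
        np.testing.assert_allclose(cond.sem_fractions, 0.0, atol=1e-15)

    def test_sem_hand_value(self):
        """Bin values 0.2 and 0.4: mean 0.3, SD 0.1414, SEM 0.1."""
        h1 = hist_from([0.2, 0.8])
        h2 = hist_from([0.4, 0.6])
        cond = average_histograms([h1, h2])
        assert cond.mean_fractions[0] == pytest.approx(0.3)
        assert cond.sem_fractions[0] == pytest.approx(0.1)

    def test_single_movie_sem_zero_by_convention(self):
        cond = average_histograms([hist_from([0.5, 0.5])])
        np.testing.assert_allclose(cond.sem_fractions, 0.0)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError, match="binning"):
            average_histograms([hist_from([0.5, 0.5]), hist_from([0.3, 0.3, 0.4])])

    def test_condition_quartiles_average_per_movie_quartiles(self):
        h1 = hist_from([1.0, 0.0, 0.0])
        h2 = hist_from([0.0, 0.0, 1.0])
        cond = average_histograms([h1, h2])
        expected = tuple(np.mean([histogram_quartiles(h1), histogram_quartiles(h2)], axis=0))
        assert cond.quartiles == pytest.approx(expected)


class TestHistogramQuartiles:
    def test_single_bin_mass(self):
        h = hist_from([0.0, 1.0, 0.0])
        q = histogram_quartiles(h)
        assert q[0] == q[1] == q[2] == pytest.approx(h.bin_centers[1])

    def test_uniform_ten_bins_median_in_sixth(self):
        h = hist_from([0.1] * 10)
        q = histogram_quartiles(h)
        assert q[1] == pytest.approx(h.bin_centers[5])  # cumulative passes 50% at bin 6

    def test_cumulative_rule_three_bins(self):
        h = hist_from([0.3, 0.3, 0.4])
        q = histogram_quartiles(h)
        np.testing.assert_allclose(q, h.bin_centers)

    def test_empty_histogram_rejected(self):
        edges = np.arange(4) * 0.02
        h = FretHistogram(bin_edges=edges, fractions=np.zeros(3), n_traces=0,
                          n_frames_counted=0)
        with pytest.raises(ValueError):
            histogram_quartiles(h)

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=55).filter(
            lambda fr: sum(fr) > 0
        )
    )
    def test_quartile_monotonicity(self, fractions):
        h = hist_from(np.asarray(fractions) + 1e-12)
        q25, q50, q75 = histogram_quartiles(h)
        assert q25 <= q50 <= q75


class TestSingleStateEndToEnd:
    def test_condition_median_within_one_bin_of_truth(self):
        """Single-state molecules at E*=0.5, SNR 10: q50 lands on E*."""
        from smfretq.fixtures import photophysics_for_snr
        from smfretq.kinetics import KineticModel
        from smfretq.photophysics import simulate_condition
        from smfretq.selection import apply_selection, analyze_trace, SelectionCriteria

        m = KineticModel(("s",), (0.5,), np.zeros((1, 1)))
        pp = photophysics_for_snr(10.0, donor_bleach_tau=40.0, acceptor_bleach_tau=25.0)
        cond = simulate_condition(m, pp, 4, 40, seed=3, n_frames=400)
        hists = []
        crit = SelectionCriteria(max_anticorrelation_r=0.9)  # static E has no dynamics
        for movie in cond.movies:
            _, reports = apply_selection(movie, crit)
            series = [
                compute_fret(t, rep.fret_lifetime_frames)
                for t, rep in zip(movie, reports)
                if rep.accepted
            ]
            if series:
                hists.append(movie_histogram(series))
        cond_hist = average_histograms(hists)
        assert abs(cond_hist.quartiles[1] - 0.5) <= 0.02
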