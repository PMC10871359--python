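import numpy as np
import pytest

from smfretq.histograms import FretHistogram, default_bin_edges
from smfretq.occupancy import (
    TrimodalFit,
    TrimodalModel,
    component_area,
    fit_trimodal,
    occupancy_percentages,
)

EDGES = default_bin_edges()
CENTERS = 0.5 * (EDGES[:-1] + EDGES[1:])


def normalized_hist(values):
    values = np.asarray(values, float)
    return FretHistogram(bin_edges=EDGES, fractions=values / values.sum(),
                         n_traces=1, n_frames_counted=1000)


def gaussian_density(x, mu, sigma):
    return np.exp(-((x - mu) ** 2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))


class TestModelValidation:
    def test_means_must_increase(self):
        with pytest.raises(ValueError):
            TrimodalModel(fixed_means=(0.5, 0.3, 0.7))

    def test_amplitudes_nonnegative(self):
        with pytest.raises(ValueError):
            TrimodalModel(amplitudes=(-0.1, 0.1, 0.1))


class TestComponentArea:
    def test_zero_amplitude_zero_area(self):
        assert component_area(0.0, 0.05, 0.5, np.arange(0, 1.005, 0.005)) == 0.0

    def test_matches_closed_form_gaussian_integral(self):
        grid = np.arange(0.0, 1.0 + 1e-12, 0.005)
        area = component_area(1.0, 0.05, 0.5, grid)
        exact = 0.05 * np.sqrt(2 * np.pi)
        assert abs(area - exact) / exact < 1e-3

    def test_fourth_order_convergence_under_refinement(self):
        coarse = component_area(1.0, 0.05, 0.5, np.arange(0.0, 1.0 + 1e-12, 0.005))
        fine = component_area(1.0, 0.05, 0.5, np.arange(0.0, 1.0 + 1e-12, 0.0025))
        assert abs(fine - coarse) / coarse < 1e-4

    def test_even_point_grid_extended(self):
        grid = np.arange(0.0, 1.0, 0.005)  # 200 points (even)
        area = component_area(1.0, 0.05, 0.5, grid)
        assert area == pytest.approx(0.05 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            component_area(1.0, 0.05, 0.5, np.array([0.0, 0.1, 0.3]))


class TestOccupancyPercentages:
    def _fit_with_areas(self, areas):
        return TrimodalFit(
            model=TrimodalModel(), areas=areas, total_area=sum(areas),
            occupancy_percent=(0, 0, 0), residual_ss=0.0, converged=True,
        )

    def test_equal_areas(self):
        p = occupancy_percentages(self._fit_with_areas((1.0, 1.0, 1.0)))
        np.testing.assert_allclose(p, 100 / 3)

    def test_two_one_one(self):
        p = occupancy_percentages(self._fit_with_areas((2.0, 1.0, 1.0)))
        np.testing.assert_allclose(p, (50.0, 25.0, 25.0))

    def test_percentages_sum_to_hundred(self, rng):
        areas = tuple(rng.uniform(0.1, 5.0, 3))
        assert sum(occupancy_percentages(self._fit_with_areas(areas))) == pytest.approx(100.0)

    def test_zero_total_area_rejected(self):
        with pytest.raises(ValueError):
            occupancy_percentages(self._fit_with_areas((0.0, 0.0, 0.0)))


class TestFitTrimodal:
    def test_single_gaussian_resolves_to_middle_component(self):
        h = normalized_hist(gaussian_density(CENTERS, 0.5, 0.06))
        fit = fit_trimodal(h)
        assert fit.converged
        assert fit.occupancy_percent[1] > 99.0
        assert fit.occupancy_percent[0] + fit.occupancy_percent[2] < 1.0

    def test_two_component_mixture_weights_recovered(self):
        """0.6 N(0.3, 0.05) + 0.4 N(0.7, 0.05) -> occupancies (60, 0, 40)."""
        y = 0.6 * gaussian_density(CENTERS, 0.3, 0.05) + 0.4 * gaussian_density(
            CENTERS, 0.7, 0.05
        )
        fit = fit_trimodal(normalized_hist(y))
        np.testing.assert_allclose(fit.occupancy_percent, (60.0, 0.0, 40.0), atol=2.0)

    def test_exactly_trimodal_input_machine_recovery(self):
        truth = TrimodalModel(amplitudes=(0.03, 0.01, 0.02), sigma=0.05)
        fit = fit_trimodal(normalized_hist(truth(CENTERS)))
        assert fit.residual_ss < 1e-8

    def test_default_start_matches_multistart(self, rng):
        """The prescribed initial values find the same optimum as 100 restarts."""
        y = 0.6 * gaussian_density(CENTERS, 0.3, 0.05) + 0.4 * gaussian_density(
            CENTERS, 0.7, 0.05
        )
        h = normalized_hist(y)
        default_fit = fit_trimodal(h)
        best = None
        for _ in range(100):
            init = TrimodalModel(
                amplitudes=tuple(rng.uniform(1e-3, 1.0, 3)), sigma=rng.uniform(5e-3, 0.3)
            )
            f = fit_trimodal(h, init)
            if best is None or f.residual_ss < best.residual_ss:
                best = f
        np.testing.assert_allclose(
            default_fit.occupancy_percent, best.occupancy_percent, atol=0.1
        )

    def test_occupancy_invariant_to_histogram_scale(self):
        y = 0.6 * gaussian_density(CENTERS, 0.3, 0.05) + 0.4 * gaussian_density(
            CENTERS, 0.7, 0.05
        )
        h1 = normalized_hist(y)
        h2 = FretHistogram(bin_edges=EDGES, fractions=h1.fractions, n_traces=9,
                           n_frames_counted=9)
        f1, f2 = fit_trimodal(h1), fit_trimodal(h2)
        np.testing.assert_allclose(f1.occupancy_percent, f2.occupancy_percent, atol=1e-6)

    def test_shared_width_occupancies_equal_amplitude_ratios(self):
        y = 0.5 * gaussian_density(CENTERS, 0.3, 0.04) + 0.5 * gaussian_density(
            CENTERS, 0.5, 0.04
        )
        fit = fit_trimodal(normalized_hist(y))
        np.testing.assert_allclose(
            fit.occupancy_percent, fit.amplitude_percent, atol=0.5
        )

    def test_all_zero_histogram_rejected(self):
        h = FretHistogram(bin_edges=EDGES, fractions=np.zeros(len(CENTERS)),
                          n_traces=0, n_frames_counted=0)
        with pytest.raises(ValueError):
            fit_trimodal(h)

    def test_sparse_histogram_warns(self):
        y = np.zeros(len(CENTERS))
        y[20] = 1.0
        h = FretHistogram(bin_edges=EDGES, fractions=y, n_traces=1, n_frames_counted=10)
        with pytest.warns(UserWarning, match="non-empty bins"):
            fit_trimodal(h)
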