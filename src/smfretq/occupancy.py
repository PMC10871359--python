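"""Fixed-mean trimodal Gaussian decomposition of FRET histograms.

A condition histogram is modelled as the sum of three Gaussian components
with fixed means (defaults 0.3, 0.5, 0.7 -- the low/medium/high FRET states)
and a single shared width:

    f(x) = sum_n  A_n * exp(-(x - mu_n)^2 / (2 sigma^2))

Only the three amplitudes and sigma are fitted (nonlinear least squares over
the bin centers, starting from A = 0.05 and sigma = 0.01).  The area under
each fitted component is computed by composite Simpson's rule on the
histogram's own grid and reported as a percentage of the area under the
trimodal sum -- the occupancy of each conformational state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import least_squares

from smfretq.histograms import ConditionHistogram, FretHistogram

__all__ = [
    "TrimodalModel",
    "TrimodalFit",
    "fit_trimodal",
    "component_area",
    "occupancy_percentages",
]

SIGMA_BOUNDS = (1e-4, 0.5)


@dataclass(frozen=True)
class TrimodalModel:
    """Three fixed-mean Gaussian components with a shared width."""

    fixed_means: tuple[float, float, float] = (0.3, 0.5, 0.7)
    amplitudes: tuple[float, float, float] = (0.05, 0.05, 0.05)
    sigma: float = 0.01

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fixed_means) <= 0):
            raise ValueError("fixed_means must be strictly increasing")
        if np.any(np.asarray(self.amplitudes) < 0):
            raise ValueError("amplitudes must be >= 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for a, mu in zip(self.amplitudes, self.fixed_means):
            out += a * np.exp(-((x - mu) ** 2) / (2.0 * self.sigma**2))
        return out

    def component(self, n: int, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        mu = self.fixed_means[n]
        return self.amplitudes[n] * np.exp(-((x - mu) ** 2) / (2.0 * self.sigma**2))


@dataclass
class TrimodalFit:
    """Result of a trimodal fit: model, Simpson areas and occupancies."""

    model: TrimodalModel
    areas: tuple[float, float, float]
    total_area: float
    occupancy_percent: tuple[float, float, float]
    residual_ss: float
    converged: bool
    # amplitude-ratio occupancies; equal to the Simpson ratio in the
    # infinite-domain limit because the components share sigma
    amplitude_percent: tuple[float, float, float] = (np.nan, np.nan, np.nan)


def component_area(
    amplitude: float,
    sigma: float,
    mean: float,
    grid: np.ndarray,
) -> float:
    """Composite Simpson's-rule area of one Gaussian component on a grid.

    ``grid`` is the (uniform) set of evaluation points, normally the
    histogram's bin centers.  Simpson's rule needs an odd number of points;
    an even grid is extended by one step at the upper end.
    """
    x = np.asarray(grid, dtype=float)
    if len(x) < 3:
        raise ValueError("grid must have at least 3 points")
    step = np.diff(x)
    if not np.allclose(step, step[0]):
        raise ValueError("grid must be uniformly spaced")
    if len(x) % 2 == 0:
        x = np.append(x, x[-1] + step[0])
    y = amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sigma**2))
    return float(simpson(y, x=x))


def occupancy_percentages(fit: TrimodalFit) -> tuple[float, float, float]:
    """Per-component percentage of the area under the trimodal fit."""
    if fit.total_area <= 0:
        raise ValueError("total trimodal area must be > 0")
    return tuple(100.0 * a / fit.total_area for a in fit.areas)  # type: ignore[return-value]


def fit_trimodal(
    hist: FretHistogram | ConditionHistogram,
    model_init: TrimodalModel | None = None,
) -> TrimodalFit:
    """Fit the fixed-mean trimodal model to a normalized histogram.

    Nonlinear least squares over (A1, A2, A3, sigma) with the means held
    fixed; amplitudes are bounded below by zero and sigma to (1e-4, 0.5).
    Non-convergence is reported through the ``converged`` flag (with a
    warning), not raised.
    """
    init = model_init or TrimodalModel()
    if isinstance(hist, ConditionHistogram):
        x = hist.bin_centers
        y = hist.mean_fractions
    else:
        x = hist.bin_centers
        y = hist.fractions
    if np.all(y == 0):
        raise ValueError("cannot fit an all-zero histogram")
    if np.count_nonzero(y) < 10:
        warnings.warn("fewer than 10 non-empty bins; trimodal fit may be unstable")

    means = init.fixed_means

    def residuals(p: np.ndarray) -> np.ndarray:
        a1, a2, a3, sigma = p
        model = TrimodalModel(fixed_means=means, amplitudes=(a1, a2, a3), sigma=sigma)
        return model(x) - y

    p0 = np.array([*init.amplitudes, init.sigma])
    res = least_squares(
        residuals,
        p0,
        bounds=([0.0, 0.0, 0.0, SIGMA_BOUNDS[0]], [np.inf, np.inf, np.inf, SIGMA_BOUNDS[1]]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=10_000,
    )
    if not res.success:
        warnings.warn(f"trimodal fit did not converge: {res.message}")

    fitted = TrimodalModel(
        fixed_means=means,
        amplitudes=tuple(res.x[:3]),
        sigma=float(res.x[3]),
    )
    areas = tuple(
        component_area(fitted.amplitudes[n], fitted.sigma, means[n], x) for n in range(3)
    )
    total = float(sum(areas))
    fit = TrimodalFit(
        model=fitted,
        areas=areas,  # type: ignore[arg-type]
        total_area=total,
        occupancy_percent=(np.nan, np.nan, np.nan),
        residual_ss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
    )
    fit.occupancy_percent = occupancy_percentages(fit)
    amp_sum = float(sum(fitted.amplitudes))
    if amp_sum > 0:
        fit.amplitude_percent = tuple(100.0 * a / amp_sum for a in fitted.amplitudes)
    return fit
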