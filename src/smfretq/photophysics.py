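"""Dye photophysics: rendering state paths into noisy two-channel traces.

The emission model is deliberately minimal but produces every signature the
downstream selection filters test for:

* while both dyes are emitting, donor = I*(1-E) and acceptor = I*E, where I is
  the mean photon budget of the pair per frame and E the within-frame
  time-averaged FRET efficiency -- donor and acceptor are exactly
  anti-correlated and their sum is constant;
* each dye photobleaches irreversibly after a single-exponential lifetime;
  after the acceptor bleaches the donor recovers to I, after the donor
  bleaches both channels fall to background;
* the acceptor may additionally blink (reversible two-state on/off);
* noise is Poisson shot noise on signal + background photons plus additive
  Gaussian read noise (camera gain fixed at 1 photon/count); traces are
  reported background-subtracted, as produced by aperture photometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from smfretq.kinetics import KineticModel, StatePath, simulate_state_path
from smfretq.traces import FluorTrace

__all__ = [
    "PhotophysicsParams",
    "GroundTruth",
    "SimulatedCondition",
    "render_trace",
    "simulate_condition",
]


@dataclass(frozen=True)
class PhotophysicsParams:
    """Emission, photobleaching and camera-noise parameters.

    Parameters
    ----------
    total_intensity
        Mean photons per frame emitted by the donor/acceptor pair.
    frame_interval
        Camera integration time in seconds (default 0.1 s, i.e. 10 fps).
    donor_bleach_tau, acceptor_bleach_tau
        Single-exponential photobleaching lifetimes in seconds; ``inf``
        disables bleaching of that dye.
    acceptor_blink_on_rate, acceptor_blink_off_rate
        Rates (1/s) of the acceptor's dark->emitting and emitting->dark
        transitions; both zero (default) disables blinking.
    background_mean
        Mean background photons per frame per channel (removed again by
        background subtraction, but it contributes shot noise).
    read_noise_sd
        Gaussian read noise per channel per frame, in photons.
    donor_leak_fraction
        Fraction of detected donor signal that also appears in the acceptor
        channel (spectral bleed-through).
    shot_noise
        Disable to obtain deterministic, noise-free ideal traces.
    """

    total_intensity: float = 1000.0
    frame_interval: float = 0.1
    donor_bleach_tau: float = 40.0
    acceptor_bleach_tau: float = 25.0
    acceptor_blink_on_rate: float = 0.0
    acceptor_blink_off_rate: float = 0.0
    background_mean: float = 200.0
    read_noise_sd: float = 20.0
    donor_leak_fraction: float = 0.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        for name in (
            "total_intensity",
            "donor_bleach_tau",
            "acceptor_bleach_tau",
            "acceptor_blink_on_rate",
            "acceptor_blink_off_rate",
            "background_mean",
            "read_noise_sd",
        ):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.donor_leak_fraction < 1.0:
            raise ValueError("donor_leak_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Simulation ground truth emitted alongside each synthetic trace."""

    state_path: StatePath
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    occupancy: np.ndarray  # time-in-state fractions over the FRET-alive frames
    alive_frames: int      # frames before the first bleach of either dye


@dataclass
class SimulatedCondition:
    """One experimental condition: several movies' worth of traces."""

    movies: list[list[FluorTrace]]
    ground_truth: list[list[GroundTruth]]
    pooled_occupancy: np.ndarray
    model: KineticModel
    photophysics: PhotophysicsParams


def _draw_bleach_frame(
    tau: float, frame_interval: float, n_frames: int, rng: np.random.Generator
) -> int | None:
    """Exponential bleach time, reported as the first fully dark frame."""
    if not math.isfinite(tau):
        return None
    t = rng.exponential(tau) if tau > 0 else 0.0
    frame = int(t / frame_interval)
    return frame if frame < n_frames else None


def _blink_on_fraction(
    params: PhotophysicsParams, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame fraction of the exposure the acceptor spends emitting."""
    if params.acceptor_blink_off_rate <= 0:
        return np.ones(n_frames)
    model = KineticModel(
        state_names=("on", "off"),
        state_fret=(1.0, 0.0),  # reused as the on-indicator
        rate_matrix=np.array(
            [[0.0, params.acceptor_blink_off_rate], [params.acceptor_blink_on_rate, 0.0]]
        ),
        initial_probs=np.array([1.0, 0.0]),  # start emitting
    )
    path = simulate_state_path(model, n_frames * params.frame_interval, rng)
    return path.frame_fret(params.frame_interval, n_frames)


def render_trace(
    path: StatePath,
    photophysics: PhotophysicsParams,
    n_frames: int,
    seed: int | np.random.Generator,
    *,
    donor_bleach_frame: int | None | str = "draw",
    acceptor_bleach_frame: int | None | str = "draw",
    trace_id: str = "trace",
) -> tuple[FluorTrace, GroundTruth]:
    """Render a conformational state path into a noisy two-channel trace.

    Bleach frames are drawn from the exponential dye lifetimes unless forced
    via ``donor_bleach_frame`` / ``acceptor_bleach_frame`` (pass ``None`` to
    force no bleach, an integer to force the frame).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    p = photophysics
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if donor_bleach_frame == "draw":
        donor_bleach_frame = _draw_bleach_frame(p.donor_bleach_tau, p.frame_interval, n_frames, rng)
    if acceptor_bleach_frame == "draw":
        acceptor_bleach_frame = _draw_bleach_frame(
            p.acceptor_bleach_tau, p.frame_interval, n_frames, rng
        )

    e = path.frame_fret(p.frame_interval, n_frames)
    on_frac = _blink_on_fraction(p, n_frames, rng)
    frames = np.arange(n_frames)

    acceptor_alive = np.ones(n_frames, dtype=bool)
    if acceptor_bleach_frame is not None:
        acceptor_alive &= frames < acceptor_bleach_frame
    donor_alive = np.ones(n_frames, dtype=bool)
    if donor_bleach_frame is not None:
        donor_alive &= frames < donor_bleach_frame

    e_eff = np.where(acceptor_alive, e * on_frac, 0.0)
    donor_sig = np.where(donor_alive, p.total_intensity * (1.0 - e_eff), 0.0)
    acceptor_sig = np.where(donor_alive, p.total_intensity * e_eff, 0.0)
    acceptor_sig = acceptor_sig + p.donor_leak_fraction * donor_sig

    if p.shot_noise:
        donor = rng.poisson(donor_sig + p.background_mean).astype(float)
        acceptor = rng.poisson(acceptor_sig + p.background_mean).astype(float)
    else:
        donor = donor_sig + p.background_mean
        acceptor = acceptor_sig + p.background_mean
    if p.read_noise_sd > 0:
        donor = donor + rng.normal(0.0, p.read_noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, p.read_noise_sd, n_frames)
    donor -= p.background_mean
    acceptor -= p.background_mean

    first_bleach = [f for f in (donor_bleach_frame, acceptor_bleach_frame) if f is not None]
    alive = min(first_bleach) if first_bleach else n_frames
    occ = path.frame_occupancy(p.frame_interval, max(alive, 1))

    trace = FluorTrace(
        trace_id=trace_id,
        donor=donor,
        acceptor=acceptor,
        frame_interval=p.frame_interval,
    )
    truth = GroundTruth(
        state_path=path,
        donor_bleach_frame=donor_bleach_frame,
        acceptor_bleach_frame=acceptor_bleach_frame,
        occupancy=occ,
        alive_frames=alive,
    )
    return trace, truth


def simulate_condition(
    model: KineticModel,
    photophysics: PhotophysicsParams,
    n_movies: int = 4,
    traces_per_movie: int = 50,
    seed: int | np.random.SeedSequence = 0,
    n_frames: int = 600,
) -> SimulatedCondition:
    """Simulate one condition: ``n_movies`` movies of independent molecules.

    Each movie gets an independent seeded random stream spawned from the
    master seed, so the output is bit-reproducible and movies are exchangeable.
    Pooled ground-truth occupancy is the frame-weighted average of the
    per-trace occupancies over their FRET-alive segments.
    """
    if n_movies < 1:
        raise ValueError("n_movies must be >= 1")
    if traces_per_movie < 1:
        raise ValueError("traces_per_movie must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    movie_seeds = ss.spawn(n_movies)

    movies: list[list[FluorTrace]] = []
    truths: list[list[GroundTruth]] = []
    occ_sum = np.zeros(model.n_states)
    occ_weight = 0.0
    duration = n_frames * photophysics.frame_interval
    for mi, mseed in enumerate(movie_seeds):
        rng = np.random.default_rng(mseed)
        movie: list[FluorTrace] = []
        movie_truth: list[GroundTruth] = []
        for ti in range(traces_per_movie):
            path = simulate_state_path(model, duration, rng)
            trace, truth = render_trace(
                path,
                photophysics,
                n_frames,
                rng,
                trace_id=f"m{mi:02d}_t{ti:04d}",
            )
            trace.source = {"movie": mi, "index": ti}
            movie.append(trace)
            movie_truth.append(truth)
            if truth.alive_frames > 0:
                occ_sum += truth.occupancy * truth.alive_frames
                occ_weight += truth.alive_frames
        movies.append(movie)
        truths.append(movie_truth)

    pooled = occ_sum / occ_weight if occ_weight > 0 else np.full(model.n_states, np.nan)
    return SimulatedCondition(
        movies=movies,
        ground_truth=truths,
        pooled_occupancy=pooled,
        model=model,
        photophysics=photophysics,
    )
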