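"""Synthetic benchmark fixtures for validating the analysis stages.

These builders produce the standard test conditions used throughout the test
suite and the acceptance checks: photophysics at a target signal-to-noise
ratio, ideal one-donor/one-acceptor traces with conformational dynamics and
forced in-window bleaching, the canonical selection violators (dual-donor,
dual-acceptor, short-lifetime, non-anticorrelated), two-change-point step
traces, and a well-separated synthetic spot movie.

SNR is defined per channel: mean signal at E = 0.5 (half the pair's photon
budget) divided by the channel noise SD (shot noise of signal plus
background, plus read noise).
"""

from __future__ import annotations

import numpy as np

from smfretq.kinetics import KineticModel, simulate_state_path
from smfretq.movie_sim import SyntheticMovie, render_movie
from smfretq.photophysics import PhotophysicsParams, render_trace
from smfretq.registration import ChannelTransform
from smfretq.traces import FluorTrace

__all__ = [
    "photophysics_for_snr",
    "make_ideal_trace",
    "make_dual_donor_trace",
    "make_dual_acceptor_trace",
    "make_short_lifetime_trace",
    "make_uncorrelated_trace",
    "make_selection_fixture",
    "make_two_step_series",
    "make_spot_movie",
]

FIXTURE_FRAMES = 300
_I = 1000.0
_BG = 200.0


def photophysics_for_snr(
    snr: float = 10.0,
    total_intensity: float = _I,
    background_mean: float = _BG,
    **kwargs,
) -> PhotophysicsParams:
    """Photophysics whose per-channel SNR at E=0.5 equals ``snr``.

    The read-noise SD is solved from
    (I/2) / sqrt(I/2 + bg + rn^2) = snr; the requested SNR must be
    attainable given the shot-noise floor.
    """
    half = total_intensity / 2.0
    rn_sq = (half / snr) ** 2 - half - background_mean
    if rn_sq < 0:
        raise ValueError(f"SNR {snr} is above the shot-noise limit for these intensities")
    kwargs.setdefault("donor_bleach_tau", np.inf)
    kwargs.setdefault("acceptor_bleach_tau", np.inf)
    return PhotophysicsParams(
        total_intensity=total_intensity,
        background_mean=background_mean,
        read_noise_sd=float(np.sqrt(rn_sq)),
        **kwargs,
    )


def _noisy(rng: np.random.Generator, signal: np.ndarray, pp: PhotophysicsParams) -> np.ndarray:
    out = rng.poisson(signal + pp.background_mean).astype(float)
    if pp.read_noise_sd > 0:
        out = out + rng.normal(0.0, pp.read_noise_sd, len(signal))
    return out - pp.background_mean


def make_ideal_trace(
    rng: np.random.Generator,
    model: KineticModel | None = None,
    pp: PhotophysicsParams | None = None,
    n_frames: int = FIXTURE_FRAMES,
) -> tuple[FluorTrace, dict]:
    """One-donor/one-acceptor trace with dynamics and in-window bleaching.

    The acceptor bleaches first (uniformly in frames [100, 200)), the donor
    afterwards, so every selection criterion is satisfiable.
    """
    model = model or KineticModel.default_three_state()
    pp = pp or photophysics_for_snr(10.0)
    path = simulate_state_path(model, n_frames * pp.frame_interval, rng)
    ab = int(rng.integers(100, 200))
    db = int(rng.integers(ab + 30, n_frames - 10))
    trace, truth = render_trace(
        path, pp, n_frames, rng, donor_bleach_frame=db, acceptor_bleach_frame=ab,
        trace_id="ideal",
    )
    return trace, {"kind": "ideal", "acceptor_bleach": ab, "donor_bleach": db, "truth": truth}


def make_dual_donor_trace(
    rng: np.random.Generator,
    model: KineticModel | None = None,
    pp: PhotophysicsParams | None = None,
    n_frames: int = FIXTURE_FRAMES,
) -> tuple[FluorTrace, dict]:
    """Molecule carrying two donors: the donor channel bleaches in two steps."""
    model = model or KineticModel.default_three_state()
    pp = pp or photophysics_for_snr(10.0)
    e = simulate_state_path(model, n_frames * pp.frame_interval, rng).frame_fret(
        pp.frame_interval, n_frames
    )
    t1 = int(rng.integers(60, 120))          # first donor bleach (partial loss)
    t2 = int(rng.integers(t1 + 40, 240))     # acceptor bleach
    t3 = int(rng.integers(t2 + 20, n_frames - 2))  # second donor bleach
    frames = np.arange(n_frames)
    scale = np.where(frames < t1, 1.0, 0.5) * (frames < t3)
    e_eff = e * (frames < t2)
    donor_sig = scale * _I * (1.0 - e_eff)
    acceptor_sig = scale * _I * e_eff
    trace = FluorTrace(
        "dual_donor", _noisy(rng, donor_sig, pp), _noisy(rng, acceptor_sig, pp),
        pp.frame_interval,
    )
    return trace, {"kind": "dual_donor", "steps": (t1, t2, t3)}


def make_dual_acceptor_trace(
    rng: np.random.Generator,
    model: KineticModel | None = None,
    pp: PhotophysicsParams | None = None,
    n_frames: int = FIXTURE_FRAMES,
    share: float | None = None,
) -> tuple[FluorTrace, dict]:
    """Molecule with two FRET-coupled acceptors (two acceptor steps).

    When the first acceptor bleaches the apparent efficiency is compressed
    to the surviving acceptor's ``share`` (drawn uniformly in [0.4, 0.6] by
    default: two identical dyes at generic geometries contribute comparable
    but unequal shares); the second bleach takes the acceptor channel to
    background.
    """
    model = model or KineticModel.default_three_state()
    pp = pp or photophysics_for_snr(10.0)
    if share is None:
        share = float(rng.uniform(0.4, 0.6))
    e = simulate_state_path(model, n_frames * pp.frame_interval, rng).frame_fret(
        pp.frame_interval, n_frames
    )
    t1 = int(rng.integers(100, 140))
    t2 = int(rng.integers(t1 + 80, 260))
    t3 = int(rng.integers(t2 + 20, n_frames - 2))
    frames = np.arange(n_frames)
    e_eff = e * np.where(frames < t1, 1.0, share) * (frames < t2)
    donor_sig = np.where(frames < t3, _I * (1.0 - e_eff), 0.0)
    acceptor_sig = np.where(frames < t3, _I * e_eff, 0.0)
    trace = FluorTrace(
        "dual_acceptor", _noisy(rng, donor_sig, pp), _noisy(rng, acceptor_sig, pp),
        pp.frame_interval,
    )
    return trace, {"kind": "dual_acceptor", "steps": (t1, t2, t3)}


def make_short_lifetime_trace(
    rng: np.random.Generator,
    model: KineticModel | None = None,
    pp: PhotophysicsParams | None = None,
    n_frames: int = FIXTURE_FRAMES,
) -> tuple[FluorTrace, dict]:
    """Acceptor bleaches within the first 50 frames: FRET lifetime too short."""
    model = model or KineticModel.default_three_state()
    pp = pp or photophysics_for_snr(10.0)
    path = simulate_state_path(model, n_frames * pp.frame_interval, rng)
    ab = int(rng.integers(15, 46))
    db = int(rng.integers(ab + 30, n_frames - 10))
    trace, _ = render_trace(
        path, pp, n_frames, rng, donor_bleach_frame=db, acceptor_bleach_frame=ab,
        trace_id="short_lifetime",
    )
    return trace, {"kind": "short_lifetime", "acceptor_bleach": ab}


def make_uncorrelated_trace(
    rng: np.random.Generator,
    pp: PhotophysicsParams | None = None,
    n_frames: int = FIXTURE_FRAMES,
) -> tuple[FluorTrace, dict]:
    """Two spectrally co-located but non-interacting emitters: no FRET.

    Channel intensities fluctuate independently (no anti-correlation); step
    structure mimics a genuine trace (acceptor to background, donor rise,
    donor bleach) so the anti-correlation criterion is what rejects it.
    """
    pp = pp or photophysics_for_snr(10.0)
    t2 = int(rng.integers(80, 180))
    t3 = int(rng.integers(t2 + 30, n_frames - 2))
    frames = np.arange(n_frames)
    # common-mode excitation fluctuations couple the two emitters positively
    excitation = 1.0 + rng.normal(0.0, 0.05, n_frames)
    donor_sig = np.where(frames < t2, _I / 2, np.where(frames < t3, _I, 0.0)) * excitation
    acceptor_sig = np.where(frames < t2, _I / 2, 0.0) * excitation
    trace = FluorTrace(
        "uncorrelated", _noisy(rng, donor_sig, pp), _noisy(rng, acceptor_sig, pp),
        pp.frame_interval,
    )
    return trace, {"kind": "uncorrelated", "steps": (t2, t3)}


def make_selection_fixture(
    n_traces: int = 500,
    seed: int = 0,
    snr: float = 10.0,
) -> tuple[list[FluorTrace], list[str]]:
    """The mixed selection benchmark: 50% ideal, 50% violators.

    Violators split evenly between dual-donor, dual-acceptor, short-lifetime
    and non-anticorrelated traces.  Returns traces and their kind labels.
    """
    rng = np.random.default_rng(seed)
    pp = photophysics_for_snr(snr)
    model = KineticModel.default_three_state()
    makers = {
        "ideal": lambda: make_ideal_trace(rng, model, pp),
        "dual_donor": lambda: make_dual_donor_trace(rng, model, pp),
        "dual_acceptor": lambda: make_dual_acceptor_trace(rng, model, pp),
        "short_lifetime": lambda: make_short_lifetime_trace(rng, model, pp),
        "uncorrelated": lambda: make_uncorrelated_trace(rng, pp),
    }
    n_ideal = n_traces // 2
    n_violators = n_traces - n_ideal
    kinds = ["ideal"] * n_ideal
    violator_kinds = ["dual_donor", "dual_acceptor", "short_lifetime", "uncorrelated"]
    kinds += [violator_kinds[i % 4] for i in range(n_violators)]
    traces, labels = [], []
    for i, kind in enumerate(kinds):
        trace, _ = makers[kind]()
        trace.trace_id = f"{kind}_{i:04d}"
        traces.append(trace)
        labels.append(kind)
    return traces, labels


def make_two_step_series(
    rng: np.random.Generator,
    n_frames: int = 100,
    levels: tuple[float, float, float] = (1000.0, 600.0, 0.0),
    noise_sd: float = 80.0,
) -> tuple[np.ndarray, tuple[int, int]]:
    """A two-change-point piecewise-constant series with Gaussian noise.

    Change points are drawn with at least 10 frames per segment; the smaller
    step is 5x the noise SD at the defaults (SNR 5).
    """
    c1 = int(rng.integers(10, n_frames // 2))
    c2 = int(rng.integers(c1 + 10, n_frames - 10))
    x = np.full(n_frames, levels[0])
    x[c1:] = levels[1]
    x[c2:] = levels[2]
    return x + rng.normal(0.0, noise_sd, n_frames), (c1, c2)


def make_spot_movie(
    n_spots: int = 20,
    seed: int = 0,
    n_frames: int = 100,
    image_shape: tuple[int, int] = (160, 160),
    psf_sigma_px: float = 2.5,
    min_separation_px: float = 14.0,
    background_mean: float = 100.0,
    total_intensity: float = 4000.0,
    transform: ChannelTransform | None = None,
) -> tuple[SyntheticMovie, list[FluorTrace]]:
    """A two-channel movie of well-separated spots at peak SNR ~10.

    Spot traces are noise-free ideal traces (the movie adds shot and read
    noise), so extracted traces can be correlated against exact ground truth.
    Peak SNR: peak pixel amplitude I/(2 pi sigma^2) ~ 100 over a background
    noise SD of ~10 at the default background of 100 photons/px.  Both dyes
    bleach inside the window and the state efficiencies span 0.15-0.85, so
    each channel of every trace carries large intensity contrast relative to
    the aperture-photometry noise floor.
    """
    rng = np.random.default_rng(seed)
    margin = 16.0
    positions: list[np.ndarray] = []
    while len(positions) < n_spots:
        cand = rng.uniform(margin, np.array(image_shape) - margin)
        if all(np.linalg.norm(cand - p) >= min_separation_px for p in positions):
            positions.append(cand)
    positions = np.array(positions)

    model = KineticModel(
        state_names=("low", "mid", "high"),
        state_fret=(0.15, 0.5, 0.85),
        rate_matrix=np.array([[0.0, 1.2, 0.0], [1.2, 0.0, 0.8], [0.0, 1.6, 0.0]]),
    )
    pp = PhotophysicsParams(
        total_intensity=total_intensity, background_mean=0.0, read_noise_sd=0.0,
        shot_noise=False, donor_bleach_tau=np.inf, acceptor_bleach_tau=np.inf,
    )
    traces = []
    for i in range(n_spots):
        path = simulate_state_path(model, n_frames * pp.frame_interval, rng)
        ab = int(rng.integers(int(0.55 * n_frames), int(0.75 * n_frames)))
        db = int(rng.integers(int(0.8 * n_frames), int(0.94 * n_frames)))
        trace, _ = render_trace(
            path, pp, n_frames, rng, donor_bleach_frame=db, acceptor_bleach_frame=ab,
            trace_id=f"truth{i:04d}",
        )
        traces.append(trace)
    movie = render_movie(
        traces,
        positions,
        psf_sigma_px=psf_sigma_px,
        image_shape=image_shape,
        channel_offset=transform or ChannelTransform.identity(),
        seed=rng,
        background_mean=background_mean,
        read_noise_sd=2.0,
    )
    return movie, traces
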