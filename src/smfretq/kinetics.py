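"""Continuous-time Markov models of conformational dynamics.

A molecule interconverts between a small number of discrete conformational
states, each with a characteristic FRET efficiency.  State paths are simulated
with the exact stochastic simulation algorithm (Gillespie), so transition
times are continuous and a camera frame can straddle a transition; the
per-frame FRET efficiency is then the time average of the state efficiencies
over the frame interval, which reproduces the inter-state blurring seen in
real camera-limited recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticModel",
    "StatePath",
    "simulate_state_path",
]


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class KineticModel:
    """Discrete-state conformational model with FRET means and transition rates.

    Parameters
    ----------
    state_names
        One label per state, e.g. ``("splayed", "compact", "super-compact")``.
    state_fret
        FRET efficiency of each state, in [0, 1].
    rate_matrix
        Square matrix of transition rates in 1/s.  Entry ``[i, j]`` is the
        rate from state ``i`` to state ``j``; the diagonal is ignored (the
        exit rate of a state is the sum of its off-diagonal row entries).
    initial_probs
        Probability of starting a path in each state.  Defaults to the
        stationary distribution of ``rate_matrix``.
    """

    state_names: tuple[str, ...]
    state_fret: tuple[float, ...]
    rate_matrix: np.ndarray
    initial_probs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.state_names)
        if n < 1:
            raise ValueError("KineticModel needs at least one state")
        if len(self.state_fret) != n:
            raise ValueError("state_fret must have one entry per state")
        fret = np.asarray(self.state_fret, dtype=float)
        if not np.all((fret >= 0.0) & (fret <= 1.0)):
            raise ValueError("state_fret values must lie in [0, 1]")
        q = np.asarray(self.rate_matrix, dtype=float)
        if q.shape != (n, n):
            raise ValueError(f"rate_matrix must be {n}x{n}, got {q.shape}")
        if not np.all(np.isfinite(q)):
            raise ValueError("rate_matrix entries must be finite")
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0.0):
            raise ValueError("off-diagonal rates must be >= 0")
        object.__setattr__(self, "rate_matrix", off)
        if self.initial_probs is None:
            p0 = self.stationary_distribution()
        else:
            p0 = np.asarray(self.initial_probs, dtype=float)
            if p0.shape != (n,):
                raise ValueError("initial_probs must have one entry per state")
            if np.any(p0 < 0.0) or abs(p0.sum() - 1.0) > 1e-12:
                raise ValueError("initial_probs must be a probability vector")
        object.__setattr__(self, "initial_probs", p0)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution pi of the chain: pi @ Q = 0, sum(pi) = 1."""
        n = self.n_states
        if n == 1:
            return np.ones(1)
        gen = self.rate_matrix.copy()
        np.fill_diagonal(gen, -gen.sum(axis=1))
        # Augment pi @ Q = 0 with the normalisation constraint.
        a = np.vstack([gen.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    @classmethod
    def default_three_state(cls) -> "KineticModel":
        """Three conformational classes: splayed / compact / super-compact.

        Mean efficiencies 0.35, 0.50 and 0.70; interconversion rates of order
        0.5-1 per second, giving dwell times of a few hundred milliseconds to
        a couple of seconds at 10 fps.
        """
        rates = np.array(
            [
                [0.0, 0.6, 0.0],
                [0.6, 0.0, 0.4],
                [0.0, 0.8, 0.0],
            ]
        )
        return cls(
            state_names=("splayed", "compact", "super-compact"),
            state_fret=(0.35, 0.50, 0.70),
            rate_matrix=rates,
        )


@dataclass(frozen=True)
class StatePath:
    """Piecewise-constant state trajectory from a Gillespie simulation.

    ``entry_times[i]`` is when ``states[i]`` is entered; the segment lasts
    until the next entry or ``duration``.  ``fret[i]`` is the state's FRET
    efficiency, carried alongside so downstream rendering does not need the
    model object.
    """

    states: np.ndarray          # int, segment state indices
    entry_times: np.ndarray     # float seconds, strictly increasing, starts at 0
    fret: np.ndarray            # float, efficiency of each segment
    duration: float
    n_states: int

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("empty state path")
        if self.entry_times[0] != 0.0:
            raise ValueError("first segment must start at t=0")
        if np.any(np.diff(self.entry_times) <= 0):
            raise ValueError("entry times must be strictly increasing")

    def occupancy(self, t_end: float | None = None) -> np.ndarray:
        """Fraction of [0, t_end) spent in each state."""
        t_end = self.duration if t_end is None else min(t_end, self.duration)
        if t_end <= 0:
            raise ValueError("t_end must be > 0")
        ends = np.append(self.entry_times[1:], self.duration)
        dt = np.clip(np.minimum(ends, t_end) - np.minimum(self.entry_times, t_end), 0.0, None)
        occ = np.bincount(self.states, weights=dt, minlength=self.n_states)
        return occ / occ.sum()

    def frame_fret(self, frame_interval: float, n_frames: int) -> np.ndarray:
        """Time-averaged FRET efficiency of each camera frame.

        Each frame integrates over ``frame_interval`` seconds; a frame that
        straddles a transition reports the dwell-time-weighted mean of the
        efficiencies of the states visited during the exposure.
        """
        edges = np.arange(n_frames + 1) * frame_interval
        seg_start = self.entry_times
        seg_end = np.append(self.entry_times[1:], max(self.duration, edges[-1]))
        out = np.zeros(n_frames)
        weight = np.zeros(n_frames)
        for s0, s1, e in zip(seg_start, seg_end, self.fret):
            lo = int(np.searchsorted(edges, s0, side="right")) - 1
            hi = int(np.searchsorted(edges, s1, side="left"))
            for f in range(max(lo, 0), min(hi, n_frames)):
                overlap = min(s1, edges[f + 1]) - max(s0, edges[f])
                if overlap > 0:
                    out[f] += overlap * e
                    weight[f] += overlap
        covered = weight > 0
        out[covered] /= weight[covered]
        # frames beyond the simulated duration hold the last state
        out[~covered] = self.fret[-1]
        return out

    def frame_occupancy(self, frame_interval: float, n_frames: int) -> np.ndarray:
        """Time-in-state fractions over the first ``n_frames`` frames."""
        return self.occupancy(t_end=n_frames * frame_interval)


def simulate_state_path(
    model: KineticModel,
    duration: float,
    seed: int | np.random.Generator,
) -> StatePath:
    """Exact-event (Gillespie) simulation of the conformational chain.

    The initial state is drawn from ``model.initial_probs``; holding times are
    exponential with the state's total exit rate and the destination is drawn
    proportionally to the outgoing rates.  States with zero exit rate are
    absorbing.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = _as_rng(seed)
    rates = model.rate_matrix
    exit_rates = rates.sum(axis=1)
    fret = np.asarray(model.state_fret, dtype=float)

    state = int(rng.choice(model.n_states, p=model.initial_probs))
    t = 0.0
    states = [state]
    times = [0.0]
    while True:
        k = exit_rates[state]
        if k <= 0.0:
            break
        t += rng.exponential(1.0 / k)
        if t >= duration:
            break
        state = int(rng.choice(model.n_states, p=rates[state] / k))
        states.append(state)
        times.append(t)
    s = np.asarray(states, dtype=np.int64)
    return StatePath(
        states=s,
        entry_times=np.asarray(times),
        fret=fret[s],
        duration=float(duration),
        n_states=model.n_states,
    )
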