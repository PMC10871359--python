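"""Per-frame FRET efficiencies, per-movie display histograms, and
cross-movie statistics.

Efficiency is the apparent ratiometric value E = IA / (IA + ID) on
background-subtracted intensities (gamma = 1, no spectral corrections by
default).  Each accepted trace contributes its first 50 FRET-alive frames to
its movie's display histogram (bin width 0.02); per-movie histograms are
averaged with SEM across movies, and the median/quartiles of a histogram are
read off as the center of the first bin whose cumulative fraction strictly
exceeds 25, 50 or 75%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from smfretq.traces import FluorTrace

__all__ = [
    "FretSeries",
    "FretHistogram",
    "ConditionHistogram",
    "compute_fret",
    "movie_histogram",
    "combine_movies_if_sparse",
    "average_histograms",
    "histogram_quartiles",
    "default_bin_edges",
]

DEFAULT_BIN_WIDTH = 0.02
DEFAULT_RANGE = (-0.1, 1.0)
DEFAULT_DISPLAY_FRAMES = 50


@dataclass
class FretSeries:
    """Per-frame apparent FRET efficiency over the FRET-alive segment.

    Values may slightly exceed [0, 1] because of noise; frames whose total
    intensity was non-positive are NaN and excluded from histograms.
    """

    trace_id: str
    efficiency: np.ndarray

    def __len__(self) -> int:
        return len(self.efficiency)


@dataclass
class FretHistogram:
    """A normalized per-movie display histogram of FRET efficiencies."""

    bin_edges: np.ndarray
    fractions: np.ndarray
    n_traces: int
    n_frames_counted: int
    movie_id: str = "movie"

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.bin_edges) - 1:
            raise ValueError("fractions must have one entry per bin")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be >= 0")
        if self.n_frames_counted > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ConditionHistogram:
    """Cross-movie average of per-movie histograms, with SEM and quartiles."""

    movie_histograms: list[FretHistogram]
    mean_fractions: np.ndarray
    sem_fractions: np.ndarray
    movie_quartiles: list[tuple[float, float, float]]
    quartiles: tuple[float, float, float]  # mean of the per-movie quartiles

    @property
    def bin_edges(self) -> np.ndarray:
        return self.movie_histograms[0].bin_edges

    @property
    def bin_centers(self) -> np.ndarray:
        return self.movie_histograms[0].bin_centers

    @property
    def n_movies(self) -> int:
        return len(self.movie_histograms)


def default_bin_edges(
    bin_width: float = DEFAULT_BIN_WIDTH,
    fret_range: tuple[float, float] = DEFAULT_RANGE,
) -> np.ndarray:
    n_bins = int(round((fret_range[1] - fret_range[0]) / bin_width))
    return fret_range[0] + bin_width * np.arange(n_bins + 1)


def compute_fret(
    trace: FluorTrace,
    fret_lifetime: int,
    gamma: float = 1.0,
    donor_leak_fraction: float = 0.0,
) -> FretSeries:
    """Apparent ratiometric FRET efficiency for the FRET-alive frames.

    With the optional corrections, E = (IA - l*ID) / (IA - l*ID + g*ID) for
    leak fraction l and detection-efficiency ratio g; both default to the
    uncorrected apparent value E = IA / (IA + ID).
    """
    if fret_lifetime < 1:
        raise ValueError("fret_lifetime must be >= 1")
    d = trace.donor[:fret_lifetime]
    a = trace.acceptor[:fret_lifetime] - donor_leak_fraction * d
    total = a + gamma * d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, a / total, np.nan)
    return FretSeries(trace_id=trace.trace_id, efficiency=e)


def movie_histogram(
    fret_series: list[FretSeries],
    n_display_frames: int = DEFAULT_DISPLAY_FRAMES,
    bin_width: float = DEFAULT_BIN_WIDTH,
    fret_range: tuple[float, float] = DEFAULT_RANGE,
    movie_id: str = "movie",
) -> FretHistogram:
    """Display histogram of one movie's accepted traces.

    Each trace contributes at most its first ``n_display_frames`` efficiency
    values; values outside the histogram range are clipped into the terminal
    bins, so total mass is conserved.
    """
    if not fret_series:
        raise ValueError("cannot histogram an empty list of FRET series")
    edges = default_bin_edges(bin_width, fret_range)
    values = np.concatenate(
        [s.efficiency[:n_display_frames] for s in fret_series]
    )
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no finite FRET values to histogram")
    eps = 1e-12
    clipped = np.clip(values, edges[0], edges[-1] - eps)
    counts, _ = np.histogram(clipped, bins=edges)
    return FretHistogram(
        bin_edges=edges,
        fractions=counts / counts.sum(),
        n_traces=len(fret_series),
        n_frames_counted=int(counts.sum()),
        movie_id=movie_id,
    )


def combine_movies_if_sparse(
    per_movie_traces: list[list],
    min_traces: int = 20,
    max_combine: int = 3,
) -> list[list[int]]:
    """Greedily merge adjacent sparse movies (low expression) into groups.

    A movie with at least ``min_traces`` accepted traces always stands alone.
    Consecutive sparse movies are pooled until the pooled count reaches
    ``min_traces`` or the group holds ``max_combine`` movies.  Returns the
    grouping as lists of movie indices.
    """
    if max_combine < 1:
        raise ValueError("max_combine must be >= 1")
    groups: list[list[int]] = []
    current: list[int] = []
    current_count = 0
    for i, traces in enumerate(per_movie_traces):
        n = len(traces)
        if n >= min_traces:
            if current:
                groups.append(current)
                current, current_count = [], 0
            groups.append([i])
            continue
        current.append(i)
        current_count += n
        if current_count >= min_traces or len(current) >= max_combine:
            groups.append(current)
            current, current_count = [], 0
    if current:
        groups.append(current)
    return groups


def histogram_quartiles(hist: FretHistogram) -> tuple[float, float, float]:
    """Quartiles by the cumulative-bin rule.

    Each quartile is the center of the first bin (scanning in ascending FRET)
    whose cumulative fraction strictly exceeds 25, 50 or 75% of the counts.
    """
    if hist.fractions.sum() <= 0:
        raise ValueError("cannot take quartiles of an empty histogram")
    cum = np.cumsum(hist.fractions / hist.fractions.sum())
    centers = hist.bin_centers
    out = []
    for p in (0.25, 0.50, 0.75):
        idx = int(np.argmax(cum > p))
        out.append(float(centers[idx]))
    return tuple(out)  # type: ignore[return-value]


def average_histograms(histograms: list[FretHistogram]) -> ConditionHistogram:
    """Average per-movie histograms into a condition histogram.

    Per-bin mean and SEM (sample SD / sqrt(m)) are taken across the m movie
    histograms; condition quartiles are the mean of per-movie quartiles.
    With a single movie the SEM is zero by convention.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if len(h.bin_edges) != len(edges) or not np.allclose(h.bin_edges, edges):
            raise ValueError("histograms have mismatched binning")
    stack = np.vstack([h.fractions for h in histograms])
    mean = stack.mean(axis=0)
    if len(histograms) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(histograms))
    else:
        sem = np.zeros_like(mean)
    movie_q = [histogram_quartiles(h) for h in histograms]
    q = tuple(float(np.mean([mq[i] for mq in movie_q])) for i in range(3))
    return ConditionHistogram(
        movie_histograms=histograms,
        mean_fractions=mean,
        sem_fractions=sem,
        movie_quartiles=movie_q,
        quartiles=q,  # type: ignore[arg-type]
    )
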