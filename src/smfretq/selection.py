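"""Automated trace selection: single-step bleaching, stable total intensity,
donor-acceptor anti-correlation, and a minimum FRET lifetime.

A usable smFRET trace comes from a molecule carrying exactly one donor and
one acceptor.  The classic manual signatures of that stoichiometry are made
quantitative here:

* each channel must show exactly one photobleaching step -- a single abrupt,
  irreversible drop to background (or a large permanent partial loss, the
  signature of a second dye of the same colour);
* the summed donor+acceptor intensity must be constant until the donor
  bleaches (FRET redistributes photons between the channels, it does not
  destroy them);
* donor and acceptor must be globally anti-correlated while both dyes emit;
* FRET must be observable for more than a minimum number of frames
  (default 50) before the first bleach.

Step detection is penalized binary segmentation on a piecewise-constant
least-squares cost.  Distinguishing bleaching from conformational intensity
steps exploits three invariances of one-donor/one-acceptor FRET:

* the total intensity donor+acceptor is constant under conformational
  dynamics and under acceptor-side losses (FRET only redistributes photons),
  so every downward step in the total channel is a donor-side loss --
  the donor bleach-step count;
* a drop of the acceptor channel to background while the level set of the
  apparent efficiency is unchanged is the acceptor's own bleach (or a blink);
  conformational transitions never reach background because even the
  lowest-FRET state emits;
* losing one of two acceptors multiplies the apparent efficiency by the
  surviving acceptor's share, compressing *all* efficiency levels at once --
  an irreversible signature no conformational transition produces, tested by
  comparing upper and lower deciles of the efficiency before and after a
  candidate partial drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from smfretq.traces import FluorTrace

__all__ = [
    "SelectionCriteria",
    "SelectionReport",
    "detect_steps",
    "fret_lifetime",
    "total_intensity_cv",
    "anticorrelation",
    "apply_selection",
    "noise_sigma",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for automated trace selection.

    ``min_fret_lifetime_frames`` is compared strictly: a trace passes only if
    its FRET lifetime exceeds the threshold.  ``max_anticorrelation_r`` is an
    upper bound on the Pearson correlation (anti-correlation means r is
    negative).  The remaining knobs parameterize the step classifier; see the
    module docstring.
    """

    min_fret_lifetime_frames: int = 50
    max_donor_steps: int = 1
    max_acceptor_steps: int = 1
    max_total_intensity_cv: float = 0.15
    max_anticorrelation_r: float = -0.2
    min_pre_bleach_frames: int = 20
    min_step_sigma: float = 4.0          # candidate steps must exceed this x noise SD
    compression_ratio: float = 0.62      # compression must undercut the conformational level-ratio floor
    min_compression_window: int = 75     # frames needed on both sides of a candidate drop

    def __post_init__(self) -> None:
        if self.min_fret_lifetime_frames < 1:
            raise ValueError("min_fret_lifetime_frames must be >= 1")
        for name in ("max_total_intensity_cv", "max_anticorrelation_r"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SelectionReport:
    """Per-trace selection diagnostics and the accept/reject decision."""

    trace_id: str
    donor_step_count: int
    donor_step_frames: list[int]
    acceptor_step_count: int
    acceptor_step_frames: list[int]
    fret_lifetime_frames: int
    total_intensity_cv: float
    anticorrelation_r: float
    accepted: bool = False
    rejection_reasons: list[str] = field(default_factory=list)


def noise_sigma(series: np.ndarray) -> float:
    """Robust noise SD from the median absolute first difference.

    For i.i.d. noise the first difference has SD sqrt(2)*sigma and its MAD is
    0.6745 of that, hence the 1/(0.6745*sqrt(2)) factor.  Steps and slow
    dynamics contribute only a handful of large differences and barely move
    the median.
    """
    d = np.abs(np.diff(np.asarray(series, dtype=float)))
    return float(np.median(d)) / (0.6745 * np.sqrt(2.0))


def detect_steps(
    series: np.ndarray,
    min_step_size: float = 0.0,
    penalty: float | None = None,
) -> list[tuple[int, float]]:
    """Change-point detection by penalized recursive binary segmentation.

    The cost of a segmentation is the least-squares error around
    piecewise-constant means; a split is accepted when it reduces the cost by
    more than ``penalty``.  The default penalty is the BIC-like
    ``2 * sigma^2 * log(n)`` with sigma estimated by :func:`noise_sigma`.
    Steps with |height| < ``min_step_size`` are discarded from the output.

    Returns ``[(frame, height), ...]`` in frame order, where ``frame`` is the
    first frame after the change and ``height`` the difference of the
    adjacent segment means.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("series must have at least 4 frames")
    if penalty is None:
        sigma = noise_sigma(x)
        scale = max(1.0, float(np.max(np.abs(x))))
        penalty = max(2.0 * sigma**2 * np.log(n), 1e-10 * scale**2)

    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        return c2[j] - c2[i] - (c1[j] - c1[i]) ** 2 / (j - i)

    changepoints: list[int] = []

    def recurse(i: int, j: int) -> None:
        if j - i < 2:
            return
        ks = np.arange(i + 1, j)
        left = c2[ks] - c2[i] - (c1[ks] - c1[i]) ** 2 / (ks - i)
        right = c2[j] - c2[ks] - (c1[j] - c1[ks]) ** 2 / (j - ks)
        best = int(np.argmin(left + right))
        if cost(i, j) - (left[best] + right[best]) > penalty:
            k = int(ks[best])
            changepoints.append(k)
            recurse(i, k)
            recurse(k, j)

    recurse(0, n)
    changepoints.sort()

    bounds = [0, *changepoints, n]
    means = [float(x[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    steps = [
        (cp, means[k + 1] - means[k])
        for k, cp in enumerate(changepoints)
        if abs(means[k + 1] - means[k]) >= min_step_size
    ]
    return steps


def _segment_means(x: np.ndarray, steps: list[tuple[int, float]]) -> list[float]:
    bounds = [0, *[f for f, _ in steps], len(x)]
    return [float(x[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]


def _downward_drops(
    series: np.ndarray,
    steps: list[tuple[int, float]],
    sigma: float,
) -> tuple[list[int], list[int]]:
    """All downward steps, and the subset that lands at ~background.

    Traces are background-subtracted, so a bleached channel sits near zero.
    The landing level is measured as the mean over a short window right after
    the step (not the whole following segment) so that a missed later change
    point cannot drag an intermediate level down to background; being a
    15-frame mean, its sampling SD is ~sigma/4, so a 1.5-sigma cut separates
    true background from even a weak surviving emitter.
    """
    if not steps:
        return [], []
    means = _segment_means(series, steps)
    zero_level = max(1.5 * sigma, 0.1 * max(means))
    bounds = [f for f, _ in steps] + [len(series)]
    drops = [f for f, h in steps if h < 0]
    to_background = []
    for k, (f, h) in enumerate(steps):
        if h >= 0:
            continue
        local_end = min(f + 15, bounds[k + 1])
        if float(series[f:local_end].mean()) < zero_level:
            to_background.append(f)
    return drops, to_background


def _compressed_partial_drops(
    trace: FluorTrace,
    acceptor_steps: list[tuple[int, float]],
    acceptor_to_bg: list[int],
    donor_dark: int,
    criteria: SelectionCriteria,
) -> list[int]:
    """Partial acceptor-loss events, identified by efficiency compression.

    Losing one of two FRET-coupled acceptors scales the apparent efficiency
    by the surviving acceptor's share, shrinking the lower, middle and upper
    quantiles of E together across the drop; a conformational transition
    shifts occupancy between states but leaves the level set intact, so at
    least one quantile holds its value.  Candidate change points are taken
    from the efficiency series itself (where compression is a large jump
    relative to the efficiency noise) as well as from acceptor-intensity
    drops, and are testable only with a long window on both sides -- with
    short windows the quantiles measure occupancy sampling noise, not levels.
    """
    acc_dark = acceptor_to_bg[0] if acceptor_to_bg else len(trace)
    alive = min(acc_dark, donor_dark)
    w = criteria.min_compression_window
    if alive < 2 * w:
        return []
    d = trace.donor[:alive]
    a = trace.acceptor[:alive]
    total = d + a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, a / np.maximum(total, 1e-9), np.nan)
    e = np.where(np.isfinite(e), e, 0.0)
    sigma_e = noise_sigma(e)
    steps_e = detect_steps(e, min_step_size=max(2.5 * sigma_e, 1e-6))
    bounds = [0, *[f for f, _ in steps_e], alive]
    segments = [
        (lo, hi, float(e[lo:hi].mean()))
        for lo, hi in zip(bounds[:-1], bounds[1:])
        if hi - lo >= 5
    ]
    # a compression step can hide inside a conformational transition, so a
    # coarse grid of split points backs up the detected change points
    candidates = sorted(
        {f for f, h in steps_e if h < 0}
        | {f for f, h in acceptor_steps if h < 0 and f not in acceptor_to_bg}
        | set(range(w, alive - w + 1, 10))
    )
    # Conformational states sit at level ratios of ~0.7 or higher in this
    # regime; genuine loss of one of two comparable acceptors scales E well
    # below that floor.  Three sufficient signatures, each out of reach of an
    # occupancy shift between windows:
    #   (a) a sustained post-drop level below 0.62x the lowest pre level,
    #   (b) the post upper tail (q95) below 0.62x of the pre upper tail,
    #   (c) a sustained post level below 0.85x of a *well-sampled* pre
    #       bottom level (>=30 frames), which no conformational state can
    #       undercut at all.
    flagged: list[int] = []
    strong = criteria.compression_ratio  # default 0.62: below the level-ratio floor
    for f in candidates:
        if f < w or f + w > alive:
            continue
        q50_pre, q95_pre = np.quantile(e[:f], [0.5, 0.95])
        q50_post, q95_post = np.quantile(e[f:], [0.5, 0.95])
        median_shrunk = q50_pre > 0 and q50_post < 0.92 * q50_pre
        # a segment straddling the candidate split contributes its two halves
        pre_segs = [(hi - lo, m) for lo, hi, m in segments if hi <= f]
        post_segs = [(hi - lo, m) for lo, hi, m in segments if lo >= f]
        for lo, hi, _ in segments:
            if lo < f < hi:
                if f - lo >= 5:
                    pre_segs.append((f - lo, float(e[lo:f].mean())))
                if hi - f >= 5:
                    post_segs.append((hi - f, float(e[f:hi].mean())))
        pre_levels = [m for _, m in pre_segs]
        post_levels = [m for _, m in post_segs]
        min_ratio = (
            min(post_levels) / max(min(pre_levels), 1e-9)
            if pre_levels and post_levels
            else np.inf
        )
        pre_bottom_frames = sum(
            n for n, m in pre_segs if pre_levels and m < min(pre_levels) + 0.05
        )
        # the undercut signature also caps the post-window top: with the
        # surviving share at most ~0.6, no compressed level can approach the
        # uncompressed top, whereas a window that merely missed the bottom
        # state still revisits the top
        undercut = (
            pre_bottom_frames >= 12
            and post_levels
            and min(post_levels) < 0.9 * min(pre_levels)
            and max(post_levels) < 0.9 * max(pre_levels)
        )
        if undercut or (
            median_shrunk
            and (min_ratio < strong or q95_post < strong * max(q95_pre, 1e-9))
        ):
            flagged.append(f)
    return flagged


def fret_lifetime(
    trace: FluorTrace,
    donor_steps: list[int],
    acceptor_steps: list[int],
) -> int:
    """Frames from the start until the first bleach of either dye.

    FRET is defined only while both dyes emit; a trace in which neither dye
    bleaches has a lifetime equal to its length.
    """
    candidates = [f for f in (*donor_steps, *acceptor_steps)]
    return min(candidates) if candidates else len(trace)


def total_intensity_cv(trace: FluorTrace, pre_bleach_end: int) -> float:
    """Coefficient of variation of donor+acceptor over the pre-bleach frames.

    Returns ``inf`` for degenerate traces (non-positive mean total).
    """
    if pre_bleach_end < 2:
        raise ValueError("pre_bleach_end must be >= 2")
    total = trace.total[:pre_bleach_end]
    mean = total.mean()
    if mean <= 0:
        return float("inf")
    return float(total.std() / mean)


def anticorrelation(trace: FluorTrace, pre_bleach_end: int) -> float:
    """Pearson correlation of donor vs. acceptor over the pre-bleach frames.

    Returns ``nan`` when either channel has zero variance (r undefined).
    """
    d = trace.donor[:pre_bleach_end]
    a = trace.acceptor[:pre_bleach_end]
    if len(d) < 2 or d.std() == 0 or a.std() == 0:
        return float("nan")
    return float(stats.pearsonr(d, a).statistic)


def analyze_trace(trace: FluorTrace, criteria: SelectionCriteria) -> SelectionReport:
    """Evaluate every selection criterion for one trace."""
    total = trace.total
    sigma_t = noise_sigma(total)
    sigma_a = noise_sigma(trace.acceptor)
    floor = 1e-6 * max(1.0, float(np.max(np.abs(total))))
    steps_t = detect_steps(total, min_step_size=max(criteria.min_step_sigma * sigma_t, floor))
    steps_a = detect_steps(
        trace.acceptor, min_step_size=max(criteria.min_step_sigma * sigma_a, floor)
    )
    # Donor-side losses are the downward steps of the dynamics-free total.
    donor_drops, donor_to_bg = _downward_drops(total, steps_t, sigma_t)
    acceptor_all_drops, acceptor_to_bg = _downward_drops(trace.acceptor, steps_a, sigma_a)
    donor_dark = donor_to_bg[0] if donor_to_bg else len(trace)
    partial = _compressed_partial_drops(trace, steps_a, acceptor_to_bg, donor_dark, criteria)
    acceptor_counted = sorted([*acceptor_to_bg, *partial])

    lifetime = fret_lifetime(trace, donor_to_bg, acceptor_to_bg)
    cv = total_intensity_cv(trace, max(donor_dark, 2))
    corr_end = max(lifetime, 2)
    r = anticorrelation(trace, corr_end)

    reasons: list[str] = []
    n_donor = len(donor_drops)
    n_acceptor = len(acceptor_counted)
    if n_donor != criteria.max_donor_steps or not donor_to_bg:
        reasons.append("donor_steps")
    if n_acceptor != criteria.max_acceptor_steps or not acceptor_to_bg:
        reasons.append("acceptor_steps")
    if lifetime <= criteria.min_fret_lifetime_frames:
        reasons.append("fret_lifetime")
    if not cv <= criteria.max_total_intensity_cv:
        reasons.append("total_cv")
    if (
        np.isnan(r)
        or lifetime < criteria.min_pre_bleach_frames
        or r > criteria.max_anticorrelation_r
    ):
        reasons.append("anticorrelation")

    return SelectionReport(
        trace_id=trace.trace_id,
        donor_step_count=n_donor,
        donor_step_frames=donor_drops,
        acceptor_step_count=n_acceptor,
        acceptor_step_frames=acceptor_counted,
        fret_lifetime_frames=lifetime,
        total_intensity_cv=cv,
        anticorrelation_r=r,
        accepted=not reasons,
        rejection_reasons=reasons,
    )


def apply_selection(
    traces: list[FluorTrace],
    criteria: SelectionCriteria | None = None,
) -> tuple[list[FluorTrace], list[SelectionReport]]:
    """Apply all selection criteria; returns accepted traces and full reports."""
    if not traces:
        raise ValueError("no traces to select from")
    criteria = criteria or SelectionCriteria()
    reports = [analyze_trace(t, criteria) for t in traces]
    accepted = [t for t, rep in zip(traces, reports) if rep.accepted]
    return accepted, reports
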