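"""Spot detection and aperture-photometry trace extraction from movie stacks.

Single molecules are located on a time-averaged image by local-maximum
detection against a robust (median/MAD) background estimate, refined to
sub-pixel centroids, and paired across channels by an explicit registration
transform.  Intensities are extracted by circular-aperture photometry with an
annulus-median local background, which is what makes the resulting traces
background-subtracted counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import maximum_filter

from smfretq.registration import ChannelTransform
from smfretq.traces import FluorTrace

__all__ = [
    "SpotSet",
    "ChannelTransform",
    "read_movie",
    "detect_spots",
    "pair_channels",
    "extract_traces",
]

logger = logging.getLogger(__name__)


@dataclass
class SpotSet:
    """Detected spots: sub-pixel centroids, optional paired coordinates."""

    positions: np.ndarray               # (n, 2) (y, x) in the detection channel
    scores: np.ndarray                  # peak height above background, in SD units
    paired_positions: np.ndarray | None = None  # (n, 2) in the second channel

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trace_id": [f"spot{i:04d}" for i in range(len(self))],
                "y": self.positions[:, 0],
                "x": self.positions[:, 1],
                "score": self.scores,
            }
        )
        if self.paired_positions is not None:
            df["y_paired"] = self.paired_positions[:, 0]
            df["x_paired"] = self.paired_positions[:, 1]
        return df


def read_movie(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a frames x height x width array of counts."""
    path = Path(path)
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types for bad files
        raise IOError(f"cannot read movie {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise IOError(f"movie {path} has unexpected shape {stack.shape}")
    logger.info("read %s: %d frames, %s, dtype %s", path, len(stack), stack.shape[1:], stack.dtype)
    return stack.astype(float)


def _robust_background(image: np.ndarray) -> tuple[float, float]:
    """Median background level and MAD-based SD estimate."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med, 1.4826 * mad


def detect_spots(
    stack: np.ndarray,
    n_avg_frames: int = 10,
    threshold_sd: float = 5.0,
    min_separation_px: float = 6.0,
    merge_radius_px: float = 2.5,
    centroid_window_px: int = 3,
) -> SpotSet:
    """Detect single-molecule spots on the average of the first frames.

    Local maxima exceeding background + ``threshold_sd`` robust SDs are kept.
    Noise on a broad point-spread function can split one spot into several
    nearby maxima, so maxima within ``merge_radius_px`` of a brighter one are
    suppressed first; after that, any pair of distinct spots closer than
    ``min_separation_px`` is discarded entirely (both spots), because
    overlapping apertures corrupt photometry.  Centroids are refined by
    background-subtracted intensity weighting in a small window around each
    maximum.
    """
    if not 1 <= n_avg_frames <= len(stack):
        raise ValueError("n_avg_frames must be in [1, n_frames]")
    avg = stack[:n_avg_frames].mean(axis=0)
    bg, sd = _robust_background(avg)
    if sd <= 0:
        sd = max(np.std(avg), 1e-12)
    threshold = bg + threshold_sd * sd

    is_max = avg == maximum_filter(avg, size=3, mode="nearest")
    peaks = np.argwhere(is_max & (avg > threshold))
    if len(peaks) == 0:
        return SpotSet(positions=np.empty((0, 2)), scores=np.empty(0))

    # Non-maximum suppression: keep the brightest peak in each neighbourhood.
    order = np.argsort(-avg[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(np.linalg.norm(p - q) > merge_radius_px for q in kept):
            kept.append(p)
    peaks = np.asarray(kept)

    # Discard both members of any too-close pair of distinct spots.
    if len(peaks) > 1:
        d = np.linalg.norm(peaks[:, None].astype(float) - peaks[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        peaks = peaks[d.min(axis=1) >= max(min_separation_px, merge_radius_px)]

    positions = []
    scores = []
    w = centroid_window_px  # centroid window half-size
    for py, px in peaks:
        y_lo, y_hi = max(py - w, 0), min(py + w + 1, avg.shape[0])
        x_lo, x_hi = max(px - w, 0), min(px + w + 1, avg.shape[1])
        window = np.clip(avg[y_lo:y_hi, x_lo:x_hi] - bg, 0, None)
        mass = window.sum()
        if mass <= 0:
            continue
        ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        positions.append([(ys * window).sum() / mass, (xs * window).sum() / mass])
        scores.append((avg[py, px] - bg) / sd)
    return SpotSet(positions=np.asarray(positions).reshape(-1, 2), scores=np.asarray(scores))


def pair_channels(spots: SpotSet, transform: ChannelTransform) -> SpotSet:
    """Map detection-channel centroids into the second channel."""
    paired = transform.apply(spots.positions) if len(spots) else spots.positions.copy()
    return SpotSet(positions=spots.positions, scores=spots.scores, paired_positions=paired)


def _aperture_masks(
    center: np.ndarray,
    shape: tuple[int, int],
    aperture_radius_px: float,
    annulus_radii_px: tuple[float, float],
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]] | None:
    cy, cx = center
    r_out = annulus_radii_px[1]
    if (
        cy - r_out < -0.5
        or cx - r_out < -0.5
        or cy + r_out > shape[0] - 0.5
        or cx + r_out > shape[1] - 0.5
    ):
        return None
    lo_y, hi_y = int(np.floor(cy - r_out)), int(np.ceil(cy + r_out)) + 1
    lo_x, hi_x = int(np.floor(cx - r_out)), int(np.ceil(cx + r_out)) + 1
    ys, xs = np.mgrid[max(lo_y, 0) : min(hi_y, shape[0]), max(lo_x, 0) : min(hi_x, shape[1])]
    d = np.hypot(ys - cy, xs - cx)
    ap = d <= aperture_radius_px
    ann = (d >= annulus_radii_px[0]) & (d <= annulus_radii_px[1])
    if not ap.any() or not ann.any():
        return None
    return (ys[ap], xs[ap]), (ys[ann], xs[ann])


def extract_traces(
    stack_donor: np.ndarray,
    stack_acceptor: np.ndarray,
    spots: SpotSet,
    aperture_radius_px: float = 3.0,
    annulus_radii_px: tuple[float, float] = (5.0, 8.0),
    frame_interval: float = 0.1,
    movie_id: str = "movie",
) -> list[FluorTrace]:
    """Aperture-photometry traces for each paired spot.

    Per frame and channel: sum of counts inside the aperture minus the
    annulus median times the aperture pixel count.  Spots whose annulus
    leaves the image are dropped with a warning.
    """
    if spots.paired_positions is None:
        raise ValueError("spots must be paired (run pair_channels first)")
    if stack_donor.shape != stack_acceptor.shape:
        raise ValueError("donor and acceptor stacks must have equal shape")
    traces: list[FluorTrace] = []
    shape = stack_donor.shape[1:]
    for i, (dpos, apos) in enumerate(zip(spots.positions, spots.paired_positions)):
        channels = []
        ok = True
        for stack, pos in ((stack_donor, dpos), (stack_acceptor, apos)):
            masks = _aperture_masks(pos, shape, aperture_radius_px, annulus_radii_px)
            if masks is None:
                logger.warning("spot %d at %s: aperture outside image, dropped", i, pos)
                ok = False
                break
            (ap_y, ap_x), (ann_y, ann_x) = masks
            signal = stack[:, ap_y, ap_x].sum(axis=1)
            local_bg = np.median(stack[:, ann_y, ann_x], axis=1)
            channels.append(signal - local_bg * len(ap_y))
        if ok:
            traces.append(
                FluorTrace(
                    trace_id=f"{movie_id}_spot{i:04d}",
                    donor=channels[0],
                    acceptor=channels[1],
                    frame_interval=frame_interval,
                    source={"movie": movie_id, "y": float(dpos[0]), "x": float(dpos[1])},
                )
            )
    return traces
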