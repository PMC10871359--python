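"""Rendering synthetic two-channel TIRF movies from intensity traces.

Each molecule is drawn as a pixel-integrated 2-D Gaussian point-spread
function whose integrated intensity per frame equals the trace value, on a
constant-mean background with Poisson shot noise and Gaussian read noise.
Ground-truth spot positions are kept with the movie so the extraction stage
can be tested against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.special import erf

from smfretq.registration import ChannelTransform
from smfretq.traces import FluorTrace

__all__ = ["SyntheticMovie", "render_movie"]


@dataclass
class SyntheticMovie:
    """A rendered two-channel movie plus its ground truth."""

    donor_stack: np.ndarray     # frames x height x width, photons
    acceptor_stack: np.ndarray
    donor_positions: np.ndarray     # (n_spots, 2) sub-pixel (y, x)
    acceptor_positions: np.ndarray
    psf_sigma_px: float
    transform: ChannelTransform
    background_mean: float

    @property
    def n_frames(self) -> int:
        return self.donor_stack.shape[0]

    def save(self, directory: str | Path) -> dict[str, Path]:
        """Write 16-bit TIFF stacks (one per channel) plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "donor": directory / "donor.tif",
            "acceptor": directory / "acceptor.tif",
            "truth": directory / "movie_truth.json",
        }
        for key, stack in (("donor", self.donor_stack), ("acceptor", self.acceptor_stack)):
            tifffile.imwrite(paths[key], np.clip(stack, 0, 65535).astype(np.uint16))
        paths["truth"].write_text(
            json.dumps(
                {
                    "donor_positions": self.donor_positions.tolist(),
                    "acceptor_positions": self.acceptor_positions.tolist(),
                    "psf_sigma_px": self.psf_sigma_px,
                    "transform": self.transform.to_dict(),
                    "background_mean": self.background_mean,
                },
                indent=2,
            )
        )
        return paths


def _psf_patch(y0: float, x0: float, sigma: float, shape: tuple[int, int]) -> tuple:
    """Pixel-integrated unit-mass Gaussian centred at sub-pixel (y0, x0).

    Returns the patch and its (row, col) slice into an image of ``shape``.
    """
    r = int(np.ceil(4.0 * sigma)) + 1
    cy, cx = int(round(y0)), int(round(x0))
    y_lo, y_hi = max(cy - r, 0), min(cy + r + 1, shape[0])
    x_lo, x_hi = max(cx - r, 0), min(cx + r + 1, shape[1])
    ys = np.arange(y_lo, y_hi)
    xs = np.arange(x_lo, x_hi)
    s = sigma * np.sqrt(2.0)
    wy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    wx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    return np.outer(wy, wx), (slice(y_lo, y_hi), slice(x_lo, x_hi))


def render_movie(
    traces: list[FluorTrace],
    positions: np.ndarray,
    psf_sigma_px: float = 1.2,
    image_shape: tuple[int, int] = (128, 128),
    channel_offset: ChannelTransform | None = None,
    seed: int | np.random.Generator = 0,
    background_mean: float = 100.0,
    read_noise_sd: float = 2.0,
    shot_noise: bool = True,
) -> SyntheticMovie:
    """Render traces as a two-channel movie of well-separated spots.

    ``positions`` are donor-channel sub-pixel (y, x) centres, one per trace;
    acceptor-channel positions follow from ``channel_offset``.  Spots must be
    separated by at least 4 PSF sigma (non-overlapping regime).
    """
    transform = channel_offset or ChannelTransform.identity()
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(traces) != len(positions):
        raise ValueError("need one position per trace")
    if len(positions) > 0:
        margin = 3.0 * psf_sigma_px
        for name, pos in (("donor", positions), ("acceptor", transform.apply(positions))):
            if np.any(pos < margin) or np.any(
                pos > np.asarray(image_shape, dtype=float) - 1 - margin
            ):
                raise ValueError(f"{name}-channel spot positions fall outside image bounds")
        if len(positions) > 1:
            d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 4.0 * psf_sigma_px:
                raise ValueError("spot positions closer than 4 PSF sigma")
        n_frames = {len(t) for t in traces}
        if len(n_frames) != 1:
            raise ValueError("all traces must have equal length")
        n_frames = n_frames.pop()
    else:
        n_frames = 1

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n_frames, *image_shape)
    donor_ideal = np.zeros(shape)
    acceptor_ideal = np.zeros(shape)
    acceptor_positions = transform.apply(positions) if len(positions) else positions.reshape(0, 2)
    for trace, dpos, apos in zip(traces, positions, acceptor_positions):
        for stack, series, (y0, x0) in (
            (donor_ideal, trace.donor, dpos),
            (acceptor_ideal, trace.acceptor, apos),
        ):
            patch, sl = _psf_patch(y0, x0, psf_sigma_px, image_shape)
            stack[(slice(None), *sl)] += np.clip(series, 0, None)[:, None, None] * patch

    stacks = []
    for ideal in (donor_ideal, acceptor_ideal):
        img = ideal + background_mean
        if shot_noise:
            img = rng.poisson(img).astype(float)
        if read_noise_sd > 0:
            img = img + rng.normal(0.0, read_noise_sd, img.shape)
        stacks.append(img)

    return SyntheticMovie(
        donor_stack=stacks[0],
        acceptor_stack=stacks[1],
        donor_positions=positions,
        acceptor_positions=acceptor_positions,
        psf_sigma_px=psf_sigma_px,
        transform=transform,
        background_mean=background_mean,
    )
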