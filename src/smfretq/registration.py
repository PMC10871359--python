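"""Donor/acceptor channel registration transforms.

Coordinates are 0-based (row, col) with pixel centers at integer coordinates.
The transform maps donor-channel coordinates to acceptor-channel coordinates;
it is supplied explicitly (identity, translation, or an affine solved from
fiducial pairs) -- there is no automatic registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelTransform"]


@dataclass(frozen=True)
class ChannelTransform:
    """Affine map ``yx -> yx @ matrix.T + offset`` between channels."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        o = np.asarray(self.offset, dtype=float)
        if m.shape != (2, 2) or o.shape != (2,):
            raise ValueError("matrix must be 2x2 and offset length-2")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(o))):
            raise ValueError("transform parameters must be finite")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", o)

    def apply(self, yx: np.ndarray) -> np.ndarray:
        yx = np.atleast_2d(np.asarray(yx, dtype=float))
        return yx @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls()

    @classmethod
    def translation(cls, dy: float, dx: float) -> "ChannelTransform":
        return cls(offset=np.array([dy, dx], dtype=float))

    @classmethod
    def from_fiducials(cls, donor_yx: np.ndarray, acceptor_yx: np.ndarray) -> "ChannelTransform":
        """Least-squares affine from matched fiducial coordinate pairs.

        Three non-collinear pairs determine the 6 parameters exactly; more
        pairs are fit in the least-squares sense.
        """
        src = np.atleast_2d(np.asarray(donor_yx, dtype=float))
        dst = np.atleast_2d(np.asarray(acceptor_yx, dtype=float))
        if src.shape != dst.shape or src.shape[0] < 3:
            raise ValueError("need >= 3 matched fiducial pairs of equal shape")
        a = np.hstack([src, np.ones((len(src), 1))])
        sol, *_ = np.linalg.lstsq(a, dst, rcond=None)  # (3, 2)
        return cls(matrix=sol[:2].T, offset=sol[2])

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "offset": self.offset.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelTransform":
        return cls(matrix=np.asarray(d["matrix"]), offset=np.asarray(d["offset"]))
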