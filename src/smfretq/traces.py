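"""Donor/acceptor intensity traces and their columnar text format.

Traces are stored as tab-separated text, one row per (trace, frame), with a
two-line header carrying the schema version and the frame interval.  The
format round-trips at full double precision and is trivially readable from
any language.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FluorTrace", "write_traces", "read_traces", "TRACE_SCHEMA_VERSION"]

TRACE_SCHEMA_VERSION = 1

_MAGIC = "# smfretq-traces"
_COLUMNS = ["trace_id", "frame", "donor", "acceptor"]


@dataclass
class FluorTrace:
    """A paired donor/acceptor intensity time series for one molecule.

    Intensities are background-subtracted counts per frame.  ``donor`` and
    ``acceptor`` always have the same length.
    """

    trace_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D")
        if len(self.donor) != len(self.acceptor):
            raise ValueError("donor and acceptor must have equal length")
        if len(self.donor) < 1:
            raise ValueError("trace must contain at least one frame")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


def write_traces(traces: list[FluorTrace], path: str | Path) -> None:
    """Write a trace set as tab-separated text (see module docstring)."""
    path = Path(path)
    if traces:
        dt = {t.frame_interval for t in traces}
        if len(dt) != 1:
            raise ValueError("all traces in one file must share frame_interval")
        frame_interval = dt.pop()
    else:
        frame_interval = 0.1
    buf = io.StringIO()
    buf.write(f"{_MAGIC} v{TRACE_SCHEMA_VERSION}\n")
    buf.write(f"# frame_interval={frame_interval!r}\n")
    buf.write("\t".join(_COLUMNS) + "\n")
    for t in traces:
        for f in range(len(t)):
            buf.write(f"{t.trace_id}\t{f}\t{float(t.donor[f])!r}\t{float(t.acceptor[f])!r}\n")
    path.write_text(buf.getvalue())


def read_traces(path: str | Path) -> list[FluorTrace]:
    """Read a trace set written by :func:`write_traces`.

    Raises
    ------
    ValueError
        If the header magic/version or the column schema does not match.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_MAGIC):
            raise ValueError(f"{path}: line 1: not an smfretq trace file: {first!r}")
        version = first.removeprefix(_MAGIC).strip()
        if version != f"v{TRACE_SCHEMA_VERSION}":
            raise ValueError(f"{path}: line 1: unsupported schema version {version!r}")
        second = fh.readline().rstrip("\n")
        if not second.startswith("# frame_interval="):
            raise ValueError(f"{path}: line 2: missing frame_interval header: {second!r}")
        frame_interval = float(second.split("=", 1)[1])
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise ValueError(f"{path}: line 3: bad column header {header!r}")
        df = pd.read_csv(
            fh,
            sep="\t",
            names=_COLUMNS,
            dtype={"trace_id": str, "frame": np.int64, "donor": float, "acceptor": float},
            float_precision="round_trip",
        )
    traces: list[FluorTrace] = []
    if df.empty:
        return traces
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        if not np.array_equal(grp["frame"].to_numpy(), np.arange(len(grp))):
            raise ValueError(f"{path}: trace {tid!r}: frame indices not contiguous from 0")
        traces.append(
            FluorTrace(
                trace_id=str(tid),
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
                frame_interval=frame_interval,
            )
        )
    return traces
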