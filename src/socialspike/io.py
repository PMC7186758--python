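"""Reading, writing and binning of tracking and spike data.

The behavioral clock is the video frame clock (10 frames/s by default); spikes
are binned into 100 ms bins aligned with it.  File formats are deliberately
plain: a tracking CSV with one row per (frame, bee) and a spike file with one
ascending spike time (seconds) per line.  All readers transparently accept
gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["frame", "time_s", "bee_id", "x_cm", "y_cm", "theta_deg"]

FOCAL_ID = "focal"


class TrackFormatError(ValueError):
    """Malformed tracking table (missing columns, duplicates, gaps)."""


class SpikeFormatError(ValueError):
    """Malformed spike file (non-numeric or unsorted times)."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class TrackTable:
    """Per-frame positions and long-body-axis angles for all tracked bees.

    ``data`` has columns frame (0-based int), time_s, bee_id, x_cm, y_cm,
    theta_deg in [0, 360).  Bees may be absent from individual frames
    (tracker dropouts); frames present for a given bee must be consecutive
    within its tracked span only in the sense of strictly increasing.
    """

    data: pd.DataFrame
    frame_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrackFormatError(f"tracking table missing columns: {missing}")
        df = self.data
        dup = df.duplicated(subset=["frame", "bee_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise TrackFormatError(
                f"duplicate (frame, bee_id) record at row {row}: "
                f"frame={df.iloc[row]['frame']}, bee_id={df.iloc[row]['bee_id']}"
            )
        for bee, grp in df.groupby("bee_id", sort=False):
            f = grp["frame"].to_numpy()
            if np.any(np.diff(f) <= 0):
                bad = int(np.flatnonzero(np.diff(f) <= 0)[0])
                raise TrackFormatError(
                    f"non-monotone frames for bee {bee!r} near frame {f[bad]}"
                )
        theta = df["theta_deg"].to_numpy(dtype=float)
        if np.any((theta < 0) | (theta >= 360)):
            raise TrackFormatError("theta_deg must lie in [0, 360)")

    @property
    def bee_ids(self) -> list[str]:
        return sorted(self.data["bee_id"].unique().tolist())

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].max()) + 1 if len(self.data) else 0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def bee(self, bee_id: str) -> pd.DataFrame:
        """Rows for one bee, indexed by frame."""
        sub = self.data[self.data["bee_id"] == bee_id]
        return sub.set_index("frame").sort_index()

    def check_bounds(self, width_cm: float, height_cm: float) -> None:
        """Warn (not fail) if any position falls outside the arena."""
        x = self.data["x_cm"].to_numpy()
        y = self.data["y_cm"].to_numpy()
        n_out = int(np.sum((x < 0) | (x > width_cm) | (y < 0) | (y > height_cm)))
        if n_out:
            warnings.warn(
                f"{n_out} tracked positions outside the {width_cm}x{height_cm} cm arena",
                stacklevel=2,
            )


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of a single extracellularly recorded unit."""

    times: np.ndarray
    unit: str = "unit1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise SpikeFormatError("spike times must be a 1-d array")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            bad = int(np.flatnonzero(np.diff(self.times) < 0)[0])
            raise SpikeFormatError(
                f"spike times not sorted: t[{bad + 1}]={self.times[bad + 1]} "
                f"< t[{bad}]={self.times[bad]}"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RateSeries:
    """Spike counts/rates on the behavioral clock.

    Bins are half-open ``[t, t + bin_w)`` with left-edge timestamps.
    """

    edges: np.ndarray  # left edges, s
    counts: np.ndarray  # spikes per bin
    bin_w: float = 0.1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.edges) != len(self.counts):
            raise ValueError("edges and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("negative spike count")

    @property
    def rates(self) -> np.ndarray:
        """Rate per bin in Hz (count / bin width)."""
        return self.counts / self.bin_w

    def __len__(self) -> int:
        return len(self.counts)

    def index_of(self, t: float) -> int:
        """Index of the bin containing time ``t``."""
        i = int(np.floor((t - self.edges[0]) / self.bin_w + 1e-9))
        if not 0 <= i < len(self.counts):
            raise IndexError(f"time {t} s outside the binned span")
        return i


def read_tracks(path, frame_rate_hz: float = 10.0) -> TrackTable:
    """Read a tracking CSV (optionally .gz) into a validated :class:`TrackTable`."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, dtype={"bee_id": str}, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    return TrackTable(df[TRACK_COLUMNS].copy(), frame_rate_hz=frame_rate_hz)


def write_tracks(table: TrackTable, path) -> None:
    # shortest-roundtrip float repr: read(write(x)) == x exactly
    with _open_text(path, "wt") as fh:
        table.data.to_csv(fh, index=False, lineterminator="\n")


def read_spikes(path, unit: str = "unit1") -> SpikeTrain:
    """Read one spike time (s) per line; the file must already be sorted.

    Unsorted input is rejected rather than silently reordered: ordering is the
    spike sorter's contract, and reordering here would mask upstream bugs.
    """
    times = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                times.append(float(line))
            except ValueError as exc:
                raise SpikeFormatError(f"{path}:{lineno}: non-numeric spike time {line!r}") from exc
    arr = np.array(times, dtype=float)
    if len(arr) > 1 and np.any(np.diff(arr) < 0):
        bad = int(np.flatnonzero(np.diff(arr) < 0)[0])
        raise SpikeFormatError(f"{path}: spike times not sorted at line {bad + 2}")
    return SpikeTrain(arr, unit=unit)


def write_spikes(train: SpikeTrain, path) -> None:
    with _open_text(path, "wt") as fh:
        for t in train.times:
            fh.write(f"{float(t)!r}\n")


def bin_spikes(train: SpikeTrain, t0: float, t1: float, bin_w: float = 0.1) -> RateSeries:
    """Count spikes in half-open 100 ms bins aligned to ``t0``.

    Only whole bins are kept: a final partial bin is dropped.  A spike exactly
    on a bin edge belongs to the right-hand bin (half-open convention).
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    if bin_w <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.floor((t1 - t0) / bin_w + 1e-9))
    edges = t0 + bin_w * np.arange(n_bins + 1)
    counts, _ = np.histogram(train.times, bins=edges)
    # np.histogram closes the last bin on the right; drop spikes exactly at the
    # final edge to keep every bin half-open.
    if n_bins and np.any(train.times == edges[-1]):
        counts[-1] -= int(np.sum(train.times == edges[-1]))
    return RateSeries(edges[:-1], counts, bin_w=bin_w)
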