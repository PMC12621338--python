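"""Time-bin synchronization of the two asynchronous device streams.

The devices start asynchronously and occasionally miss samples.  Both
streams are mapped onto a shared 100 ms grid anchored at the recording
epoch (``t = 0``): bin *k* covers ``[k*w, (k+1)*w)`` ms and retains the
most recent sample strictly before the bin boundary.  The aligned
12-channel series is then cut into fixed 30-frame (3 s) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kneeadl.stream_io import ImuStream

DEFAULT_BIN_MS = 100
WINDOW_FRAMES = 30
N_CHANNELS = 12


class AlignmentError(ValueError):
    """Raised when the two binned streams share no common range."""


@dataclass
class BinnedStream:
    """Per-bin retained samples of one device.

    ``values`` covers the occupied range ``[start_bin, start_bin + n)``;
    rows of bins containing no sample are NaN with ``occupied`` False.
    """

    device_id: str
    bin_width: int
    start_bin: int
    values: np.ndarray      # (n_bins, 6) float, NaN where empty
    occupied: np.ndarray    # (n_bins,) bool

    @property
    def end_bin(self) -> int:
        """One past the last bin in range."""
        return self.start_bin + len(self.values)


def bin_stream(stream: ImuStream, bin_width: int = DEFAULT_BIN_MS) -> BinnedStream:
    """Assign each sample to its time bin, keeping the latest per bin.

    Bin ``k`` spans ``[k*bin_width, (k+1)*bin_width)``; a sample at
    exactly the boundary belongs to the next bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(stream) == 0:
        raise ValueError("cannot bin an empty stream")
    idx = stream.t_ms // bin_width
    first, last = int(idx[0]), int(idx[-1])
    n = last - first + 1
    values = np.full((n, 6), np.nan)
    occupied = np.zeros(n, dtype=bool)
    chans = np.hstack([stream.accel, stream.gyro])
    # timestamps are strictly increasing, so later rows overwrite:
    # the retained sample is the one with the largest t in the bin
    values[idx - first] = chans
    occupied[idx - first] = True
    return BinnedStream(stream.device_id, int(bin_width), first, values, occupied)


@dataclass
class AlignedSeries:
    """A gap-filled, contiguous run of 12-channel frames.

    Channels 0-5 are femoral (ax, ay, az, gx, gy, gz) and 6-11 tibial,
    always.  ``fill_mask[i, d]`` is True where device ``d`` (0 femoral,
    1 tibial) had no sample in bin ``start_bin + i`` and the previous
    retained sample was carried forward.
    """

    bin_width: int
    start_bin: int
    frames: np.ndarray      # (n, 12) float, all finite
    fill_mask: np.ndarray   # (n, 2) bool
    recording_id: str = ""

    def __len__(self) -> int:
        return len(self.frames)


def align_dual(
    femoral: BinnedStream,
    tibial: BinnedStream,
    max_gap: int = 3,
) -> list[AlignedSeries]:
    """Merge the two binned streams over their common bin range.

    Within the intersection of the two occupied ranges, an empty bin on
    either device is filled by carrying that device's previous retained
    sample forward; a run of more than ``max_gap`` consecutive empty
    bins on either device splits the output into separate segments.
    """
    if femoral.bin_width != tibial.bin_width:
        raise ValueError("bin widths differ between devices")
    lo = max(femoral.start_bin, tibial.start_bin)
    hi = min(femoral.end_bin, tibial.end_bin)   # exclusive
    if lo >= hi:
        raise AlignmentError(
            f"no overlapping bins: femoral range "
            f"[{femoral.start_bin}, {femoral.end_bin}) vs tibial "
            f"[{tibial.start_bin}, {tibial.end_bin})"
        )
    n = hi - lo
    frames = np.empty((n, N_CHANNELS))
    fill_mask = np.zeros((n, 2), dtype=bool)
    valid = np.ones(n, dtype=bool)

    for d, dev in enumerate((femoral, tibial)):
        off = lo - dev.start_bin
        occ = dev.occupied
        # index of the most recent occupied bin at or before each position
        last_occ = np.where(occ, np.arange(len(occ)), -1)
        last_occ = np.maximum.accumulate(last_occ)
        sel = last_occ[off:off + n]
        # sel >= 0 always: lo is >= the device's first occupied bin
        frames[:, 6 * d:6 * d + 6] = dev.values[sel]
        filled = ~occ[off:off + n]
        fill_mask[:, d] = filled
        # gap distance from the carried-forward source sample
        gap = (np.arange(off, off + n) - sel)
        valid &= gap <= max_gap

    segments: list[AlignedSeries] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        segments.append(
            AlignedSeries(
                bin_width=femoral.bin_width,
                start_bin=lo + i,
                frames=frames[i:j].copy(),
                fill_mask=fill_mask[i:j].copy(),
            )
        )
        i = j
    return segments


@dataclass
class Window:
    """A fixed-length slice of the aligned series with its label."""

    frames: np.ndarray          # (length, 12)
    label: str | None = None
    recording_id: str = ""
    start_bin: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[1] != N_CHANNELS:
            raise ValueError(
                f"window frames must be (length, {N_CHANNELS}), "
                f"got {self.frames.shape}"
            )

    @property
    def length(self) -> int:
        return self.frames.shape[0]


def cut_windows(
    series: AlignedSeries,
    length: int = WINDOW_FRAMES,
    stride: int | None = None,
    label: str | None = None,
) -> list[Window]:
    """Cut the maximal set of full windows starting at stride multiples.

    A series shorter than ``length`` yields an empty list.  Trailing
    partial windows are discarded.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    stride = length if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(series)
    windows = []
    for start in range(0, n - length + 1, stride):
        windows.append(
            Window(
                frames=series.frames[start:start + length].copy(),
                label=label,
                recording_id=series.recording_id,
                start_bin=series.start_bin + start,
            )
        )
    return windows
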