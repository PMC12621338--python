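"""Reading and writing IMU stream CSVs, dataset manifests, and windowed datasets.

Stream CSV dialect (one file per device per recording)::

    device_id,t_ms,ax_mps2,ay_mps2,az_mps2,gx_dps,gy_dps,gz_dps

``t_ms`` is integer milliseconds since the recording epoch and must be
strictly increasing.  Channel values are written with fixed 6-decimal
formatting so identical streams produce identical bytes.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from kneeadl.activities import ACTIVITY_LABELS

logger = logging.getLogger(__name__)

STREAM_COLUMNS = (
    "device_id", "t_ms",
    "ax_mps2", "ay_mps2", "az_mps2",
    "gx_dps", "gy_dps", "gz_dps",
)

DEVICE_IDS = ("femoral", "tibial")


class StreamFormatError(ValueError):
    """Raised when a stream CSV does not match the expected dialect."""


class StreamValidationError(ValueError):
    """Raised when parsed stream content violates an invariant."""


class ManifestError(ValueError):
    """Raised for malformed dataset manifests."""


class ImuSample(NamedTuple):
    """One timestamped 6-channel reading."""

    t: int                # ms since stream epoch
    accel: np.ndarray     # (3,) m/s^2
    gyro: np.ndarray      # (3,) deg/s


@dataclass
class ImuStream:
    """One device's ordered 6-channel readings.

    Attributes
    ----------
    device_id
        ``"femoral"`` or ``"tibial"``.
    t_ms
        Integer timestamps, strictly increasing.
    accel, gyro
        ``(n, 3)`` arrays in m/s^2 and deg/s.
    """

    device_id: str
    t_ms: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        if self.device_id not in DEVICE_IDS:
            raise StreamValidationError(
                f"device_id must be one of {DEVICE_IDS}, got {self.device_id!r}"
            )
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.accel = np.asarray(self.accel, dtype=np.float64).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=np.float64).reshape(-1, 3)
        n = len(self.t_ms)
        if len(self.accel) != n or len(self.gyro) != n:
            raise StreamValidationError("t_ms, accel and gyro lengths differ")
        if n > 1:
            bad = np.nonzero(np.diff(self.t_ms) <= 0)[0]
            if bad.size:
                raise StreamValidationError(
                    f"timestamps not strictly increasing at row {int(bad[0]) + 1} "
                    f"(t={int(self.t_ms[bad[0] + 1])} after t={int(self.t_ms[bad[0]])})"
                )
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise StreamValidationError("non-finite channel values in stream")

    def __len__(self) -> int:
        return len(self.t_ms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImuStream):
            return NotImplemented
        return (
            self.device_id == other.device_id
            and np.array_equal(self.t_ms, other.t_ms)
            and np.array_equal(self.accel, other.accel)
            and np.array_equal(self.gyro, other.gyro)
        )

    @property
    def samples(self) -> Iterator[ImuSample]:
        for i in range(len(self)):
            yield ImuSample(int(self.t_ms[i]), self.accel[i], self.gyro[i])


def write_stream(stream: ImuStream, path: str | Path) -> None:
    """Write a stream to CSV with deterministic 6-decimal formatting."""
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            fh.write(",".join(STREAM_COLUMNS) + "\n")
            for i in range(len(stream)):
                vals = [f"{v:.6f}" for v in (*stream.accel[i], *stream.gyro[i])]
                fh.write(f"{stream.device_id},{int(stream.t_ms[i])}," + ",".join(vals) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write stream to {path}: {exc}") from exc


def read_stream(path: str | Path) -> ImuStream:
    """Parse a stream CSV, rejecting malformed rows.

    Rows containing non-finite channel values are dropped (count
    logged); non-monotone timestamps raise :class:`StreamValidationError`
    naming the first offending row.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StreamFormatError(f"{path}: empty file, expected header") from None
        header = [h.strip() for h in header]
        if tuple(header) != STREAM_COLUMNS:
            missing = set(STREAM_COLUMNS) - set(header)
            raise StreamFormatError(
                f"{path}: bad header {header!r}"
                + (f", missing columns {sorted(missing)}" if missing else "")
            )
        device_id = None
        t_list: list[int] = []
        chans: list[list[float]] = []
        n_rejected = 0
        for rownum, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # tolerate trailing blank line
            if len(row) != len(STREAM_COLUMNS):
                raise StreamFormatError(
                    f"{path}: row {rownum} has {len(row)} fields, expected "
                    f"{len(STREAM_COLUMNS)}"
                )
            if device_id is None:
                device_id = row[0]
            try:
                t = int(row[1])
                values = [float(v) for v in row[2:8]]
            except ValueError as exc:
                raise StreamFormatError(f"{path}: row {rownum}: {exc}") from None
            if not all(math.isfinite(v) for v in values):
                n_rejected += 1
                continue
            if t_list and t <= t_list[-1]:
                raise StreamValidationError(
                    f"{path}: row {rownum}: timestamp {t} not after previous "
                    f"{t_list[-1]}"
                )
            t_list.append(t)
            chans.append(values)
    if n_rejected:
        logger.info("read_stream(%s): rejected %d rows with non-finite values",
                    path, n_rejected)
    if device_id is None:
        device_id = "femoral"
    arr = np.asarray(chans, dtype=np.float64).reshape(-1, 6)
    return ImuStream(
        device_id=device_id,
        t_ms=np.asarray(t_list, dtype=np.int64),
        accel=arr[:, :3],
        gyro=arr[:, 3:],
    )


# ---------------------------------------------------------------------------
# Dataset manifests


@dataclass
class RecordingEntry:
    recording_id: str
    activity: str
    femoral_csv: str
    tibial_csv: str
    reps: int = 1

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_LABELS:
            raise ManifestError(
                f"unknown activity {self.activity!r}; allowed labels: "
                f"{', '.join(ACTIVITY_LABELS)}"
            )


@dataclass
class DatasetManifest:
    recordings: list[RecordingEntry] = field(default_factory=list)
    root: Path | None = None  # directory paths are resolved against

    def resolve(self, rel: str) -> Path:
        return (self.root / rel) if self.root is not None else Path(rel)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "recordings": [
            {
                "recording_id": r.recording_id,
                "activity": r.activity,
                "femoral_csv": r.femoral_csv,
                "tibial_csv": r.tibial_csv,
                "reps": r.reps,
            }
            for r in manifest.recordings
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_manifest(path: str | Path, check_files: bool = True) -> DatasetManifest:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "recordings" not in payload:
        raise ManifestError(f"{path}: expected an object with a 'recordings' list")
    entries = []
    for rec in payload["recordings"]:
        entry = RecordingEntry(
            recording_id=str(rec["recording_id"]),
            activity=str(rec["activity"]),
            femoral_csv=str(rec["femoral_csv"]),
            tibial_csv=str(rec["tibial_csv"]),
            reps=int(rec.get("reps", 1)),
        )
        entries.append(entry)
    manifest = DatasetManifest(recordings=entries, root=path.parent)
    if check_files:
        for entry in entries:
            for rel in (entry.femoral_csv, entry.tibial_csv):
                if not manifest.resolve(rel).exists():
                    raise ManifestError(f"{path}: referenced file missing: {rel}")
    return manifest


# ---------------------------------------------------------------------------
# Windowed dataset container


@dataclass
class WindowedDataset:
    """Array container for the model-ready dataset.

    ``windows`` is ``(N, 30, 12)`` time-domain input, ``spectrograms``
    ``(N, 8, 8, 12)``, ``labels`` ``(N,)`` integer class indices into
    ``label_names``, and ``groups`` ``(N,)`` recording ids (strings) for
    leakage-safe splitting.
    """

    windows: np.ndarray
    spectrograms: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    label_names: tuple[str, ...] = ACTIVITY_LABELS
    params: dict | None = None

    def __len__(self) -> int:
        return len(self.labels)


def save_windows(dataset: WindowedDataset, path: str | Path) -> None:
    """Save to an ``.npz`` container plus a JSON parameter sidecar."""
    path = Path(path)
    np.savez(
        path,
        windows=dataset.windows.astype(np.float32),
        spectrograms=dataset.spectrograms.astype(np.float32),
        labels=dataset.labels.astype(np.int64),
        groups=np.asarray(dataset.groups, dtype=np.str_),
        label_names=np.asarray(dataset.label_names, dtype=np.str_),
    )
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(dataset.params or {}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_windows(path: str | Path) -> WindowedDataset:
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        params = None
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                params = json.load(fh)
        return WindowedDataset(
            windows=data["windows"],
            spectrograms=data["spectrograms"],
            labels=data["labels"],
            groups=data["groups"],
            label_names=tuple(data["label_names"]),
            params=params,
        )
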