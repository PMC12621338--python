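"""End-to-end orchestration: simulate -> sync -> filter -> features ->
train -> evaluate."""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy

from kneeadl.activities import ACTIVITY_LABELS, default_profiles
from kneeadl.config import PipelineConfig
from kneeadl.filters import preprocess_segment, preprocess_window
from kneeadl.metrics import EvalReport, evaluate_predictions, split_dataset, write_report
from kneeadl.model import (
    TrainedModel,
    build_model,
    save_model,
    train_model,
)
from kneeadl.simulate import generate_dataset
from kneeadl.spectrogram import ChannelScaler, spectrogram_tensor
from kneeadl.stream_io import (
    DatasetManifest,
    WindowedDataset,
    read_stream,
    save_windows,
)
from kneeadl.sync import align_dual, bin_stream, cut_windows
from kneeadl.version import __version__

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def prepare_dataset(
    manifest: DatasetManifest,
    config: PipelineConfig,
) -> WindowedDataset:
    """Turn raw dual streams into model-ready windows and tensors."""
    sync_cfg = config.sync
    filt = config.filters
    windows_list, tensors_list, labels, groups = [], [], [], []
    n_filled = 0
    for entry in manifest.recordings:
        fem = read_stream(manifest.resolve(entry.femoral_csv))
        tib = read_stream(manifest.resolve(entry.tibial_csv))
        fem_bins = bin_stream(fem, sync_cfg.bin_ms)
        tib_bins = bin_stream(tib, sync_cfg.bin_ms)
        segments = align_dual(fem_bins, tib_bins, max_gap=sync_cfg.max_gap)
        for segment in segments:
            segment.recording_id = entry.recording_id
            n_filled += int(segment.fill_mask.sum())
            if filt.per_window:
                raw_windows = cut_windows(segment, sync_cfg.window_frames,
                                          sync_cfg.stride, label=entry.activity)
                wins = [preprocess_window(w, filt.accel, filt.gyro)
                        for w in raw_windows]
                raw_for_spec = raw_windows if filt.spectrogram_from_raw else wins
            else:
                if len(segment) >= 3 * max(filt.accel.order, filt.gyro.order):
                    filtered = preprocess_segment(segment, filt.accel, filt.gyro)
                else:
                    continue
                wins = cut_windows(filtered, sync_cfg.window_frames,
                                   sync_cfg.stride, label=entry.activity)
                if filt.spectrogram_from_raw:
                    raw_for_spec = cut_windows(segment, sync_cfg.window_frames,
                                               sync_cfg.stride,
                                               label=entry.activity)
                else:
                    raw_for_spec = wins
            for w, ws in zip(wins, raw_for_spec):
                windows_list.append(w.frames)
                tensors_list.append(spectrogram_tensor(ws, config.features).values)
                labels.append(ACTIVITY_LABELS.index(entry.activity))
                groups.append(entry.recording_id)
    logger.info("prepare: %d recordings -> %d windows (%d bins gap-filled)",
                len(manifest.recordings), len(labels), n_filled)
    if not labels:
        raise PipelineError("prepare", "no windows produced from manifest")
    return WindowedDataset(
        windows=np.stack(windows_list).astype(np.float32),
        spectrograms=np.stack(tensors_list).astype(np.float32),
        labels=np.asarray(labels, dtype=np.int64),
        groups=np.asarray(groups, dtype=np.str_),
        label_names=ACTIVITY_LABELS,
        params={
            "bin_ms": sync_cfg.bin_ms,
            "window_frames": sync_cfg.window_frames,
            "stride": sync_cfg.stride,
            "max_gap": sync_cfg.max_gap,
            "stft": config.features.to_dict(),
            "accel_filter": vars(config.filters.accel).copy(),
            "gyro_filter": vars(config.filters.gyro).copy(),
        },
    )


def _restrict_classes(dataset: WindowedDataset,
                      classes: tuple[str, ...]) -> WindowedDataset:
    keep_idx = [ACTIVITY_LABELS.index(c) for c in classes]
    mask = np.isin(dataset.labels, keep_idx)
    remap = {old: new for new, old in enumerate(keep_idx)}
    labels = np.array([remap[int(v)] for v in dataset.labels[mask]],
                      dtype=np.int64)
    return WindowedDataset(
        windows=dataset.windows[mask],
        spectrograms=dataset.spectrograms[mask],
        labels=labels,
        groups=dataset.groups[mask],
        label_names=tuple(classes),
        params=dataset.params,
    )


@dataclass
class BenchmarkResult:
    report: EvalReport
    trained: TrainedModel
    dataset: WindowedDataset
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    elapsed_s: float


def train_on_dataset(
    dataset: WindowedDataset,
    config: PipelineConfig,
    verbose: bool = False,
) -> tuple[TrainedModel, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Split, normalize with training statistics, and train the model."""
    tr, va, te = split_dataset(dataset.labels, config.split,
                               groups=dataset.groups)
    logger.info("split: train=%d val=%d test=%d", len(tr), len(va), len(te))
    win_scaler = ChannelScaler().fit(dataset.windows[tr])
    ten_scaler = ChannelScaler().fit(dataset.spectrograms[tr])
    xw = win_scaler.transform(dataset.windows).astype(np.float32)
    xs = ten_scaler.transform(dataset.spectrograms).astype(np.float32)
    model = build_model(config.model)
    history = train_model(
        model,
        xw[tr], xs[tr], dataset.labels[tr],
        xw[va], xs[va], dataset.labels[va],
        verbose=verbose,
    )
    trained = TrainedModel(
        model=model,
        window_scaler=win_scaler,
        tensor_scaler=ten_scaler,
        label_names=dataset.label_names,
        history=history,
    )
    return trained, (tr, va, te)


def run_benchmark(
    config: PipelineConfig,
    out_dir: str | Path,
    verbose: bool = False,
    keep_dataset: bool = True,
) -> BenchmarkResult:
    """Full reproduction harness; writes dataset, model, report, provenance."""
    t_start = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        manifest = generate_dataset(config.simulate,
                                    default_profiles(),
                                    out / "streams")
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    logger.info("simulate: %d recordings", len(manifest.recordings))

    try:
        dataset = prepare_dataset(manifest, config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("prepare", str(exc)) from exc
    if config.classes:
        dataset = _restrict_classes(dataset, config.classes)
    if keep_dataset:
        save_windows(dataset, out / "windows.npz")

    try:
        trained, (tr, va, te) = train_on_dataset(dataset, config,
                                                 verbose=verbose)
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc
    save_model(trained, out / "model")

    try:
        predicted = trained.classify(dataset.windows[te],
                                     dataset.spectrograms[te])
        report = evaluate_predictions(dataset.labels[te], predicted,
                                      dataset.label_names)
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    write_report(report, out / "report")

    elapsed = time.perf_counter() - t_start
    provenance = {
        "package_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": config.stage_seeds(),
        "split_sizes": {"train": len(tr), "val": len(va), "test": len(te)},
        "n_windows": len(dataset),
        "elapsed_s": elapsed,
        "best_epoch": trained.history.best_epoch if trained.history else None,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("benchmark: accuracy=%.4f macro_f1=%.4f (%.1fs)",
                report.accuracy, report.macro["f1"], elapsed)
    return BenchmarkResult(report, trained, dataset, (tr, va, te), elapsed)
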