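"""Time-frequency features: 8x8 spectrogram images per channel.

Each filtered 30-frame window is converted to a stack of twelve 8x8
power images (one per channel): short-time Fourier transform with
segment length 8, hop 3, zero-padded transform length 14, Hann taper,
one-sided spectrum, then ``log(1 + power)`` scaling.

Shape arithmetic: ``floor((30 - 8) / 3) + 1 = 8`` time frames and
``14 / 2 + 1 = 8`` one-sided frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from kneeadl.sync import Window


@dataclass(frozen=True)
class StftParams:
    segment_length: int = 8
    hop: int = 3
    transform_length: int = 14
    scaling: str = "log1p"

    @property
    def n_freq(self) -> int:
        return self.transform_length // 2 + 1

    def n_time(self, series_length: int) -> int:
        return (series_length - self.segment_length) // self.hop + 1

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_STFT = StftParams()


@dataclass
class SpectrogramTensor:
    """8 (frequency) x 8 (time) x 12 (channel) log-power stack."""

    values: np.ndarray
    params: StftParams = DEFAULT_STFT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("spectrogram tensor contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def spectrogram_channel(series: np.ndarray,
                        params: StftParams = DEFAULT_STFT) -> np.ndarray:
    """One channel's STFT power image, frequency bins x time frames."""
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.shape[0] < params.segment_length:
        raise ValueError(
            f"series length {x.shape[0]} shorter than segment length "
            f"{params.segment_length}"
        )
    segments = sliding_window_view(x, params.segment_length)[::params.hop]
    taper = hann(params.segment_length, sym=False)
    spectrum = np.fft.rfft(segments * taper, n=params.transform_length, axis=1)
    power = np.abs(spectrum) ** 2
    if params.scaling == "log1p":
        power = np.log1p(power)
    elif params.scaling != "none":
        raise ValueError(f"unknown scaling {params.scaling!r}")
    return power.T  # (n_freq, n_time)


def spectrogram_tensor(window: Window,
                       params: StftParams = DEFAULT_STFT) -> SpectrogramTensor:
    """Stack the 12 per-channel images in fixed channel order."""
    frames = window.frames
    images = [spectrogram_channel(frames[:, c], params)
              for c in range(frames.shape[1])]
    return SpectrogramTensor(values=np.stack(images, axis=-1), params=params)


class ChannelScaler:
    """Per-channel standardization with training-set statistics only.

    Works on any array whose last axis is the channel axis (windows
    ``(N, 30, 12)`` or tensors ``(N, 8, 8, 12)``).  Channels with zero
    variance get an sd floor of 1e-8, so a constant channel maps to 0.
    """

    SD_FLOOR = 1e-8

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, data: np.ndarray) -> "ChannelScaler":
        data = np.asarray(data, dtype=np.float64)
        axes = tuple(range(data.ndim - 1))
        self.mean_ = data.mean(axis=axes)
        self.sd_ = np.maximum(data.std(axis=axes), self.SD_FLOOR)
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler not fitted; compute training statistics first")
        return (np.asarray(data, dtype=np.float64) - self.mean_) / self.sd_

    def fit_transform(self, data: np.ndarray) -> np.ndarray:
        return self.fit(data).transform(data)

    def to_dict(self) -> dict:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        return {"mean": self.mean_.tolist(), "sd": self.sd_.tolist()}

    @classmethod
    def from_dict(cls, payload: dict) -> "ChannelScaler":
        scaler = cls()
        scaler.mean_ = np.asarray(payload["mean"], dtype=np.float64)
        scaler.sd_ = np.asarray(payload["sd"], dtype=np.float64)
        return scaler


def normalize_tensors(
    tensors: np.ndarray,
    scaler: ChannelScaler | None = None,
) -> tuple[np.ndarray, ChannelScaler]:
    """Standardize a tensor stack per channel.

    Pass ``scaler=None`` to fit on ``tensors`` (the training set);
    pass a fitted scaler to apply training statistics to other splits.
    """
    if scaler is None:
        scaler = ChannelScaler().fit(tensors)
    return scaler.transform(tensors), scaler
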