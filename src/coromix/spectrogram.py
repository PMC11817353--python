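"""Short-time Fourier spectrograms and their RGB image rendering.

Each ECG lead is converted to a time-frequency magnitude matrix (Hamming
window, zero-padded FFT, one-sided spectrum, dB scale) and then rendered as
a small square RGB image: dB values over a fixed display range below the
per-image peak are scaled to [0, 1], mapped through a perceptually uniform
colormap (viridis by default), and bilinearly resized.  The twelve per-lead
images of a record are the model's inputs.

The dB conversion is ``20*log10(|X| + eps)`` with ``eps = 1e-12``; an
all-zero signal therefore maps to a flat matrix at the -240 dB floor.
Because that floor (and chance noise notches near it) is a numerical
artifact, normalization deliberately ignores the image minimum: values are
clipped to ``dynamic_range_db`` (default 80 dB) below the peak, the usual
spectrogram display convention.  The rendering is therefore invariant to a
constant dB offset but not to per-image noise-floor jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import matplotlib as mpl
from scipy.fft import rfft
from skimage.transform import resize

from .ecg_io import LEAD_NAMES, ECGRecord

DB_EPS = 1e-12


class SignalTooShortError(ValueError):
    def __init__(self, n: int, window: int):
        super().__init__(f"signal-too-short: {n} samples < window {window}")


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT and rendering parameters.

    ``window`` is the Hamming window length in samples, ``hop`` the stride
    between frames, ``nfft`` the zero-padded FFT length, ``out_size`` the
    side of the square RGB image.
    """

    window: int = 10
    hop: int = 5
    nfft: int = 512
    fs: float = 500.0
    colormap: str = "viridis"
    out_size: int = 64
    dynamic_range_db: float = 80.0

    def __post_init__(self) -> None:
        if self.window > self.nfft:
            raise ValueError("window must not exceed nfft")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.out_size < 8:
            raise ValueError("out_size must be >= 8")
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic_range_db must be > 0")

    @property
    def n_bins(self) -> int:
        return self.nfft // 2 + 1

    def n_frames(self, n_samples: int) -> int:
        return (n_samples - self.window) // self.hop + 1


@dataclass(frozen=True)
class SpectrogramMatrix:
    """dB magnitudes, shape (nfft/2 + 1, n_frames), with axis vectors."""

    values: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    params: SpectrogramParams


@dataclass(frozen=True)
class SpectrogramImage:
    """RGB pixels in [0, 1], shape (out_size, out_size, 3)."""

    pixels: np.ndarray = field(repr=False)
    lead: str
    params: SpectrogramParams


def stft_spectrogram(signal: np.ndarray, params: SpectrogramParams) -> SpectrogramMatrix:
    """One-sided dB magnitude STFT of a 1-d signal.

    Frames of length ``window`` are taken at stride ``hop``, multiplied by a
    symmetric Hamming window, zero-padded to ``nfft``, and transformed;
    magnitudes go through ``20*log10(|X| + 1e-12)``.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-d")
    if x.size < params.window:
        raise SignalTooShortError(x.size, params.window)
    frames = np.lib.stride_tricks.sliding_window_view(x, params.window)[:: params.hop]
    win = np.hamming(params.window)
    spec = np.abs(rfft(frames * win, n=params.nfft, axis=1))
    values = 20.0 * np.log10(spec + DB_EPS).T  # (n_bins, n_frames)
    freqs = np.arange(params.n_bins) * params.fs / params.nfft
    centers = np.arange(frames.shape[0]) * params.hop + (params.window - 1) / 2.0
    return SpectrogramMatrix(values=values, freqs=freqs, times=centers / params.fs,
                             params=params)


def _colormap_lut(name: str) -> np.ndarray:
    try:
        cmap = mpl.colormaps[name]
    except KeyError:
        known = ", ".join(sorted(mpl.colormaps)[:20])
        raise ValueError(
            f"unknown colormap {name!r}; supported names include {known}, ..."
        )
    return cmap(np.linspace(0.0, 1.0, 256))[:, :3]


def spectrogram_to_image(
    matrix: SpectrogramMatrix, params: SpectrogramParams | None = None,
    lead: str = "",
) -> SpectrogramImage:
    """Render a dB matrix as a square RGB image.

    The display window ``[peak - dynamic_range_db, peak]`` is scaled to
    [0, 1] with values below the window clipped to 0; a constant matrix
    (silence) maps to all zeros, the colormap's low end.  The normalized
    matrix goes through the colormap lookup and is bilinearly resized to
    ``out_size`` on each channel.
    """
    params = params or matrix.params
    vals = matrix.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("spectrogram matrix must be finite")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        norm = np.zeros_like(vals)
    else:
        floor = hi - params.dynamic_range_db
        norm = np.clip((vals - floor) / params.dynamic_range_db, 0.0, 1.0)
    lut = _colormap_lut(params.colormap)
    idx = np.clip((norm * 255.0).round().astype(int), 0, 255)
    rgb = lut[idx]  # (n_bins, n_frames, 3)
    # anti-aliased bilinear resize: when shrinking, each output pixel is a
    # local average rather than a single source sample, so the rendering is
    # stable against frame-level phase jitter (this matches the default
    # behavior of the common image-resize routines)
    out = resize(
        rgb, (params.out_size, params.out_size),
        order=1, mode="edge", anti_aliasing=True, preserve_range=True,
    )
    return SpectrogramImage(pixels=np.clip(out, 0.0, 1.0), lead=lead, params=params)


def record_to_inputs(
    record: ECGRecord, params: SpectrogramParams
) -> list[SpectrogramImage]:
    """One image per lead, in canonical lead order (I ... V6)."""
    images = []
    for lead in LEAD_NAMES:
        matrix = stft_spectrogram(record.leads[lead], params)
        images.append(spectrogram_to_image(matrix, params, lead=lead))
    return images


def record_to_tensor(record: ECGRecord, params: SpectrogramParams) -> np.ndarray:
    """Stack the 12 lead images into a (12, out_size, out_size, 3) array."""
    return np.stack([img.pixels for img in record_to_inputs(record, params)])
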