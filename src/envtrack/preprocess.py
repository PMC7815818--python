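"""EEG preprocessing: band filtering, epoching, referencing, normalization.

Operates on already-cleaned multichannel EEG (artifact removal is delegated
upstream). Bands: full 1-8 Hz, delta 1-4 Hz, theta 4-8 Hz; epochs span -5 to
70 s around stimulus onset; common-average reference; per-subject pooled
z-scoring before TRF estimation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt, sosfreqz

__all__ = [
    "BandSpec",
    "EEGEpochs",
    "DEFAULT_BANDS",
    "DEFAULT_CHANNELS_32",
    "bandpass",
    "common_average_reference",
    "zscore_subject",
    "epoch_tracks",
    "resample_eeg",
    "filter_response",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"band {self.name}: need 0 < f_lo < f_hi")


DEFAULT_BANDS = {
    "full": BandSpec("full", 1.0, 8.0),
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
}

# Standard 10-20 derived montage for a 32-channel active-electrode cap.
DEFAULT_CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]


@dataclass
class EEGEpochs:
    """Channel x time x track array with band/epoch metadata."""

    data: np.ndarray  # (n_channels, n_samples, n_tracks)
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    band: str = "raw"
    epoch_window_s: tuple[float, float] = (-5.0, 70.0)
    subject_id: str = "sub"
    group: str = "HC"
    onset_sample: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError("data must be channel x time x track")
        if self.band not in {"raw", "full", "delta", "theta"}:
            raise ValueError(f"unknown band label {self.band!r}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length mismatch")
        if self.onset_sample is None:
            self.onset_sample = int(round(-self.epoch_window_s[0] * self.fs))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_tracks(self) -> int:
        return self.data.shape[2]


def _band_sos(band: BandSpec, fs: float):
    if band.f_hi >= fs / 2.0:
        raise ValueError(f"band {band.name} upper edge {band.f_hi} Hz >= Nyquist {fs / 2}")
    return butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(epochs: EEGEpochs, band: BandSpec) -> EEGEpochs:
    """Zero-phase (forward-backward) 4th-order Butterworth bandpass per channel/track."""
    if epochs.band not in {"raw", "full"}:
        raise ValueError("delta/theta bands are derived from raw/wideband data")
    sos = _band_sos(band, epochs.fs)
    out = sosfiltfilt(sos, epochs.data, axis=1)
    return replace(epochs, data=out, band=band.name)


def common_average_reference(epochs: EEGEpochs) -> EEGEpochs:
    """Subtract the instantaneous mean across channels."""
    if epochs.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    out = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    return replace(epochs, data=out)


def zscore_subject(epochs: EEGEpochs, mode: str = "pooled") -> EEGEpochs:
    """Center/scale a subject's data.

    ``pooled``: one scalar mean/SD over all channels, samples, and tracks
    (preserves relative channel amplitudes). ``per_channel``: each channel
    standardized by its own mean/SD.
    """
    if not np.all(np.isfinite(epochs.data)):
        raise ValueError("non-finite data")
    if mode == "pooled":
        mu, sd = epochs.data.mean(), epochs.data.std()
        if sd == 0:
            raise ValueError("degenerate input: zero variance")
        out = (epochs.data - mu) / sd
    elif mode == "per_channel":
        mu = epochs.data.mean(axis=(1, 2), keepdims=True)
        sd = epochs.data.std(axis=(1, 2), keepdims=True)
        if np.any(sd == 0):
            raise ValueError("degenerate input: zero-variance channel")
        out = (epochs.data - mu) / sd
    else:
        raise ValueError(f"unknown zscore mode {mode!r}")
    return replace(epochs, data=out)


def epoch_tracks(
    continuous: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-5.0, 70.0),
    **meta,
) -> EEGEpochs:
    """Cut equal-length epochs around each stimulus onset of a continuous recording."""
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_total = continuous.shape[1]
    start_off = int(round(window_s[0] * fs))
    length = int(round((window_s[1] - window_s[0]) * fs))
    epochs = []
    for k, onset in enumerate(np.atleast_1d(onsets_s)):
        i0 = int(round(onset * fs)) + start_off
        if i0 < 0 or i0 + length > n_total:
            raise ValueError(
                f"track {k}: window {window_s} at onset {onset}s exceeds recording bounds"
            )
        epochs.append(continuous[:, i0 : i0 + length])
    data = np.stack(epochs, axis=2)
    return EEGEpochs(data=data, fs=fs, epoch_window_s=window_s, **meta)


def resample_eeg(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase (anti-aliased) resampling along the time axis (axis 1)."""
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return resample_poly(np.asarray(data, dtype=float), frac.numerator, frac.denominator, axis=1)


def filter_response(band: BandSpec, fs: float, n_freqs: int = 512):
    """Frequency response (Hz, two-pass amplitude gain) of the band filter, for reporting."""
    sos = _band_sos(band, fs)
    w, h = sosfreqz(sos, worN=n_freqs, fs=fs)
    return w, np.abs(h) ** 2  # filtfilt applies the filter twice
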