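"""Multiband envelope-edge stimulus features.

Audio is decomposed by a bank of 4th-order gammatone filters uniformly spaced
on the ERB-rate scale, per-band Hilbert envelopes are power-law compressed,
resampled to the EEG clock, and differentiated to emphasise acoustic onsets
and offsets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import butter, hilbert, lfilter, resample_poly, sosfiltfilt

__all__ = [
    "AudioTrack",
    "FilterbankSpec",
    "MultibandEnvelope",
    "erb_rate",
    "erb_rate_inverse",
    "erb_bandwidth",
    "erb_center_frequencies",
    "gammatone_filterbank",
    "envelope_edges",
    "multiband_envelope",
]

# Glasberg & Moore ERB-rate constants (Slaney toolbox convention).
_ERB_SCALE = 21.4
_ERB_COEF = 0.00437


@dataclass
class AudioTrack:
    """A single narrative segment's waveform."""

    samples: np.ndarray
    fs: float
    track_id: str = "track"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 2:  # stereo: average to mono
            self.samples = self.samples.mean(axis=0 if self.samples.shape[0] < self.samples.shape[1] else 1)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D (or stereo 2-D) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class FilterbankSpec:
    """Gammatone filterbank layout on the ERB-rate scale."""

    n_bands: int = 16
    f_low: float = 250.0
    f_high: float = 8000.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.f_low >= self.f_high:
            raise ValueError(f"f_low ({self.f_low}) must be < f_high ({self.f_high})")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if self.order != 4:
            raise ValueError("only 4th-order gammatone filters are supported")


@dataclass
class MultibandEnvelope:
    """Band x time envelope-edge feature matrix on the EEG sample clock."""

    features: np.ndarray  # (n_bands, n_samples)
    fs: float
    band_centers: np.ndarray
    compression_exponent: float = 0.6
    track_id: str = "track"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (band x time)")
        if len(self.band_centers) != self.features.shape[0]:
            raise ValueError("band_centers length must equal the number of bands")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain NaN/Inf")
        if np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("band_centers must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.features.shape[0]

    @property
    def n_samples(self) -> int:
        return self.features.shape[1]


def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-rate (number of ERBs) at frequency ``f`` in Hz."""
    return _ERB_SCALE * np.log10(_ERB_COEF * np.asarray(f, dtype=float) + 1.0)


def erb_rate_inverse(e: np.ndarray | float) -> np.ndarray | float:
    """Frequency in Hz whose ERB-rate is ``e``."""
    return (10.0 ** (np.asarray(e, dtype=float) / _ERB_SCALE) - 1.0) / _ERB_COEF


def erb_bandwidth(fc: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth (Hz) at center frequency ``fc``."""
    return 24.7 * (4.37 * np.asarray(fc, dtype=float) / 1000.0 + 1.0)


def erb_center_frequencies(spec: FilterbankSpec) -> np.ndarray:
    """Center frequencies uniformly spaced on the ERB-rate scale, endpoints inclusive."""
    rates = np.linspace(erb_rate(spec.f_low), erb_rate(spec.f_high), spec.n_bands)
    fc = np.asarray(erb_rate_inverse(rates), dtype=float)
    fc[0] = spec.f_low  # exact endpoints (round-trip is ~1e-13 off)
    fc[-1] = spec.f_high
    return fc


def _gammatone_coefs(fc: float, fs: float):
    """Slaney all-pole gammatone: four cascaded 2nd-order sections plus gain.

    Returns (feedback a, per-stage numerators b1..b4, overall gain).
    """
    T = 1.0 / fs
    B = 2.0 * np.pi * 1.019 * erb_bandwidth(fc)
    arg = 2.0 * fc * np.pi * T
    cos_a, sin_a = np.cos(arg), np.sin(arg)
    eB = np.exp(B * T)

    a = np.array([1.0, -2.0 * cos_a / eB, np.exp(-2.0 * B * T)])

    rt_pos = np.sqrt(3.0 + 2.0 ** 1.5)
    rt_neg = np.sqrt(3.0 - 2.0 ** 1.5)
    k = T / eB
    b_stages = [
        np.array([T, -(k * cos_a + rt_pos * k * sin_a), 0.0]),
        np.array([T, -(k * cos_a - rt_pos * k * sin_a), 0.0]),
        np.array([T, -(k * cos_a + rt_neg * k * sin_a), 0.0]),
        np.array([T, -(k * cos_a - rt_neg * k * sin_a), 0.0]),
    ]

    z = np.exp(2j * arg)
    zb = np.exp(-(B * T) + 1j * arg)
    num = 1.0
    for s in (-rt_neg, rt_neg, -rt_pos, rt_pos):
        num = num * (-2.0 * z * T + 2.0 * zb * T * (cos_a + s * sin_a))
    den = (-2.0 / np.exp(2.0 * B * T) - 2.0 * z + 2.0 * (1.0 + z) / eB) ** 4
    gain = abs(num / den)
    return a, b_stages, gain


def gammatone_filterbank(audio: AudioTrack, spec: FilterbankSpec = FilterbankSpec()) -> np.ndarray:
    """Filter ``audio`` through the gammatone bank; returns (n_bands, n_samples)."""
    if audio.fs < 2.0 * spec.f_high:
        raise ValueError(
            f"sampling rate {audio.fs} Hz cannot represent the top band at {spec.f_high} Hz"
        )
    centers = erb_center_frequencies(spec)
    out = np.empty((spec.n_bands, len(audio.samples)))
    for i, fc in enumerate(centers):
        a, b_stages, gain = _gammatone_coefs(fc, audio.fs)
        y = lfilter(b_stages[0] / gain, a, audio.samples)
        for b in b_stages[1:]:
            y = lfilter(b, a, y)
        out[i] = y
    return out


def _hilbert_magnitude(band_signals: np.ndarray, fs: float, pad_s: float = 1.0) -> np.ndarray:
    """|analytic signal| per band with reflection padding to tame edge ringing."""
    n = band_signals.shape[1]
    pad = min(int(round(pad_s * fs)), n - 1)
    x = np.pad(band_signals, ((0, 0), (pad, pad)), mode="reflect")
    nfft = next_fast_len(x.shape[1])
    env = np.abs(hilbert(x, N=nfft, axis=1)[:, : x.shape[1]])
    return env[:, pad : pad + n]


def envelope_edges(
    band_signals: np.ndarray,
    fs_in: float,
    fs_out: float,
    exponent: float = 0.6,
    *,
    rectify: bool = False,
    band_centers: np.ndarray | None = None,
    track_id: str = "track",
) -> MultibandEnvelope:
    """Compressed-envelope first derivative per band, resampled to ``fs_out``.

    Pipeline per band: Hilbert magnitude -> power-law compression -> anti-alias
    low-pass at 0.4*fs_out -> polyphase resample to fs_out -> first temporal
    difference scaled by fs_out (first sample defined as 0). The signed
    derivative is kept by default (onsets positive, offsets negative); pass
    ``rectify=True`` for half-wave rectified onsets only.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    if fs_out > fs_in:
        raise ValueError("fs_out must be <= fs_in")
    band_signals = np.atleast_2d(np.asarray(band_signals, dtype=float))

    env = _hilbert_magnitude(band_signals, fs_in) ** exponent

    if fs_out != fs_in:
        nyq_frac = 0.4 * fs_out / (fs_in / 2.0)
        sos = butter(4, nyq_frac, output="sos")
        env = sosfiltfilt(sos, env, axis=1)
        from fractions import Fraction

        frac = Fraction(fs_out / fs_in).limit_denominator(10000)
        env = resample_poly(env, frac.numerator, frac.denominator, axis=1)

    edges = np.diff(env, axis=1, prepend=env[:, :1]) * fs_out
    edges[:, 0] = 0.0
    if rectify:
        edges = np.maximum(edges, 0.0)

    if band_centers is None:
        band_centers = np.arange(1, band_signals.shape[0] + 1, dtype=float)
    return MultibandEnvelope(
        features=edges,
        fs=fs_out,
        band_centers=band_centers,
        compression_exponent=exponent,
        track_id=track_id,
    )


def multiband_envelope(
    audio: AudioTrack,
    spec: FilterbankSpec = FilterbankSpec(),
    fs_out: float = 128.0,
    exponent: float = 0.6,
    rectify: bool = False,
) -> MultibandEnvelope:
    """Full stimulus-model pipeline: gammatone bank -> envelope edges at ``fs_out``."""
    bands = gammatone_filterbank(audio, spec)
    return envelope_edges(
        bands,
        audio.fs,
        fs_out,
        exponent,
        rectify=rectify,
        band_centers=erb_center_frequencies(spec),
        track_id=audio.track_id,
    )
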