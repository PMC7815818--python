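"""Synthetic stimuli and simulated EEG with known ground-truth encoding.

Emulates the study design (2 groups x 2 narratives x 15 tracks x 32 channels
at 128 Hz): speech-like stimuli are pink noise amplitude-modulated at a
quasi-periodic syllable rate; simulated EEG is the lagged convolution of the
multiband envelope edges with a smooth ground-truth kernel (group-specific
theta-band gain) plus 1/f background noise, preceded by a noise-only
pre-stimulus segment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann, tukey
from scipy.stats import gamma as gamma_dist

from .envelope import AudioTrack, FilterbankSpec, multiband_envelope
from .preprocess import DEFAULT_CHANNELS_32, EEGEpochs
from .trf import LagWindow, build_lagged_design

__all__ = [
    "SimulationConfig",
    "GroundTruthKernel",
    "make_syllabic_stimulus",
    "pink_noise",
    "default_kernel",
    "simulate_subject_eeg",
    "simulate_comprehension",
]


@dataclass
class SimulationConfig:
    """Scale and noise parameters of one simulated study arm."""

    n_subjects_per_group: int = 10
    n_tracks: int = 15
    track_duration_s: float = 60.0
    n_channels: int = 32
    eeg_fs: float = 128.0
    audio_fs: float = 16000.0
    noise_exponent: float = 1.0
    snr_db: float = 0.0
    seed: int = 0
    n_bands: int = 16
    f_low: float = 250.0
    f_high: float = 8000.0
    syllable_rate_hz: float = 4.5
    pre_stimulus_s: float = 5.0
    common_mode_weight: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_group", "n_tracks", "n_channels", "n_bands"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.track_duration_s <= 0:
            raise ValueError("track_duration_s must be > 0")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.pre_stimulus_s < 5.0:
            raise ValueError("pre_stimulus_s must be >= 5 s (epoching needs -5 s)")

    @property
    def filterbank(self) -> FilterbankSpec:
        return FilterbankSpec(self.n_bands, self.f_low, self.f_high)


@dataclass
class GroundTruthKernel:
    """Known encoding kernel used to generate (and later recover) EEG."""

    lags_ms: np.ndarray
    weights: np.ndarray  # (n_lags, n_bands, n_channels)
    theta_gain: float = 1.0
    latency_ms: float = 100.0
    gain_band_hz: tuple[float, float] = (5.0, 8.0)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")
        if self.theta_gain <= 0:
            raise ValueError("theta_gain must be > 0")
        if self.weights.ndim != 3:
            raise ValueError("weights must be lag x band x channel")
        if np.any(self.weights[0] != 0) or np.any(self.weights[-1] != 0):
            raise ValueError("kernel must be compactly supported (zero at first/last lag)")


def pink_noise(
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    exponent: float = 1.0,
    size: int | None = None,
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**exponent, unit RMS."""
    shape = (size, n_samples) if size is not None else (n_samples,)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    rms = np.sqrt((x**2).mean(axis=-1, keepdims=True))
    return x / rms


def make_syllabic_stimulus(
    duration_s: float,
    audio_fs: float = 16000.0,
    syllable_rate_hz: float = 4.5,
    seed: int | np.random.Generator = 0,
) -> AudioTrack:
    """Pink-noise carrier amplitude-modulated by a jittered syllable-rate pulse train.

    Inter-pulse intervals are uniform within +/-20% of 1/rate; pulses are
    smoothed with a raised-cosine (Hann) window so the broadband envelope's
    modulation spectrum peaks at the syllable rate. Peak-normalized to |x|<=1.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if not (2.0 <= syllable_rate_hz <= 8.0):
        raise ValueError("syllable_rate_hz must lie in [2, 8]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * audio_fs))

    carrier = pink_noise(n, audio_fs, rng, exponent=1.0)

    period = 1.0 / syllable_rate_hz
    t, times = 0.5 * period, []
    while t < duration_s:
        times.append(t)
        t += period * (1.0 + rng.uniform(-0.2, 0.2))
    env = np.zeros(n)
    width = int(round(0.6 * period * audio_fs))
    win = hann(max(width, 3))
    for pt in times:
        i0 = int(round(pt * audio_fs)) - len(win) // 2
        lo, hi = max(i0, 0), min(i0 + len(win), n)
        if hi > lo:
            env[lo:hi] += win[lo - i0 : hi - i0]
    env += 0.05  # voicing floor so the carrier never fully gates off

    x = carrier * env
    x = 0.99 * x / np.max(np.abs(x))
    return AudioTrack(samples=x, fs=audio_fs, track_id=f"syl{syllable_rate_hz:g}Hz")


def default_kernel(
    window: LagWindow,
    n_bands: int,
    n_channels: int,
    seed: int | np.random.Generator = 0,
    latency_ms: float = 100.0,
    theta_gain: float = 1.0,
    amplitude: float = 1.0,
) -> GroundTruthKernel:
    """Difference-of-Gammas lag profile (peak at ``latency_ms``), Gaussian band
    profile, and a seeded random +/-1 channel polarity map with mild gain spread."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lags_ms = window.lags_ms
    t = np.maximum(lags_ms, 0.0)
    # gamma mode = (a-1)*scale; positive lobe peaks at latency, negative ~1.8x later
    pos = gamma_dist.pdf(t, a=4.0, scale=latency_ms / 3.0)
    neg = gamma_dist.pdf(t, a=6.0, scale=latency_ms * 1.8 / 5.0)
    lag_profile = pos / pos.max() - 0.6 * neg / neg.max()
    lag_profile *= tukey(len(lags_ms), alpha=0.2)
    lag_profile[0] = lag_profile[-1] = 0.0

    band_idx = np.arange(n_bands)
    band_profile = np.exp(-0.5 * ((band_idx - (n_bands - 1) / 2.0) / (n_bands / 3.0)) ** 2)

    # balanced +/-1 polarity map (random assignment, zero channel mean for even
    # channel counts) so common-average referencing does not erase signal
    polarity = np.ones(n_channels)
    polarity[: n_channels // 2] = -1.0
    polarity = rng.permutation(polarity)

    w = lag_profile[:, None, None] * band_profile[None, :, None] * polarity[None, None, :]
    w *= amplitude / np.sqrt((w**2).mean())
    w[0] = 0.0
    w[-1] = 0.0
    return GroundTruthKernel(
        lags_ms=lags_ms,
        weights=w,
        theta_gain=theta_gain,
        latency_ms=latency_ms,
    )


def _theta_boost(sig: np.ndarray, fs: float, gain: float, band: tuple[float, float]) -> np.ndarray:
    """Scale the signal's band component by ``gain`` using an exact FFT mask.

    The brick-wall mask guarantees zero energy change outside ``band``, so a
    theta-band gain cannot leak into the delta analysis band.
    """
    if gain == 1.0:
        return sig
    n = sig.shape[0]
    spec = np.fft.rfft(sig, axis=0)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[mask] *= gain
    return np.fft.irfft(spec, n=n, axis=0)


def simulate_subject_eeg(
    stimuli: list[AudioTrack],
    kernel: GroundTruthKernel,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    *,
    envelopes=None,
    window: LagWindow | None = None,
    subject_id: str = "sub",
    group: str = "HC",
) -> EEGEpochs:
    """Forward-simulate one subject's epoched EEG from stimuli and a kernel.

    Per track: EEG(ch, t) = sum_band sum_tau weights(tau, band, ch) *
    envelope_edge(band, t - tau), with the clean signal's theta component
    scaled by ``kernel.theta_gain``, plus 1/f noise (independent per channel
    with a shared common-mode component) scaled to ``config.snr_db``. A
    noise-only pre-stimulus segment of ``config.pre_stimulus_s`` precedes each
    track.
    """
    if not stimuli and envelopes is None:
        raise ValueError("stimuli must be non-empty")
    if window is None:
        window = LagWindow(kernel.lags_ms[0], kernel.lags_ms[-1], config.eeg_fs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    if envelopes is None:
        envelopes = [
            multiband_envelope(s, config.filterbank, fs_out=config.eeg_fs) for s in stimuli
        ]
    n_bands = envelopes[0].n_bands
    if kernel.weights.shape[1] != n_bands:
        raise ValueError(
            f"kernel has {kernel.weights.shape[1]} bands, features have {n_bands}"
        )
    w_flat = kernel.weights.reshape(-1, kernel.weights.shape[2])
    n_ch = kernel.weights.shape[2]
    n_pre = int(round(config.pre_stimulus_s * config.eeg_fs))
    amp = 10.0 ** (config.snr_db / 20.0)

    tracks = []
    for env in envelopes:
        X = build_lagged_design(env, window)
        sig = X[:, 1:] @ w_flat  # (time, ch)
        # snr_db is referenced to the unboosted signal so the theta gain
        # raises in-band SNR instead of being cancelled by noise rescaling
        rms_sig = np.sqrt((sig**2).mean())
        sig = _theta_boost(sig, config.eeg_fs, kernel.theta_gain, kernel.gain_band_hz)
        n_post = sig.shape[0]

        private = pink_noise(n_pre + n_post, config.eeg_fs, rng,
                             config.noise_exponent, size=n_ch)
        shared = pink_noise(n_pre + n_post, config.eeg_fs, rng, config.noise_exponent)
        noise = (private + config.common_mode_weight * shared) / np.sqrt(
            1.0 + config.common_mode_weight**2
        )
        rms_noise = np.sqrt((noise[:, n_pre:] ** 2).mean())
        if rms_sig > 0:
            noise *= rms_sig / (amp * rms_noise)
        track = noise.copy()
        track[:, n_pre:] += sig.T
        tracks.append(track)

    data = np.stack(tracks, axis=2)
    labels = (
        DEFAULT_CHANNELS_32[:n_ch]
        if n_ch <= len(DEFAULT_CHANNELS_32)
        else [f"ch{i:02d}" for i in range(n_ch)]
    )
    duration = (data.shape[1] - n_pre) / config.eeg_fs
    return EEGEpochs(
        data=data,
        fs=config.eeg_fs,
        channel_labels=list(labels),
        band="raw",
        epoch_window_s=(-config.pre_stimulus_s, duration),
        subject_id=subject_id,
        group=group,
        onset_sample=n_pre,
    )


def simulate_comprehension(
    subject_ids: list[str],
    groups: list[str],
    p_correct: dict[str, float],
    n_questions: int = 30,
    n_narratives: int = 2,
    seed: int | np.random.Generator = 0,
):
    """Per-track Bernoulli comprehension scores (2 questions x 15 tracks default).

    Returns a tidy DataFrame (subject, group, narrative, correct, total).
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sid, grp in zip(subject_ids, groups):
        for nar in range(1, n_narratives + 1):
            correct = int(rng.binomial(n_questions, p_correct[grp]))
            rows.append(
                {"subject": sid, "group": grp, "narrative": f"narrative{nar}",
                 "correct": correct, "total": n_questions}
            )
    return pd.DataFrame(rows)
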