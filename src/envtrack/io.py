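"""File I/O: WAV audio, the portable HDF5+JSON EEG/feature container, a
ground-truth kernel store, and minimal EDF / BrainVision ingestion readers."""
from __future__ import annotations

import configparser
import json
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .envelope import AudioTrack, MultibandEnvelope
from .preprocess import EEGEpochs
from .synthdata import GroundTruthKernel

__all__ = [
    "read_wav",
    "write_wav",
    "save_epochs",
    "load_epochs",
    "save_envelope",
    "load_envelope",
    "save_kernel",
    "load_kernel",
    "save_trf_model",
    "load_trf_model",
    "read_edf",
    "read_brainvision",
]


def write_wav(path, track: AudioTrack) -> None:
    wavfile.write(str(path), int(track.fs), track.samples.astype(np.float32))


def read_wav(path, track_id: str | None = None) -> AudioTrack:
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":  # PCM -> [-1, 1]
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2.0) / (info.max / 2.0)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioTrack(samples=data.astype(float), fs=float(fs),
                      track_id=track_id or Path(path).stem)


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def save_epochs(path, epochs: EEGEpochs) -> None:
    """Write data to HDF5 and metadata to a JSON sidecar ``<path>.json``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
    meta = {
        "fs": epochs.fs,
        "channel_labels": list(epochs.channel_labels),
        "band": epochs.band,
        "epoch_window_s": list(epochs.epoch_window_s),
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "onset_sample": int(epochs.onset_sample),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_epochs(path) -> EEGEpochs:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
    meta = json.loads(_sidecar(path).read_text())
    meta["epoch_window_s"] = tuple(meta["epoch_window_s"])
    return EEGEpochs(data=data, **meta)


def save_envelope(path, env: MultibandEnvelope) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=env.features)
        f.create_dataset("band_centers", data=env.band_centers)
        f.attrs["fs"] = env.fs
        f.attrs["compression_exponent"] = env.compression_exponent
        f.attrs["track_id"] = env.track_id


def load_envelope(path) -> MultibandEnvelope:
    with h5py.File(path, "r") as f:
        return MultibandEnvelope(
            features=f["features"][()],
            band_centers=f["band_centers"][()],
            fs=float(f.attrs["fs"]),
            compression_exponent=float(f.attrs["compression_exponent"]),
            track_id=str(f.attrs["track_id"]),
        )


def save_kernel(path, kernel: GroundTruthKernel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=kernel.weights)
        f.create_dataset("lags_ms", data=kernel.lags_ms)
        f.attrs["theta_gain"] = kernel.theta_gain
        f.attrs["latency_ms"] = kernel.latency_ms
        f.attrs["gain_band_hz"] = list(kernel.gain_band_hz)


def load_kernel(path) -> GroundTruthKernel:
    with h5py.File(path, "r") as f:
        return GroundTruthKernel(
            lags_ms=f["lags_ms"][()],
            weights=f["weights"][()],
            theta_gain=float(f.attrs["theta_gain"]),
            latency_ms=float(f.attrs["latency_ms"]),
            gain_band_hz=tuple(f.attrs["gain_band_hz"]),
        )


def save_trf_model(path, model) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=model.weights)
        f.create_dataset("intercept", data=model.intercept)
        f.create_dataset("lag_axis_ms", data=model.lag_axis_ms)
        if model.band_centers is not None:
            f.create_dataset("band_centers", data=model.band_centers)
        f.attrs["lambda"] = model.lam


def load_trf_model(path):
    from .trf import TRFModel

    with h5py.File(path, "r") as f:
        return TRFModel(
            weights=f["weights"][()],
            intercept=f["intercept"][()],
            lam=float(f.attrs["lambda"]),
            lag_axis_ms=f["lag_axis_ms"][()],
            band_centers=f["band_centers"][()] if "band_centers" in f else None,
        )


# --- ingestion readers -------------------------------------------------------

def read_edf(path):
    """Minimal EDF reader: continuous (channels x samples) float data.

    Supports uniform sampling rate across signals; annotations channels are
    skipped. Returns (data, fs, labels).
    """
    with open(path, "rb") as f:
        hdr = f.read(256)
        n_records = int(hdr[236:244].decode().strip())
        record_dur = float(hdr[244:252].decode().strip())
        n_sig = int(hdr[252:256].decode().strip())

        def _fields(width):
            raw = f.read(width * n_sig)
            return [raw[i * width : (i + 1) * width].decode().strip() for i in range(n_sig)]

        labels = _fields(16)
        f.read(80 * n_sig)  # transducer
        f.read(8 * n_sig)  # physical dimension
        phys_min = np.array([float(v) for v in _fields(8)])
        phys_max = np.array([float(v) for v in _fields(8)])
        dig_min = np.array([float(v) for v in _fields(8)])
        dig_max = np.array([float(v) for v in _fields(8)])
        f.read(80 * n_sig)  # prefiltering
        n_samp = np.array([int(v) for v in _fields(8)])
        f.read(32 * n_sig)  # reserved

        keep = [i for i, lab in enumerate(labels) if "EDF Annotations" not in lab]
        if len(set(n_samp[keep])) != 1:
            raise ValueError("mixed sampling rates are not supported")
        spr = int(n_samp[keep[0]])
        fs = spr / record_dur

        gain = (phys_max - phys_min) / (dig_max - dig_min)
        offset = phys_min - gain * dig_min
        data = np.empty((len(keep), n_records * spr))
        for rec in range(n_records):
            for i in range(n_sig):
                raw = np.frombuffer(f.read(2 * int(n_samp[i])), dtype="<i2")
                if i in keep:
                    row = keep.index(i)
                    data[row, rec * spr : (rec + 1) * spr] = raw * gain[i] + offset[i]
    return data, fs, [labels[i] for i in keep]


def read_brainvision(vhdr_path):
    """Minimal BrainVision reader (.vhdr + binary .eeg, multiplexed).

    Supports IEEE_FLOAT_32 and INT_16 binary formats. Returns (data, fs, labels).
    """
    vhdr_path = Path(vhdr_path)
    text = vhdr_path.read_text()
    # strip the non-INI first line ("Brain Vision Data Exchange Header File ...")
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("Brain Vision"))
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str
    cp.read_string(body)

    common = cp["Common Infos"]
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])  # interval is in microseconds
    data_file = vhdr_path.parent / common["DataFile"]
    fmt = cp["Binary Infos"]["BinaryFormat"].strip()

    labels, resolutions = [], []
    for i in range(1, n_ch + 1):
        parts = cp["Channel Infos"][f"Ch{i}"].split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    if fmt == "IEEE_FLOAT_32":
        raw = np.fromfile(data_file, dtype="<f4")
    elif fmt == "INT_16":
        raw = np.fromfile(data_file, dtype="<i2").astype(float)
    else:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")
    data = raw.reshape(-1, n_ch).T * np.asarray(resolutions)[:, None]
    return data, fs, labels
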