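"""Readers and writers for the formats the toolbox consumes and emits.

CSV: either two columns ``time_s,value`` (sampling rate inferred from the
median sample spacing, uniformity checked) or a single ``value`` column with
an explicit sampling rate.  WAV: PCM16 and float32, mono enforced.
Modulation spectrograms export as labeled CSV matrices with a metadata
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InputError, ParameterError
from .types import ModulationSpectrogram, TimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_csv",
    "write_csv",
    "read_wav",
    "write_wav",
    "export_modspec_csv",
]

#: Allowed relative jitter of CSV time stamps around uniform sampling.
UNIFORMITY_TOL = 1e-6


def read_csv(path: str | Path, fs: float | None = None) -> TimeSeries:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    has_header = any(c.isalpha() for c in first.replace("e", "").replace("E", ""))
    data = np.genfromtxt(path, delimiter=",", skip_header=1 if has_header else 0,
                         dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] >= 2:
        t, v = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if dt.size < 1 or np.any(dt <= 0):
            raise InputError("time column must be strictly increasing")
        med = float(np.median(dt))
        jitter = float(np.max(np.abs(dt - med)) / med)
        if jitter > UNIFORMITY_TOL:
            raise InputError(
                f"non-uniform sampling in {path.name}: relative jitter "
                f"{jitter:.2e} exceeds {UNIFORMITY_TOL:.0e}"
            )
        return TimeSeries(v, 1.0 / med, path.stem)
    if fs is None:
        raise InputError(
            f"{path.name} has a single value column; pass the sampling rate "
            "(--fs on the command line)"
        )
    return TimeSeries(data[:, 0], fs, path.stem)


def write_csv(x: TimeSeries, path: str | Path, with_time: bool = True) -> None:
    path = Path(path)
    if with_time:
        arr = np.column_stack([x.times, x.samples])
        # time stamps need full precision or re-reading sees spurious jitter
        np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="",
                   fmt=["%.15g", "%.9g"])
    else:
        np.savetxt(path, x.samples, delimiter=",", header="value", comments="",
                   fmt="%.9g")


def read_wav(path: str | Path, channel: int | None = None) -> TimeSeries:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fs, data = wavfile.read(path)
    if data.ndim == 2:
        if channel is None:
            raise InputError(
                f"{path.name} has {data.shape[1]} channels; pass --channel "
                f"(0..{data.shape[1] - 1}) to select one"
            )
        data = data[:, channel]
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648.0
    else:
        data = data.astype(float)
    return TimeSeries(data, float(fs), path.stem)


def write_wav(x: TimeSeries, path: str | Path, subtype: str = "float32") -> None:
    if subtype == "float32":
        wavfile.write(path, int(round(x.fs)), x.samples.astype(np.float32))
    elif subtype == "pcm16":
        peak = np.max(np.abs(x.samples))
        scaled = x.samples / peak if peak > 1.0 else x.samples
        q = np.clip(np.round(scaled * 32768.0), -32768, 32767)
        wavfile.write(path, int(round(x.fs)), q.astype(np.int16))
    else:
        raise ParameterError(f"unknown WAV subtype {subtype!r}")


def read_timeseries(path: str | Path, fs: float | None = None,
                    channel: int | None = None) -> TimeSeries:
    """Read a mono time series, dispatching on the file extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".csv":
        return read_csv(path, fs=fs)
    if ext == ".wav":
        return read_wav(path, channel=channel)
    raise InputError(f"unsupported extension {ext!r} (expected .csv or .wav)")


def write_timeseries(x: TimeSeries, path: str | Path, **kw) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".csv":
        write_csv(x, path, **kw)
    elif ext == ".wav":
        write_wav(x, path, **kw)
    else:
        raise InputError(f"unsupported extension {ext!r} (expected .csv or .wav)")


def export_modspec_csv(M: ModulationSpectrogram, path: str | Path,
                       params: dict | None = None) -> None:
    """Write a modulation spectrogram as a labeled CSV matrix plus sidecar.

    Rows are modulation-frequency bins (first column carries the f_mod value
    in Hz); the header row carries the conventional-frequency axis.  A
    ``<path>.meta.json`` sidecar records scale, axes and parameters.
    """
    path = Path(path)
    header = "fmod_hz," + ",".join(f"{f:.6g}" for f in M.freq_axis)
    arr = np.column_stack([M.fmod_axis, M.values])
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.9g")
    meta = {
        "scale": M.scale,
        "normalization": M.normalization,
        "mod_nfft": int(M.mod_nfft),
        "n_env_frames": int(M.n_env_frames),
        "fmod_max_hz": float(M.fmod_axis[-1]),
        "freq_max_hz": float(M.freq_axis[-1]),
        "params": params or {},
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w",
              encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
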