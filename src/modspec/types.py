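"""Core containers for the two-stage modulation spectral analysis.

The analysis chain is ``TimeSeries -> SpectroTemporal -> ModulationSpectrogram``:
a first time-to-frequency transform produces complex spectrotemporal
coefficients ``X(t, f)`` (phase retained so the chain is invertible), and a
second Fourier transform applied along the time axis of the magnitude
envelopes ``|X(t, f)|`` yields the modulation spectrogram ``X(f_mod, f)``,
indexed by modulation frequency (rate of envelope change, Hz) versus
conventional frequency (Hz).  A time-resolved stack of modulation
spectrograms over sliding frames is a :class:`ModulationTensor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Real amplitude sequence, arbitrary units.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text channel name.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise InputError(f"sampling rate must be > 0, got {self.fs}")
        if self.samples.size < 1:
            raise InputError("signal is empty")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class WindowDesc:
    """Descriptor of the first-transform analysis window.

    ``sig_len`` records the original signal length in samples so that
    synthesis can restore the exact input length.
    """

    shape: str
    length: int
    hop: int
    nfft: int
    sig_len: int = 0


@dataclass
class SpectroTemporal:
    """Complex first-transform output ``X(t, f)`` with retained phase.

    ``coeffs`` is indexed ``(frame, frequency bin)``.  ``env_rate`` is the
    sampling rate of the per-bin magnitude envelopes (``fs / hop``); it caps
    the representable modulation frequency at ``env_rate / 2``.
    """

    coeffs: np.ndarray
    freq_axis: np.ndarray
    env_rate: float
    frame_times: np.ndarray
    window_desc: WindowDesc
    fs: float

    @property
    def envelopes(self) -> np.ndarray:
        """Magnitude envelopes ``|X(t, f)|``, shape (frames, bins)."""
        return np.abs(self.coeffs)

    @property
    def phases(self) -> np.ndarray:
        return np.angle(self.coeffs)

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[0]

    def with_envelopes(self, env: np.ndarray) -> "SpectroTemporal":
        """Return a copy with new magnitude envelopes and the original phase.

        Envelopes must be nonnegative; phase is reattached bin-for-bin.
        """
        env = np.asarray(env, dtype=float)
        if env.shape != self.coeffs.shape:
            raise InputError(
                f"envelope shape {env.shape} != coefficient shape {self.coeffs.shape}"
            )
        phase = np.exp(1j * np.angle(self.coeffs))
        return SpectroTemporal(
            coeffs=env * phase,
            freq_axis=self.freq_axis,
            env_rate=self.env_rate,
            frame_times=self.frame_times,
            window_desc=self.window_desc,
            fs=self.fs,
        )


@dataclass
class ModulationSpectrogram:
    """Real nonnegative modulation spectrogram ``X(f_mod, f)``.

    ``values`` is indexed ``(f_mod bin, frequency bin)``; ``scale`` records
    whether entries are spectral magnitudes or powers.  ``win_energy`` is the
    energy of the modulation-analysis window (sum of squared window samples)
    used for Parseval-style energy bookkeeping.
    """

    values: np.ndarray
    fmod_axis: np.ndarray
    freq_axis: np.ndarray
    scale: str = "magnitude"
    normalization: str = "none"
    mod_nfft: int = 0
    n_env_frames: int = 0
    win_energy: float = 1.0

    @property
    def power(self) -> np.ndarray:
        """Values on a power scale regardless of the stored scale."""
        return self.values**2 if self.scale == "magnitude" else self.values

    def band_energy(self, fmod_lo: float, fmod_hi: float,
                    freq_mask: np.ndarray | None = None) -> float:
        """Total modulation power in ``fmod_lo < f_mod <= fmod_hi``.

        One-sided spectra of real envelopes double-count interior bins, so
        non-DC/non-Nyquist bins carry weight 2 (Parseval convention).
        """
        sel = (self.fmod_axis > fmod_lo) & (self.fmod_axis <= fmod_hi)
        w = self._parseval_weights()[sel]
        p = self.power[sel]
        if freq_mask is not None:
            p = p[:, freq_mask]
        return float((w[:, None] * p).sum())

    def _parseval_weights(self) -> np.ndarray:
        w = np.full(self.fmod_axis.size, 2.0)
        w[0] = 1.0
        if self.mod_nfft and self.mod_nfft % 2 == 0:
            w[-1] = 1.0
        return w

    def envelope_energy(self) -> np.ndarray:
        """Per-frequency-bin envelope energy recovered via Parseval.

        Equals ``sum_t |w(t) X(t, f)|^2`` of the (windowed) envelope fed to
        the second transform; with the default boxcar modulation window this
        is exactly ``sum_t |X(t, f)|^2``.
        """
        w = self._parseval_weights()
        return (w[:, None] * self.power).sum(axis=0) / self.mod_nfft


@dataclass
class ModulationTensor:
    """Time-resolved stack of modulation spectrograms, dims ``(F, Fm, N)``."""

    frames: Sequence[ModulationSpectrogram]
    frame_times: np.ndarray

    def __post_init__(self):
        if len(self.frames) < 1:
            raise InputError("tensor needs at least one frame")
        ref = self.frames[0]
        for fr in self.frames[1:]:
            if (fr.fmod_axis.shape != ref.fmod_axis.shape
                    or fr.freq_axis.shape != ref.freq_axis.shape):
                raise InputError("tensor frames must share axes")

    @property
    def fmod_axis(self) -> np.ndarray:
        return self.frames[0].fmod_axis

    @property
    def freq_axis(self) -> np.ndarray:
        return self.frames[0].freq_axis

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.freq_axis.size, self.fmod_axis.size, len(self.frames))

    def as_array(self) -> np.ndarray:
        """Stack as ndarray of shape (F, Fm, N)."""
        return np.stack([fr.values.T for fr in self.frames], axis=-1)


@dataclass
class QualityReport:
    """Scalar quality index plus the intermediates used to compute it."""

    index_name: str
    score: float
    hr_est_bpm: float | None = None
    lobe_centers: np.ndarray | None = None
    band_energies: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "index_name": self.index_name,
            "score": float(self.score),
            "band_energies": {k: float(v) for k, v in self.band_energies.items()},
            "params": self.params,
            "flags": list(self.flags),
        }
        if self.hr_est_bpm is not None:
            d["hr_est_bpm"] = float(self.hr_est_bpm)
        if self.lobe_centers is not None:
            d["lobe_centers_hz"] = [float(c) for c in self.lobe_centers]
        return d


@dataclass
class BeatSeries:
    """Detected or ground-truth R-peak times and RR intervals."""

    r_times: np.ndarray
    source: str = "detected"

    def __post_init__(self):
        self.r_times = np.asarray(self.r_times, dtype=float).ravel()
        if np.any(np.diff(self.r_times) <= 0):
            raise InputError("r_times must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.r_times)

    @property
    def suspect_rr(self) -> np.ndarray:
        """Boolean mask of RR intervals outside the physiological (0.25, 3) s."""
        rr = self.rr_intervals
        return (rr <= 0.25) | (rr >= 3.0)

    @property
    def n_beats(self) -> int:
        return self.r_times.size


@dataclass
class HrvSummary:
    """Time-domain HRV statistics plus the modulation-domain HRV index."""

    mean_hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    pnn50_pct: float
    mod_hrv: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_hr_bpm": float(self.mean_hr_bpm),
            "sdnn_ms": float(self.sdnn_ms),
            "rmssd_ms": float(self.rmssd_ms),
            "pnn50_pct": float(self.pnn50_pct),
        }
        if self.mod_hrv is not None:
            d["mod_hrv_ms"] = float(self.mod_hrv)
        return d
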