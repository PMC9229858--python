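"""Seeded synthetic-signal generators with ground truth.

Every generator is a pure function of its parameters and an integer seed and
returns the ground truth needed to score the analytics built on top of it:
R-peak times and RR statistics for ECG, component signals for auscultation
mixtures, stride rate for gait, RT60 for reverberation.  These emulate the
salient structure the modulation-domain methods rely on — periodic QRS
energy bursts, respiratory amplitude modulation, syllabic envelopes,
heart-sound pips over respiration-gated lung noise, alternating footfalls —
not full physiological morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InputError, ParameterError
from .types import TimeSeries

__all__ = [
    "SynthGroundTruth",
    "synth_ecg",
    "add_noise",
    "synth_am",
    "synth_speechlike",
    "apply_reverb",
    "synth_heart_lung",
    "synth_gait",
]


@dataclass
class SynthGroundTruth:
    """Ground truth accompanying a generated signal."""

    seed: int | None = None
    params: dict = field(default_factory=dict)
    r_times: np.ndarray | None = None
    rr_intervals: np.ndarray | None = None
    breath_rate_bpm: float | None = None
    stride_rate_hz: float | None = None
    snr_db: float | None = None
    components: dict = field(default_factory=dict)


# PQRST template: five Gaussian waves (amplitude, center offset from the R
# apex in seconds, width sigma in seconds).  Widths are fixed in absolute
# time (QRS morphology does not scale with heart rate); amplitudes are in
# arbitrary mV-like units.
_PQRST = (
    (0.15, -0.200, 0.025),  # P
    (-0.10, -0.025, 0.010),  # Q
    (1.00, 0.000, 0.012),   # R
    (-0.15, 0.025, 0.010),  # S
    (0.30, 0.300, 0.060),   # T
)


def synth_ecg(
    hr_bpm: float = 60.0,
    duration_s: float = 60.0,
    fs: float = 256.0,
    sdnn_ms: float = 0.0,
    resp_rate_bpm: float = 0.0,
    resp_depth: float = 0.0,
    seed: int = 0,
) -> tuple[TimeSeries, SynthGroundTruth]:
    """Template ECG with controllable rate, RR variability and respiration.

    A sum-of-Gaussians PQRST template is repeated at RR intervals drawn from
    a first-order autoregressive process (lag-1 coefficient 0.8) whose
    stationary standard deviation is ``sdnn_ms``.  Respiration multiplies the
    whole trace by ``1 + resp_depth*cos(2*pi*f_resp*t)`` — the amplitude
    modulation that ECG-derived respiration recovers.
    """
    if not (30.0 <= hr_bpm <= 220.0):
        raise ParameterError(f"hr_bpm must be in [30, 220], got {hr_bpm}")
    if not (0.0 <= resp_depth <= 0.5):
        raise ParameterError(f"resp_depth must be in [0, 0.5], got {resp_depth}")
    if sdnn_ms < 0 or duration_s <= 0:
        raise ParameterError("sdnn_ms must be >= 0 and duration positive")
    rng = np.random.default_rng(seed)
    mean_rr = 60.0 / hr_bpm
    sd_rr = sdnn_ms / 1000.0
    phi = 0.8
    n_max = int(np.ceil(duration_s / mean_rr)) + 8
    rr = np.full(n_max, mean_rr)
    if sd_rr > 0:
        innov_sd = sd_rr * np.sqrt(1.0 - phi**2)
        dev = 0.0
        for i in range(n_max):
            dev = phi * dev + rng.normal(0.0, innov_sd)
            rr[i] = mean_rr + dev
        rr = np.clip(rr, 0.35 * mean_rr, 2.0 * mean_rr)
    r_times = 0.5 + np.concatenate([[0.0], np.cumsum(rr)])
    r_times = r_times[r_times < duration_s - 0.35]
    t = np.arange(int(round(duration_s * fs))) / fs
    x = np.zeros_like(t)
    for amp, off, sig in _PQRST:
        centers = r_times + off
        # each Gaussian only contributes within +-5 sigma of its center
        half = int(np.ceil(5 * sig * fs))
        for c in centers:
            i0 = int(round(c * fs))
            lo, hi = max(i0 - half, 0), min(i0 + half + 1, t.size)
            if lo < hi:
                x[lo:hi] += amp * np.exp(-((t[lo:hi] - c) ** 2) / (2 * sig**2))
    if resp_depth > 0 and resp_rate_bpm > 0:
        x *= 1.0 + resp_depth * np.cos(2 * np.pi * (resp_rate_bpm / 60.0) * t)
    gt = SynthGroundTruth(
        seed=seed,
        params=dict(hr_bpm=hr_bpm, duration_s=duration_s, fs=fs, sdnn_ms=sdnn_ms,
                    resp_rate_bpm=resp_rate_bpm, resp_depth=resp_depth),
        r_times=r_times,
        rr_intervals=np.diff(r_times),
        breath_rate_bpm=resp_rate_bpm if resp_depth > 0 else None,
    )
    return TimeSeries(x, fs, "synthetic-ecg"), gt


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n)
    return out / out.std()


def add_noise(
    x: TimeSeries,
    kind: str = "white",
    snr_db: float = 0.0,
    seed: int = 0,
) -> TimeSeries:
    """Add noise of a given kind at an exact target SNR.

    Kinds: ``white`` (Gaussian), ``pink`` (1/f-shaped), ``baseline_wander``
    (band-limited < 0.5 Hz random walk), ``emg_like`` (20-100 Hz band-limited
    noise with burst gating), and ``white+pink`` (equal-power sum).  The
    noise is rescaled so the realized SNR matches ``snr_db`` exactly.
    """
    p_sig = float(np.mean(x.samples**2))
    if p_sig <= 0:
        raise InputError("cannot set an SNR against a zero-power signal")
    rng = np.random.default_rng(seed)
    n = len(x)
    if kind == "white":
        noise = rng.standard_normal(n)
    elif kind == "pink":
        noise = _pink_noise(n, rng)
    elif kind == "white+pink":
        a = rng.standard_normal(n)
        b = _pink_noise(n, rng)
        noise = a / a.std() + b
    elif kind == "baseline_wander":
        walk = np.cumsum(rng.standard_normal(n))
        cut = min(0.5, 0.45 * x.fs / 2.0)
        sos = sps.butter(4, cut, btype="lowpass", fs=x.fs, output="sos")
        noise = sps.sosfiltfilt(sos, walk)
    elif kind == "emg_like":
        hi = min(100.0, 0.45 * x.fs)
        sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=x.fs, output="sos")
        base = sps.sosfiltfilt(sos, rng.standard_normal(n))
        # burst gating: smoothed random on/off envelope
        gate = rng.random(max(int(x.duration * 2), 2)) > 0.5
        gate_t = np.repeat(gate.astype(float), int(np.ceil(n / gate.size)))[:n]
        sos_g = sps.butter(2, 1.0, btype="lowpass", fs=x.fs, output="sos")
        noise = base * (0.1 + sps.sosfiltfilt(sos_g, gate_t))
    else:
        raise ParameterError(f"unknown noise kind {kind!r}")
    p_noise = float(np.mean(noise**2))
    if p_noise <= 0:
        raise InputError("generated noise has zero power")
    noise *= np.sqrt(p_sig / (p_noise * 10.0 ** (snr_db / 10.0)))
    return TimeSeries(x.samples + noise, x.fs, x.label)


def synth_am(
    fc_hz: float,
    fm_hz: float,
    depth: float,
    fs: float,
    duration_s: float,
) -> TimeSeries:
    """Amplitude-modulated tone ``(1 + depth*cos(2*pi*fm*t)) * sin(2*pi*fc*t)``."""
    if not (0.0 <= depth <= 1.0):
        raise ParameterError(f"modulation depth must be in [0, 1], got {depth}")
    if fc_hz >= fs / 2:
        raise ParameterError("carrier must be below Nyquist")
    t = np.arange(int(round(duration_s * fs))) / fs
    x = (1.0 + depth * np.cos(2 * np.pi * fm_hz * t)) * np.sin(2 * np.pi * fc_hz * t)
    return TimeSeries(x, fs, "am-tone")


def synth_speechlike(
    duration_s: float = 4.0,
    fs: float = 16000.0,
    syllable_rate_hz: float = 4.0,
    seed: int = 0,
) -> TimeSeries:
    """Speech-like stimulus: band-shaped noise with a syllabic envelope.

    The carrier is 300-3400 Hz bandpassed Gaussian noise; the envelope is a
    raised cosine at the syllable rate (default 4 Hz, the center of the
    2-20 Hz modulation band where speech energy lives).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    sos = sps.butter(4, [300.0, 3400.0], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
    t = np.arange(n) / fs
    env = 0.55 + 0.45 * np.cos(2 * np.pi * syllable_rate_hz * t)
    return TimeSeries(carrier * env, fs, "speechlike")


def apply_reverb(x: TimeSeries, rt60_s: float, seed: int = 0) -> TimeSeries:
    """Convolve with a synthetic exponentially decaying impulse response.

    The IR is white noise under an exponential envelope whose -60 dB decay
    time equals ``rt60_s``; ``rt60_s = 0`` returns the input unchanged.
    Output is trimmed to the input length and rescaled to the input RMS.
    """
    if rt60_s < 0:
        raise ParameterError("rt60 must be >= 0")
    if rt60_s == 0:
        return TimeSeries(x.samples.copy(), x.fs, x.label)
    rng = np.random.default_rng(seed)
    n_ir = int(round(1.2 * rt60_s * x.fs))
    t = np.arange(n_ir) / x.fs
    # amplitude decay rate: -60 dB in rt60  =>  exp(-6.908 * t / rt60)
    ir = rng.standard_normal(n_ir) * np.exp(-np.log(10.0**3) * t / rt60_s)
    ir[0] = 1.0
    y = sps.fftconvolve(x.samples, ir)[: len(x)]
    rms_in = np.sqrt(np.mean(x.samples**2))
    rms_out = np.sqrt(np.mean(y**2))
    if rms_out > 0:
        y *= rms_in / rms_out
    return TimeSeries(y, x.fs, f"{x.label}:reverb")


def synth_heart_lung(
    hr_bpm: float = 72.0,
    breath_rate_bpm: float = 15.0,
    mix_db: float = 0.0,
    fs: float = 4000.0,
    duration_s: float = 60.0,
    seed: int = 0,
) -> tuple[TimeSeries, TimeSeries, TimeSeries, SynthGroundTruth]:
    """Chest auscultation mixture: heart-sound pips over lung noise.

    Heart: per cardiac cycle, an S1 pip (60 Hz decaying tone, tau 40 ms) and
    an S2 pip (110 Hz, tau 30 ms, 70% amplitude) at 30% of the cycle.  Lung:
    100-800 Hz bandpassed noise amplitude-modulated at the respiratory rate.
    The two components overlap in conventional frequency by construction but
    modulate at very different rates, which is what the modulation-domain
    separation exploits.  ``mix_db`` sets the heart/lung power ratio;
    ``mixture = heart + lung`` exactly.

    Returns ``(mixture, heart, lung, ground_truth)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    cycle = 60.0 / hr_bpm
    heart = np.zeros(n)
    pip_len = int(round(0.12 * fs))
    tp = np.arange(pip_len) / fs
    s1 = np.sin(2 * np.pi * 60.0 * tp) * np.exp(-tp / 0.040)
    s2 = 0.7 * np.sin(2 * np.pi * 110.0 * tp) * np.exp(-tp / 0.030)
    beat = 0.2
    while beat < duration_s:
        for pip, off in ((s1, 0.0), (s2, 0.30 * cycle)):
            i0 = int(round((beat + off) * fs))
            hi = min(i0 + pip_len, n)
            if i0 < n:
                heart[i0:hi] += pip[: hi - i0]
        beat += cycle
    sos = sps.butter(4, [100.0, 800.0], btype="bandpass", fs=fs, output="sos")
    lung_carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
    f_resp = breath_rate_bpm / 60.0
    lung_env = 0.35 + 0.65 * (0.5 * (1 + np.cos(2 * np.pi * f_resp * t))) ** 2
    lung = lung_carrier * lung_env
    # scale lung so heart/lung power ratio equals mix_db
    p_h = np.mean(heart**2)
    p_l = np.mean(lung**2)
    lung *= np.sqrt(p_h / (p_l * 10.0 ** (mix_db / 10.0)))
    mixture = heart + lung
    gt = SynthGroundTruth(
        seed=seed,
        params=dict(hr_bpm=hr_bpm, breath_rate_bpm=breath_rate_bpm, mix_db=mix_db,
                    fs=fs, duration_s=duration_s),
        breath_rate_bpm=breath_rate_bpm,
        components={"heart": heart, "lung": lung},
    )
    return (
        TimeSeries(mixture, fs, "auscultation-mixture"),
        TimeSeries(heart, fs, "heart-sounds"),
        TimeSeries(lung, fs, "lung-sounds"),
        gt,
    )


def synth_gait(
    stride_rate_hz: float = 0.9,
    fs: float = 50.0,
    duration_s: float = 60.0,
    asymmetry: float = 0.3,
    seed: int = 0,
) -> tuple[TimeSeries, SynthGroundTruth]:
    """Walking accelerometry: damped oscillations excited at every footfall.

    Steps occur at twice the stride rate; left/right footfalls alternate in
    amplitude by ``1 +- asymmetry``, which is what creates the stride-rate
    (half-step-rate) periodicity that survives in the modulation domain.
    Each footfall excites a damped 6 Hz oscillation; small seeded amplitude
    jitter (5%) keeps steps from being perfectly identical.
    """
    if not (0.0 <= asymmetry < 1.0):
        raise ParameterError("asymmetry must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    step_period = 1.0 / (2.0 * stride_rate_hz)
    imp = np.zeros(n)
    k = 0
    tstep = 0.2
    while tstep < duration_s:
        amp = 1.0 + asymmetry * (1 if k % 2 == 0 else -1)
        amp *= 1.0 + 0.05 * rng.standard_normal()
        i = int(round(tstep * fs))
        if i < n:
            imp[i] = amp
        tstep += step_period
        k += 1
    ring_len = int(round(0.25 * fs))
    tr = np.arange(ring_len) / fs
    ring = np.sin(2 * np.pi * 6.0 * tr) * np.exp(-tr / 0.06)
    x = sps.fftconvolve(imp, ring)[:n]
    gt = SynthGroundTruth(
        seed=seed,
        params=dict(stride_rate_hz=stride_rate_hz, fs=fs, duration_s=duration_s,
                    asymmetry=asymmetry),
        stride_rate_hz=stride_rate_hz,
    )
    return TimeSeries(x, fs, "synthetic-gait"), gt
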