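# modspec

Modulation spectral analysis for wearable physiological signals: quality
measurement, enhancement, blind source separation, and noise-robust feature
extraction for ECG, audio (speech, chest auscultation) and accelerometry.

## The idea

Wearable recordings are routinely corrupted by motion artifacts and sensor
noise that overlap the signal in both time and frequency.  What usually
*does* differ is the rate at which their spectral content changes.  The
modulation spectrogram makes that rate explicit through two cascaded
time-to-frequency transforms:

1. a short-time Fourier transform (or bandpass filterbank + Hilbert
   transform) maps the signal *x(t)* to complex spectrotemporal
   coefficients *X(t, f)*, with phase retained;
2. a Fourier transform along time of each frequency bin's magnitude
   envelope |*X(t, f)*| yields *X(f_mod, f)* — energy as a function of
   modulation frequency *f_mod* (rate of envelope change, Hz) versus
   conventional frequency *f* (Hz).

The first transform's hop sets the envelope sampling rate and hence the
maximum representable *f_mod*; the envelope length sets the *f_mod*
resolution.  A time-resolved variant stacks modulation spectrograms over
sliding frames into an *F × F_m × N* tensor.

In this domain, physiological structure concentrates in known places — a
clean ECG puts its energy in narrow **lobes at harmonics of the heart rate**
along the *f_mod* axis, speech lives in the 2–20 Hz syllabic band, breathing
amplitude-modulates the ECG far below the cardiac lobes, and left/right gait
asymmetry puts a line at the stride rate — while noise spreads in between.
The package builds on that separation:

| capability | function |
|---|---|
| reference-free ECG quality (in/out-of-lobe energy ratio, MS-QI) | `msqi` |
| blind speech reverberation score (below/above 20 Hz *f_mod*, SRMR) | `srmr` |
| invertible modulation-domain FIR filtering and enhancement | `enhance`, `adaptive_enhance_ecg` |
| heart/lung sound separation (power-complementary filters) | `separate_heart_lung` |
| noise-robust heart rate from the fundamental lobe | `estimate_hr` |
| modulation-domain HRV index, SDNN/RMSSD/pNN50 | `hrv_metrics`, `mod_hrv_index` |
| ECG-derived respiration rate | `breathing_rate_from_ecg` |
| gait cadence from accelerometry | `stride_rate_modspec` |
| seeded synthetic generators with ground truth | `modspec.synth` |

## A worked example

```python
import modspec as ms
from modspec.ecg import hr_from_beats

clean, truth = ms.synth.synth_ecg(hr_bpm=60.0, duration_s=60.0, fs=256.0, seed=1)
noisy = ms.synth.add_noise(clean, "white+pink", snr_db=-10.0, seed=2)

print(ms.msqi(clean).score, ms.msqi(noisy).score)
enhanced = ms.adaptive_enhance_ecg(noisy)
print(hr_from_beats(ms.detect_r_peaks(enhanced)))
print(ms.estimate_hr(noisy).bpm)
```

prints (see `examples/ecg_quality_and_enhancement.py` for the full script):

```
MS-QI  clean: score  3.766  HR  60.0 bpm
MS-QI -10 dB: score  0.665  HR  60.1 bpm

beats on enhanced trace : 48 (true 60)
HR from enhanced beats  : 59.96 bpm (error 0.06%)
HR from modulation lobe : 60.10 bpm (no enhancement needed)
```

The quality index collapses from 3.77 to 0.67 as noise drowns the signal —
that is the blind SNR correlate.  At −10 dB the raw trace is useless for
beat detection, but after comb filtering in the modulation domain
(passbands at the detected heart-rate harmonics, everything else rejected)
the beat-derived heart rate is accurate to 0.06%; reading the rate straight
off the fundamental modulation lobe needs no enhancement at all.

Each script under `examples/` demonstrates one capability the same way:
transform + exact reconstruction, breathing from ECG, heart/lung
separation, SRMR under reverberation, and gait cadence.

There is also a thin command-line interface:

```sh
modspec simulate ecg --seed 1 --out ecg.csv
modspec msqi --in ecg.csv
modspec enhance --in ecg.csv --filter comb --f0 auto --out enhanced.csv
```

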