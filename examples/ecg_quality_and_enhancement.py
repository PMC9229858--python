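"""ECG quality scoring and modulation-domain enhancement under heavy noise.

Generates a clean synthetic ECG, corrupts it at -10 dB, scores both with the
modulation-spectrum quality index (MS-QI), then enhances the noisy trace
with an adaptive harmonic comb and recovers the heart rate from detected
beats.  MS-QI drops with noise; the enhanced HR error stays far below the
raw signal's.
"""

import numpy as np

import modspec as ms
from modspec.ecg import hr_from_beats

clean, truth = ms.synth.synth_ecg(hr_bpm=60.0, duration_s=60.0, fs=256.0,
                                  seed=1)
noisy = ms.synth.add_noise(clean, "white+pink", snr_db=-10.0, seed=2)

for label, sig in (("clean", clean), ("-10 dB", noisy)):
    rep = ms.msqi(sig)
    print(f"MS-QI {label:>6}: score {rep.score:6.3f}  "
          f"HR {rep.hr_est_bpm:5.1f} bpm")

enhanced = ms.adaptive_enhance_ecg(noisy)
beats = ms.detect_r_peaks(enhanced)
hr = hr_from_beats(beats)
print(f"\nbeats on enhanced trace : {beats.n_beats} "
      f"(true {truth.r_times.size})")
print(f"HR from enhanced beats  : {hr:.2f} bpm "
      f"(error {abs(hr - 60) / 60 * 100:.2f}%)")
print(f"HR from modulation lobe : {ms.estimate_hr(noisy).bpm:.2f} bpm "
      "(no enhancement needed)")
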