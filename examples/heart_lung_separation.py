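"""Blind separation of heart and lung sounds from one chest recording.

Heart pips and breath noise overlap in conventional frequency but modulate
at very different rates; power-complementary modulation filters split them
while conserving envelope power.  The printed captures say how much of each
true component's energy its output retains.
"""

import numpy as np

import modspec as ms

mix, heart, lung, _ = ms.synth.synth_heart_lung(
    hr_bpm=72.0, breath_rate_bpm=15.0, mix_db=0.0, fs=4000.0,
    duration_s=30.0, seed=5)

split = ms.separate_heart_lung(mix)
h_cap = np.sum(split.heart.samples * heart.samples) / np.sum(heart.samples**2)
l_cap = np.sum(split.lung.samples * lung.samples) / np.sum(lung.samples**2)

print(f"detected cardiac rate   : {split.hr_est_bpm:.1f} bpm (true 72.0)")
print(f"heart energy capture    : {100 * h_cap:.1f}%")
print(f"lung energy capture     : {100 * l_cap:.1f}%")
print(f"unaccounted envelope pwr: {split.residual_energy_pct:.2f}% "
      "(power-complementary contract: < 5%)")
print(f"heart LSD               : {ms.lsd(heart, split.heart):.2f} dB")
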