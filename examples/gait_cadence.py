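"""Gait cadence from noisy accelerometry, modulation domain vs PSD.

Left/right footfall asymmetry creates a stride-rate line in the modulation
spectrum that survives 0 dB of added noise; the conventional Welch-spectrum
comparator only sees the step frequency and degrades faster.
"""

import modspec as ms

x, _ = ms.synth.synth_gait(stride_rate_hz=0.9, fs=50.0, duration_s=60.0,
                           asymmetry=0.3, seed=8)
noisy = ms.synth.add_noise(x, "white", snr_db=0.0, seed=9)

for label, sig in (("clean", x), ("0 dB ", noisy)):
    est = ms.stride_rate_modspec(sig)
    psd = ms.stride_rate_psd(sig)
    print(f"{label}: stride {est.stride_rate_hz:.3f} Hz "
          f"(true 0.900), cadence {est.cadence_steps_per_min:.0f} steps/min, "
          f"PSD peak {psd:.2f} Hz (step frequency)")
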