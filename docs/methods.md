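# Methods

This note records the models and procedures the package implements, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## The two-stage representation

**First transform.** `stft_analysis` frames the signal with a Hamming window
(frame `k` covers samples `[k·hop, k·hop + win)`, centered at
`k·hop + win/2`; frame count `⌊(len − win)/hop⌋ + 1`; segments zero-padded
to `nfft`).  Phase is retained.  The window/hop pair is checked against the
nonzero-overlap-add condition at analysis time, so a configuration that
could not be inverted fails immediately.  `filterbank_hilbert_analysis`
offers the alternative pathway — zero-phase Butterworth bandpasses followed
by the analytic signal — producing one complex envelope per band at the
full signal rate.

**Second transform.** `modulation_spectrogram` Fourier-transforms each
bin's magnitude envelope along time.  Defaults: a boxcar modulation window,
so that one-sided spectral power (DC and Nyquist weighted 1, interior bins
2) conserves envelope energy *exactly* (Parseval; `envelope_energy()`
recovers `Σ_t |X(t,f)|²` to machine precision).  With any other window the
identity holds against the windowed envelope, with the window energy
`Σ w²` recorded on the result.  `mod_nfft` defaults to the next power of
two ≥ 4× the envelope length: the zero padding interpolates the `f_mod`
axis finely enough (≲ 0.1 Hz for a 10 s ECG) for the lobe geometry used by
the quality index.  The per-bin envelope mean (DC) is retained by default —
it is physically meaningful — and `detrend=True` removes it where DC
leakage would obscure low modulation frequencies (respiration, all peak
searches).

**Inverse.** `synthesize` uses least-squares weighted overlap-add: each
frame's inverse FFT is windowed again, accumulated, and divided by the
accumulated squared window.  An unmodified analysis round-trips to machine
precision; modified envelope/phase combinations are projected onto the
nearest consistent signal.  Output is padded/trimmed to the recorded input
length.

**Per-modality first-transform defaults** (window / hop → envelope rate,
max `f_mod`):

| modality | window | hop | env. rate | max f_mod | rationale |
|---|---|---|---|---|---|
| ECG | 125 ms | 31.25 ms | 32 Hz | 16 Hz | cardiac lobes ≤ 4× HR up to 240 bpm |
| speech | 32 ms | 4 ms | 250 Hz | 125 Hz | 2–20 Hz syllabic band + reverberant tail |
| auscultation | 20 ms | 5 ms | 200 Hz | 100 Hz | heart-pip envelopes (~0.1 s bursts) |
| accelerometry | 0.5 s | 0.125 s | 8 Hz | 4 Hz | stride rates ≤ 1.5 Hz plus harmonics |

The time-resolved tensor defaults to 8 s frames hopped by 4 s (2 s for the
HRV index, trading frame count against per-frame resolution).

## Modulation-domain filtering

Filters are odd-length linear-phase FIRs (windowed sinc via `firwin`); a
comb is the sum of per-harmonic bandpasses (same length and delay, so the
sum stays linear-phase).  Group delay `(taps−1)/2` is compensated by
centered convolution.  Default lengths: 257 taps at a 32 Hz envelope rate
(≈ 0.4 Hz transition, so midpoints between comb lobes spaced 1 Hz apart sit
below −30 dB, while the 4 s group delay still fits an 8 s tensor frame) and
501 taps at 250 Hz for speech.

Filtering a magnitude envelope can produce negative values, which a
magnitude cannot be.  Three rectification policies exist: `floor` (default)
and `halfwave` clip to zero; `none` keeps the signed value, carrying the
sign as a phase flip so the chain stays exactly linear — required by the
power-complementary split and by bandwidth expansion.  The fraction of
envelope *energy* removed by flooring is reported (`rectified_fraction`);
an energy-weighted measure is used because sign flips of near-zero cells
would otherwise dominate a cell count without mattering physically.

**Power-complementary splits.** The second filter of a pair is designed on
a dense grid from `sqrt(1 − |H|²)` (`firwin2`); it needs ~4× the taps of
the first to track comb notches, after which `|H|² + |H_c|²` stays within
±1–2% of unity.  The complementarity contract is verified in the envelope
domain, where it mathematically lives; measuring it from re-analyzed
reconstructions adds spectrogram-consistency projection error (up to ~8% on
broadband noise, < 2% on structured signals), which is a property of
inverse-transforming *any* modified spectrogram, not of the filters.

**Bandwidth expansion.** Bandpass modulation filtering (keeping 2–20 Hz for
speech) removes the DC/slow envelope and forces rectification artifacts
("musical noise").  The re-estimation of the 0–2 Hz band implemented here
is deliberately simple and swappable: a per-bin constant offset equal to
the pre-filter envelope mean over *active* frames (broadband envelope above
10% of its maximum), applied to the signed filtered envelope and floored.
It guarantees nonnegativity and restores ≥ 90% of the DC envelope energy on
band-limited test material.

## Quality indices

**MS-QI (ECG).** Harmonic-sum search for the cardiac fundamental in
f_mod ∈ [0.5, 3] Hz (candidates scored `Σ_{k≤4} P(k·f0)/k`; among local
maxima within 5% of the best, the lowest fundamental wins, which resolves
the octave ambiguity of peaky QRS spectra; parabolic sub-bin refinement).
The search runs on modulation power aggregated over the QRS
conventional-frequency band (2–40 Hz) — under heavy pink/low-frequency
noise a full-band aggregation buries the lobes.  The score is then the
full-band energy inside lobes `k·f0 ± 0.3125 Hz` (k = 1..4) over the energy
outside them, within the DC-guarded range (0.125, 8] Hz.  The index is a
ratio of energies, hence amplitude-scale invariant; a flat (noise-only)
spectrum scores ≈ 2.5/5.375 ≈ 0.47 by construction of the band widths.

**SRMR (speech).** Modulation energy in (0.5, 20] Hz over energy in
(20, env_rate/2] Hz, both summed over the frequency axis with Parseval
weights.  Silence is flagged; a near-empty denominator saturates at 10⁶.
This is the base energy-ratio metric; critical-band front-ends and
normalized or hearing-impaired variants are out of scope.

**Log-spectral distance.** Hann frames of 32 ms hopped 16 ms; per frame the
RMS difference of log-power spectra, each floored at −80 dB relative to its
own frame maximum; per-frame values averaged.  The log spectrum of digital
silence is undefined, so the average is taken over frames in which *both*
signals are active (above −60 dB of their own loudest frame) — the
symmetric analogue of speech-active gating.  `lsd(x, x) = 0`; a pure gain
`g` gives `20·log10 g` exactly.

## ECG analytics

*Heart rate* comes from the fundamental lobe (search above), which needs no
beat detection and degrades gracefully: at −10 dB the median error across
noise realizations stays below 0.2%.  *Beat detection* is the classic
energy chain — 5–15 Hz bandpass, squared derivative, 150 ms moving-window
integration, adaptive signal/noise threshold with a 250 ms refractory
period — with beats refined to the bandpassed-magnitude extremum
(polarity-insensitive).  Beat-based heart rate uses `60/median(RR)`: a
missed beat doubles one interval, which a mean absorbs and a median
ignores.

*Adaptive enhancement* rebuilds the signal from a comb at the detected HR
harmonics (K = 4, half-width 0.3125 Hz by default; tensor mode re-centers
the comb per 8 s frame and cross-fades).  The comb excludes DC
deliberately: keeping it retains the stationary noise envelope and beat
detection at −10 dB collapses.  A consequence is that repeated enhancement
is not idempotent in the RMS sense — flooring regenerates a mean envelope
that every pass removes afresh — but the detected beat train and waveform
correlation are stable across passes, which is the property the
applications rely on.

*Modulation-domain HRV.* The fundamental-lobe track across a tensor
(8 s frames, 2 s hop) converted to RR (`1000/f0` ms); the index is the SD of
that track.  Each frame's search is anchored to 0.75–1.33× the
whole-recording fundamental: an unconstrained 8 s frame at −8 dB throws
occasional octave outliers that dominate the spread, while genuine
beat-to-beat variability stays well inside the window.  The index is a
correlate of SDNN (frame averaging attenuates its absolute scale), so it is
validated by correlation against ground truth, not by agreement in ms.

*Respiration.* Respiratory amplitude modulation appears as a line in
f_mod ∈ [0.05, 0.7] Hz of the QRS-band-aggregated modulation spectrum
(Hann modulation window + detrend to keep DC leakage out of the band);
≥ 60 s of signal is required for resolution at 0.05 Hz.  A secondary
estimate reads the sideband spacing around the first cardiac lobe.
Confidence is the peak over the *mean* of the f_mod ∈ [0.05, 8] Hz
spectrum (threshold 3): the mean includes the cardiac lobes and so sets a
physiological scale, where a median would collapse to the near-zero
between-line floor of clean periodic ECG and saturate.

## Heart/lung separation

A comb at the cardiac fundamental's harmonics (up to 16, half-width
0.35 Hz) *plus the DC lobe* forms the heart filter; its power complement
forms the lung filter; conventional-frequency bins above 250 Hz (above the
S1/S2 acoustic band) go wholly to the lung (per-bin filters 0 and 1 —
still power-complementary).  Including DC matters: the pip train's mean
envelope belongs to the heart, and excluding it hands ~30% of the heart's
envelope energy to the lung output.  On the packaged mixtures the heart
output captures ~90% of the true heart component's energy and the lung
~85% of its own, with < 1% of envelope power unaccounted.

**Why the LSD figure stays high on synthetic mixtures.** The separated
heart is benchmarked with the deep-floor LSD above.  The synthetic heart
component is digitally silent between pips, and in those frames the
separated component carries a small lung residual; the −80 dB floor then
charges tens of dB per frame for energy that is inaudibly far below the
pips.  Injecting lung residue at −20 / −30 / −40 dB below the heart
component into an otherwise *perfect* separation scores 18 / 13 / 9 dB
under this metric variant, so sub-dB values are unreachable on these
mixtures by any separation method — they require reference components that
share a recorded noise floor.  The separation quality itself is therefore
asserted through the energy-capture, power-complementarity, pure-input
leakage and determinism tests, and the LSD is reported as-is.

## Gait cadence

The stride estimator aggregates modulation power over 0.5–10 Hz
conventional frequency and searches f_mod ∈ [0.4, 1.5] Hz.  The step line
(2× stride) often falls inside that band and dominates; if the dominant
peak has a subharmonic at half its frequency standing ≥ 8× above its local
spectral floor — the signature of left/right amplitude alternation — the
subharmonic is taken as the stride rate.  The factor 8 sits between
measured noise-peak prominences (~3×) and true stride-line prominences
(> 20×) at 0 dB.  Cadence is `2 × 60 × stride` steps/min; gait *speed*
would need a stride-length model and is out of scope.  The Welch-PSD
comparator (`stride_rate_psd`) returns the raw spectral peak in
[0.4, 3] Hz, which lands on the step frequency when clean and wanders
under noise — the behavior the modulation-domain estimator improves on.

## Synthetic generators

All generators are pure functions of parameters and an integer seed.

- `synth_ecg` — five-Gaussian PQRST template (fixed widths in absolute
  time) repeated at RR intervals from an AR(1) process (lag-1 coefficient
  0.8, stationary SD = `sdnn_ms`, clipped to 0.35–2× the mean RR);
  respiration multiplies the trace by `1 + depth·cos(2πf_resp t)`.  R-peak
  times are returned as ground truth and coincide with the QRS apex to
  within a sample.
- `add_noise` — white, pink (1/f), baseline wander (< 0.5 Hz filtered
  random walk), EMG-like (20–100 Hz gated bursts), or equal-power
  white+pink; always rescaled so the realized SNR is exact.
- `synth_am`, `synth_speechlike`, `apply_reverb` — AM tone with known
  envelope; 300–3400 Hz noise under a raised-cosine syllabic envelope
  (default 4 Hz); reverberation by convolution with exponentially decaying
  white noise whose −60 dB time is RT60.
- `synth_heart_lung` — S1 (60 Hz, τ = 40 ms) and S2 (110 Hz, τ = 30 ms,
  70%) pips per cardiac cycle over 100–800 Hz noise gated at the breath
  rate; components overlap in conventional frequency by construction and
  `mixture = heart + lung` exactly at the stated power ratio.
- `synth_gait` — footfall impulses at 2× the stride rate exciting a damped
  6 Hz oscillation, amplitudes alternating by `1 ± asymmetry` with 5%
  seeded jitter.

**What they do not emulate.** Recorded sensor noise (the synthetic kinds
are stationary or simply gated), electrode-contact transients, PQRST
morphology variation, heart-sound murmurs, true speech phonetics, or
non-steady gait.  Tests passing on these signals demonstrate the mechanics
and noise-robustness of the methods under controlled conditions, not
field performance on device data.

## Numerical notes and limitations

- Seeds: every stochastic routine takes an explicit integer seed;
  `scripts/acceptance.py` derives all trial seeds from its `--seed`.
- Degenerate inputs: empty/non-finite signals, hop > window, non-invertible
  window/hop pairs, bands outside (0, Nyquist) and single-frame modulation
  analyses raise typed errors (`InputError`, `ParameterError`,
  `InsufficientDataError`); the CLI maps them to exit codes 2/2/3.
- Problem sizes in the acceptance script (20 × 60 s HR trials, 30 × 5 min
  HRV recordings, 20 × 2 min respiration trials, 10 × 5 min pNN50
  recordings, 10 × 60 s mixtures) mirror the packaged study conditions and
  complete in well under a minute on one core.
- The continuous-wavelet first-transform pathway, streaming operation,
  multi-microphone processing and EEG applications are out of scope.
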