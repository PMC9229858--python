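"""Internal helpers: peak search on modulation spectra.

Harmonic-sum scoring locates a fundamental modulation frequency whose
harmonics concentrate energy (cardiac lobes, stride lines); 1/k weights damp
the contribution of higher harmonics.  A lower-fundamental preference
resolves the classic octave ambiguity: on peaky spectra the score at twice
the true fundamental can come close to the true score.
"""

from __future__ import annotations

import numpy as np


def parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-bin peak offset from a 3-point parabola around index ``i``.

    Returns the fractional index of the vertex, clamped to ``i +- 0.5``.
    """
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def harmonic_sum_search(
    fmod_axis: np.ndarray,
    pxx: np.ndarray,
    f0_lo: float,
    f0_hi: float,
    n_harmonics: int = 3,
    prefer_lower_tol: float = 0.05,
    refine: bool = True,
) -> tuple[float, float]:
    """Find the fundamental in ``[f0_lo, f0_hi]`` by weighted harmonic sums.

    ``pxx`` is a 1-D modulation power density on ``fmod_axis``.  The score of
    a candidate f0 is ``sum_k (1/k) P(k*f0)`` for ``k = 1..n_harmonics``.
    Among candidates whose score is within ``prefer_lower_tol`` (relative) of
    the maximum, the lowest f0 wins.  The winner is refined by parabolic
    interpolation of the fundamental peak.

    Returns ``(f0_hz, score)``.
    """
    df = fmod_axis[1] - fmod_axis[0]
    cand = np.where((fmod_axis >= f0_lo) & (fmod_axis <= f0_hi))[0]
    if cand.size == 0:
        raise ValueError("empty candidate range for fundamental search")
    scores = np.zeros(cand.size)
    nbins = fmod_axis.size
    for j, i0 in enumerate(cand):
        s = 0.0
        for k in range(1, n_harmonics + 1):
            ik = int(round(i0 * k))
            if ik >= nbins:
                break
            s += pxx[ik] / k
        scores[j] = s
    smax = scores.max()
    if smax <= 0:
        return float(fmod_axis[cand[0]]), 0.0
    # Only local maxima of the score curve are admissible candidates; among
    # those within prefer_lower_tol (relative) of the best, take the lowest.
    from scipy.signal import find_peaks

    pk, _ = find_peaks(scores)
    pk = np.union1d(pk, [int(np.argmax(scores))])
    ok = pk[scores[pk] >= (1.0 - prefer_lower_tol) * smax]
    j = int(ok[0])  # lowest admissible fundamental
    i0 = cand[j]
    f0 = float(fmod_axis[i0])
    if refine:
        # refine on the fundamental lobe itself: local max of pxx near i0
        lo = max(i0 - int(round(0.1 / df)), 1)
        hi = min(i0 + int(round(0.1 / df)) + 1, nbins - 1)
        ip = lo + int(np.argmax(pxx[lo:hi]))
        f0 = float(np.interp(parabolic_refine(pxx, ip), np.arange(nbins), fmod_axis))
    return f0, float(scores[j])
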