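"""Independent oracles used by the test suite.

These deliberately avoid the package's implementation paths:

* brute-force O(n^2) template counting for both entropies, written as plain
  nested Python loops;
* a minimal textbook EMD variant with *different* numerical choices
  (naive pointwise extrema without plateau handling, constant-extension
  envelope boundaries instead of reflection) so agreement between the two
  is evidence about the algorithm, not about shared code.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import CubicSpline


# ---------------------------------------------------------------- entropies


def brute_apen(x, m: int, r: float, lag: int = 1) -> float:
    """Approximate entropy by direct template counting (self-matches in)."""
    x = list(x)
    n = len(x)

    def phi(mm: int) -> float:
        nt = n - (mm - 1) * lag
        templates = [[x[i + k * lag] for k in range(mm)] for i in range(nt)]
        total = 0.0
        for i in range(nt):
            c = sum(
                1
                for j in range(nt)
                if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r
            )
            total += math.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def brute_sampen(x, m: int, r: float, lag: int = 1) -> float:
    """Sample entropy by direct pair counting (self-matches excluded)."""
    x = list(x)
    n = len(x)
    nt = n - m * lag
    a_count = b_count = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            dm = max(abs(x[i + k * lag] - x[j + k * lag]) for k in range(m))
            if dm <= r:
                b_count += 1
                if abs(x[i + m * lag] - x[j + m * lag]) <= r:
                    a_count += 1
    if a_count == 0 or b_count == 0:
        return math.nan
    return -math.log(a_count / b_count)


# --------------------------------------------------------------- textbook EMD


def _ref_extrema(x: np.ndarray):
    mx = [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    mn = [i for i in range(1, len(x) - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]
    return mx, mn


def _ref_envelope(idx, val, n: int) -> np.ndarray:
    # constant extension: clamp the envelope beyond the end-nearest extrema
    pad = n // 10 + 2
    ii = np.concatenate([[-pad], idx, [n - 1 + pad]])
    vv = np.concatenate([[val[0]], val, [val[-1]]])
    t = np.arange(n)
    if ii.size > 3:
        return CubicSpline(ii, vv)(t)
    return np.interp(t, ii, vv)


def _ref_sift(x: np.ndarray, tol: float = 0.05, max_iter: int = 50) -> np.ndarray:
    h = x.copy()
    n = len(x)
    for _ in range(max_iter):
        mx, mn = _ref_extrema(h)
        if len(mx) < 1 or len(mn) < 1:
            break
        upper = _ref_envelope(np.asarray(mx), h[mx], n)
        lower = _ref_envelope(np.asarray(mn), h[mn], n)
        m = 0.5 * (upper + lower)
        sd = float(np.sum(m * m)) / float(np.sum(h * h))
        h = h - m
        if sd < tol:
            break
    return h


def reference_emd(x, max_imf: int = 12):
    """Minimal sifting decomposition; returns (imfs, residue)."""
    x = np.asarray(x, dtype=float)
    imfs = []
    residue = x.copy()
    for _ in range(max_imf):
        mx, mn = _ref_extrema(residue)
        if len(mx) + len(mn) < 3:
            break
        imf = _ref_sift(residue)
        imfs.append(imf)
        residue = residue - imf
    return imfs, residue


def significant_imf_count(imfs, source, energy_frac: float = 0.01) -> int:
    """Number of IMFs carrying at least ``energy_frac`` of the source energy.

    Trailing near-zero modes are boundary-dependent bookkeeping in any EMD
    variant, so cross-implementation count comparisons use this measure.
    """
    e = float(np.sum(np.asarray(source, dtype=float) ** 2))
    return sum(1 for imf in imfs if float(np.sum(np.asarray(imf) ** 2)) >= energy_frac * e)


# ------------------------------------------------------------- test signals


def bandlimited_signal(seed: int, n: int = 1000, fs: float = 100.0):
    """Sum of three well-separated random tones; returns (x, components).

    Components are ordered fast to slow; frequency ratios are kept >= 3.5
    so EMD can cleanly separate them.
    """
    rr = np.random.default_rng(seed)
    t = np.arange(n) / fs
    f = rr.uniform(8, 16)
    comps = []
    for _ in range(3):
        a = rr.uniform(0.7, 1.3)
        comps.append(a * np.sin(2 * np.pi * f * t + rr.uniform(0, 2 * np.pi)))
        f /= rr.uniform(3.5, 5.0)
    return np.sum(comps, axis=0), comps


def butter_lowpass_gain(f: float, cutoff: float, order: int, passes: int = 2) -> float:
    """Magnitude of an analog Butterworth low-pass after ``passes`` passes."""
    one_pass = 1.0 / math.sqrt(1.0 + (f / cutoff) ** (2 * order))
    return one_pass**passes
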