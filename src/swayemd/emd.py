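"""Empirical mode decomposition by envelope sifting.

A signal is decomposed into intrinsic mode functions (IMFs) by repeatedly
subtracting the mean of its upper and lower cubic-spline extrema envelopes
until the remainder oscillates about zero, then peeling that IMF off and
sifting what is left.  IMF1 carries the highest-frequency content; later
IMFs are progressively slower, and decomposition stops when the residue is
monotonic or a configured depth cap is reached.  For quiet-standing
force-plate series the conventional depth is seven IMFs.

The sifting stop rule combines the Cauchy-type criterion
``SD = sum((d_prev - d_new)^2) / sum(d_prev^2) < stop_threshold`` with the
IMF counting condition (numbers of extrema and zero crossings differ by at
most one).  End effects are curbed by symmetric reflection of the two
end-nearest extrema before spline fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import LengthError, NotDecomposableError, ValidationError
from .trial_io import TrialSeries

log = logging.getLogger(__name__)

_MIN_DECOMPOSE_LEN = 16  # spline envelopes are unreliable below this


@dataclass(frozen=True)
class SiftConfig:
    """Tunables of the sifting loop.

    ``max_imf`` is the decomposition depth cap (default 7, the standard
    depth for 100 Hz stabilograms); ``stop_threshold`` is the Cauchy
    sifting tolerance; ``boundary_rule`` is ``"reflect"`` (symmetric
    reflection of end-nearest extrema) or ``"none"``.
    """

    max_imf: int = 7
    max_sift_iterations: int = 50
    stop_threshold: float = 0.05
    boundary_rule: str = "reflect"

    def __post_init__(self) -> None:
        if self.max_imf < 1:
            raise ValidationError("max_imf must be >= 1")
        if self.max_sift_iterations < 1:
            raise ValidationError("max_sift_iterations must be >= 1")
        if self.stop_threshold <= 0:
            raise ValidationError("stop_threshold must be positive")
        if self.boundary_rule not in ("reflect", "none"):
            raise ValidationError(f"unknown boundary rule {self.boundary_rule!r}")


@dataclass
class IMFSet:
    """Ordered IMFs plus residue for one source series.

    The decomposition is complete by construction:
    ``sum(imfs) + residue == source`` up to floating rounding.
    """

    source_channel: str
    imfs: list[np.ndarray]
    residue: np.ndarray

    @property
    def k(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima, in order.

    A plateau (run of equal samples) bounded by opposite slopes counts as a
    single extremum at its midpoint index.  Endpoints are never extrema.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        empty = np.array([], dtype=int)
        return empty, empty
    dx = np.diff(x)
    nz = np.flatnonzero(dx != 0.0)
    if nz.size < 2:
        empty = np.array([], dtype=int)
        return empty, empty
    s = np.sign(dx[nz])
    turn = np.flatnonzero(s[1:] != s[:-1])
    # extremum plateau spans samples nz[t]+1 .. nz[t+1]; take the midpoint
    idx = (nz[turn] + 1 + nz[turn + 1]) // 2
    is_max = s[turn] > 0
    return idx[is_max], idx[~is_max]


def _extend_reflect(
    idx: np.ndarray, val: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two end-nearest knots about each end sample."""
    left_i = (-idx[:2])[::-1]
    left_v = (val[:2])[::-1]
    right_i = (2 * (n - 1) - idx[-2:])[::-1]
    right_v = (val[-2:])[::-1]
    return (
        np.concatenate([left_i, idx, right_i]),
        np.concatenate([left_v, val, right_v]),
    )


def _envelope(idx: np.ndarray, val: np.ndarray, n: int, boundary_rule: str) -> np.ndarray:
    if boundary_rule == "reflect":
        idx, val = _extend_reflect(idx, val, n)
        # reflection of a single knot about both ends can duplicate indices
        idx, keep = np.unique(idx, return_index=True)
        val = val[keep]
    t = np.arange(n)
    if idx.size >= 4:
        return CubicSpline(idx, val)(t)
    return np.interp(t, idx, val)


def envelope_mean(values: Sequence[float], boundary_rule: str = "reflect") -> np.ndarray:
    """Mean of the upper and lower cubic-spline extrema envelopes.

    Raises :class:`NotDecomposableError` when the signal has no interior
    maxima or no interior minima (nothing to hang an envelope on).
    """
    x = np.asarray(values, dtype=float)
    maxi, mini = find_extrema(x)
    if maxi.size < 1 or mini.size < 1:
        raise NotDecomposableError(
            f"need interior extrema of both kinds (got {maxi.size} maxima, "
            f"{mini.size} minima)"
        )
    upper = _envelope(maxi, x[maxi], x.size, boundary_rule)
    lower = _envelope(mini, x[mini], x.size, boundary_rule)
    return 0.5 * (upper + lower)


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _imf_counts_ok(x: np.ndarray) -> bool:
    maxi, mini = find_extrema(x)
    return abs((maxi.size + mini.size) - _zero_crossings(x)) <= 1


def sift(values: Sequence[float], cfg: SiftConfig = SiftConfig()) -> np.ndarray:
    """Extract one IMF from ``values`` by iterative envelope-mean removal."""
    h = np.asarray(values, dtype=float).copy()
    for it in range(cfg.max_sift_iterations):
        try:
            m = envelope_mean(h, cfg.boundary_rule)
        except NotDecomposableError:
            if it == 0:
                raise
            break  # sifting flattened the signal; keep what we have
        denom = float(np.sum(h * h))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        h -= m
        if sd < cfg.stop_threshold and _imf_counts_ok(h):
            break
    else:
        log.warning(
            "sift hit max_sift_iterations=%d without meeting the stop criterion",
            cfg.max_sift_iterations,
        )
    return h


def decompose(series: TrialSeries | Sequence[float], cfg: SiftConfig = SiftConfig()) -> IMFSet:
    """Full decomposition of one series into IMFs and a residue.

    IMFs are peeled off in order of decreasing characteristic frequency
    until the residue is monotonic (no interior extrema), can no longer be
    sifted, or ``cfg.max_imf`` is reached.  A signal with no interior
    extrema of both kinds yields ``k = 0`` with the input as residue.
    """
    if isinstance(series, TrialSeries):
        channel = series.channel
        x = series.values.astype(float)
    else:
        channel = "signal"
        x = np.asarray(series, dtype=float)
    if x.size < _MIN_DECOMPOSE_LEN:
        raise LengthError(
            f"series of length {x.size} too short to decompose "
            f"(minimum {_MIN_DECOMPOSE_LEN})"
        )
    imfs: list[np.ndarray] = []
    residue = x.copy()
    for _ in range(cfg.max_imf):
        maxi, mini = find_extrema(residue)
        if maxi.size < 1 or mini.size < 1:
            break  # monotonic (or trend-only) residue
        try:
            imf = sift(residue, cfg)
        except NotDecomposableError:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(source_channel=channel, imfs=imfs, residue=residue)


def decompose_recording(rec, cfg: SiftConfig = SiftConfig()) -> dict[str, IMFSet]:
    """Decompose all five channels of a recording."""
    return {name: decompose(ser, cfg) for name, ser in rec.channels.items()}
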