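"""Scalar features of raw and EMD-decomposed sway series.

Five features are computed per series: three time-domain statistics and two
regularity (entropy) statistics.

Time domain
    ``mean``  mean of absolute values, ``mean(abs(x))`` — well-defined on
              zero-centered IMFs (a ``signed`` mode is available);
    ``STD``   sample standard deviation (n-1 denominator);
    ``CV``    STD / mean, with the absolute-value mean above.

Regularity
    ``ApEn``  approximate entropy (Pincus): ``Phi^m - Phi^(m+1)`` where
              ``Phi^k`` is the template-wise mean log match frequency under
              the Chebyshev metric, self-matches included;
    ``sample entropy``  (Richman–Moorman): ``-ln(A/B)`` with ``B`` the
              number of m-template pairs within tolerance and ``A`` the
              number of those that still match when extended by one sample,
              self-matches excluded.

Both entropies use embedding dimension ``m``, tolerance
``r = r_fraction * SD`` of the analyzed series (each IMF uses its own SD),
and an optional embedding lag.  Lower values mean a more regular,
predictable series.

Feature names follow the ``channel_level_feature`` scheme, level 0 being
the raw series, e.g. ``COPx_0_ApEn`` or ``Fz_7_STD``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .emd import IMFSet
from .errors import LengthError, UndefinedFeatureError, ValidationError
from .trial_io import CHANNELS, TrialRecording

log = logging.getLogger(__name__)

FEATURE_NAMES = ("mean", "STD", "CV", "ApEn", "sample entropy")


@dataclass(frozen=True)
class EntropyParams:
    """Template parameters shared by both entropy statistics.

    ``r_fraction`` scales the analyzed series' own SD into the Chebyshev
    match radius; ``r_absolute``, when set, overrides it with a fixed
    radius (useful for exactly-periodic inputs and for testing).
    """

    m: int = 2
    r_fraction: float = 0.2
    lag: int = 1
    r_absolute: float | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("embedding dimension m must be >= 1")
        if self.r_absolute is None and self.r_fraction <= 0:
            raise ValidationError("r_fraction must be positive")
        if self.lag < 1:
            raise ValidationError("lag must be >= 1")


@dataclass(frozen=True)
class FeatureRecord:
    """One named scalar feature for one subject (NaN = missing)."""

    subject_id: str
    group: str | None
    name: str
    value: float


def mean_abs(values: Sequence[float]) -> float:
    """Mean of absolute values."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise LengthError("mean of an empty series")
    return float(np.mean(np.abs(x)))


def std(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise LengthError("sample SD needs at least 2 samples")
    return float(np.std(x, ddof=1))


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: SD over mean of absolute values."""
    m = mean_abs(values)
    if m == 0.0:
        raise UndefinedFeatureError("CV undefined: mean(abs(x)) is zero")
    return std(values) / m


@njit(cache=True)
def _entropy_counts(x, m, r, lag):  # pragma: no cover - exercised via wrappers
    """Fused O(n^2) template matching for ApEn and SampEn.

    Returns per-template match counts for lengths m and m+1 (self-matches
    included, for ApEn) and the SampEn pair counts A (length m+1) and B
    (length m), self-matches excluded.
    """
    n = x.shape[0]
    tm = n - (m - 1) * lag  # number of m-templates
    tm1 = n - m * lag  # number of (m+1)-templates
    cm = np.ones(tm)
    cm1 = np.ones(tm1)
    a = 0
    b = 0
    for i in range(tm - 1):
        for j in range(i + 1, tm):
            d = 0.0
            ok = True
            for k in range(m):
                diff = abs(x[i + k * lag] - x[j + k * lag])
                if diff > d:
                    d = diff
                    if d > r:
                        ok = False
                        break
            if not ok:
                continue
            cm[i] += 1.0
            cm[j] += 1.0
            if j < tm1:
                b += 1
                if abs(x[i + m * lag] - x[j + m * lag]) <= r:
                    a += 1
                    cm1[i] += 1.0
                    cm1[j] += 1.0
    return cm, cm1, a, b


def _prepare_entropy(values: Sequence[float], p: EntropyParams):
    x = np.ascontiguousarray(values, dtype=float)
    if x.size <= p.m * p.lag + 1:
        raise LengthError(
            f"series of length {x.size} too short for m={p.m}, lag={p.lag}"
        )
    sd = float(np.std(x, ddof=1))
    if p.r_absolute is not None:
        r = float(p.r_absolute)
    else:
        r = p.r_fraction * sd
    return x, sd, r


def approximate_entropy(values: Sequence[float], p: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy, self-matches included (always finite).

    A zero-variance series returns 0 with a warning so constant IMFs do not
    abort a cohort run.
    """
    x, sd, r = _prepare_entropy(values, p)
    if sd == 0.0:
        log.warning("ApEn of a zero-variance series: returning 0")
        return 0.0
    cm, cm1, _, _ = _entropy_counts(x, p.m, r, p.lag)
    phi_m = float(np.mean(np.log(cm / cm.size)))
    phi_m1 = float(np.mean(np.log(cm1 / cm1.size)))
    return phi_m - phi_m1


def sample_entropy(values: Sequence[float], p: EntropyParams = EntropyParams()) -> float:
    """Sample entropy, self-matches excluded.

    Returns NaN (recorded as missing) when no template pairs match at
    either length, and 0 with a warning for zero-variance input.
    """
    x, sd, r = _prepare_entropy(values, p)
    if sd == 0.0:
        log.warning("SampEn of a zero-variance series: returning 0")
        return 0.0
    _, _, a, b = _entropy_counts(x, p.m, r, p.lag)
    if a == 0 or b == 0:
        log.warning("SampEn undefined (A=%d, B=%d): recording as missing", a, b)
        return math.nan
    return -math.log(a / b)


def _both_entropies(values: Sequence[float], p: EntropyParams) -> tuple[float, float]:
    """(ApEn, SampEn) from a single template-counting pass."""
    x, sd, r = _prepare_entropy(values, p)
    if sd == 0.0:
        log.warning("entropy of a zero-variance series: returning 0")
        return 0.0, 0.0
    cm, cm1, a, b = _entropy_counts(x, p.m, r, p.lag)
    apen = float(np.mean(np.log(cm / cm.size)) - np.mean(np.log(cm1 / cm1.size)))
    if a == 0 or b == 0:
        log.warning("SampEn undefined (A=%d, B=%d): recording as missing", a, b)
        sampen = math.nan
    else:
        sampen = -math.log(a / b)
    return apen, sampen


def _series_features(x: np.ndarray, p: EntropyParams, mean_mode: str) -> dict[str, float]:
    if mean_mode == "abs":
        mean_val = mean_abs(x)
    elif mean_mode == "signed":
        mean_val = float(np.mean(x))
    else:
        raise ValidationError(f"unknown mean_mode {mean_mode!r}")
    std_val = std(x)
    abs_mean = mean_abs(x)
    cv_val = std_val / abs_mean if abs_mean != 0.0 else math.nan
    apen, sampen = _both_entropies(x, p)
    return {
        "mean": mean_val,
        "STD": std_val,
        "CV": cv_val,
        "ApEn": apen,
        "sample entropy": sampen,
    }


def feature_names(max_imf: int = 7) -> list[str]:
    """All feature names in canonical order: channel-major, level, feature."""
    return [
        f"{ch}_{lvl}_{feat}"
        for ch in CHANNELS
        for lvl in range(max_imf + 1)
        for feat in FEATURE_NAMES
    ]


def extract_features(
    rec: TrialRecording,
    imfsets: Mapping[str, IMFSet],
    p: EntropyParams = EntropyParams(),
    mean_mode: str = "abs",
    max_imf: int = 7,
) -> list[FeatureRecord]:
    """All five features on the raw series and each IMF of each channel.

    Always emits exactly ``5 * (1 + max_imf) * 5`` records; levels beyond a
    channel's actual IMF count are emitted with NaN values and flagged in
    the log.
    """
    missing_ch = [c for c in CHANNELS if c not in imfsets]
    if missing_ch:
        raise ValidationError(f"no decomposition for channel(s): {missing_ch}")
    records: list[FeatureRecord] = []
    for ch in CHANNELS:
        imfset = imfsets[ch]
        if imfset.k < max_imf:
            log.warning(
                "subject %s channel %s: only %d of %d IMFs; deeper levels recorded as missing",
                rec.subject_id,
                ch,
                imfset.k,
                max_imf,
            )
        for lvl in range(max_imf + 1):
            if lvl == 0:
                x = rec.channels[ch].values
            elif lvl <= imfset.k:
                x = imfset.imfs[lvl - 1]
            else:
                x = None
            if x is None:
                vals = {feat: math.nan for feat in FEATURE_NAMES}
            else:
                vals = _series_features(np.asarray(x, dtype=float), p, mean_mode)
            for feat in FEATURE_NAMES:
                records.append(
                    FeatureRecord(
                        subject_id=rec.subject_id,
                        group=rec.group,
                        name=f"{ch}_{lvl}_{feat}",
                        value=vals[feat],
                    )
                )
    return records
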