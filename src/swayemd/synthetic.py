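"""Seeded synthetic quiet-standing cohorts.

The generator emulates the statistical structure the pipeline assumes in a
real balance assessment: five channels (Fx, Fy, Fz, COPx, COPy) of 60 s at
100 Hz per subject, each built from band-limited oscillators (random phase,
slow amplitude modulation, Wiener phase jitter) riding on 1/f-shaped
broadband noise around a channel-typical operating point (e.g. body weight
on Fz).  It is not a biomechanical model of posture; it exists so every
pipeline stage is testable without downloading force-plate data.

Two kinds of group contrast can be injected, mirroring the two kinds of
finding such screenings report:

* an amplitude increase of the slowest band in the fall group on selected
  channels (low-frequency sway magnitude, visible in mean/STD features of
  deep IMFs);
* a regularity increase in the mid band of COPx for the fall group,
  implemented as a reduction of that band's phase jitter (visible as lower
  entropy of the mid-level IMFs — more regular anteroposterior sway).

All randomness derives from ``numpy.random.SeedSequence([seed,
subject_seed, channel_index])`` so cohorts are bit-reproducible across
platforms; group effects are applied as deterministic multipliers after
the draws, so a zero-effect spec yields identically distributed groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trial_io import CHANNELS, TrialRecording, TrialSeries

#: Per-subject seed offset of the non-fall group (fall subjects use 0, 1, ...).
NONFALL_SEED_OFFSET = 100_000


@dataclass(frozen=True)
class Band:
    """One band-limited oscillator.

    ``amplitude`` is in channel units (before per-channel gain);
    ``jitter_sd`` is the Wiener phase-noise intensity in rad/sqrt(s) — 0
    gives a pure (perfectly regular) tone; ``amp_delta`` is the relative
    amplitude change applied to the fall group on ``delta_channels``.
    """

    center_hz: float
    amplitude: float
    jitter_sd: float = 0.0
    amp_delta: float = 0.0
    delta_channels: tuple[str, ...] = ()


def default_bands() -> list[Band]:
    """Three bands spanning the content of a 100 Hz stabilogram.

    A fast 8 Hz component (physiological tremor range), a 1.2 Hz mid band
    carrying the regularity contrast, and a 0.3 Hz slow-sway band carrying
    the fall group's +30% low-frequency amplitude excess on COPy and Fz.
    """
    return [
        Band(center_hz=8.0, amplitude=0.35, jitter_sd=3.0),
        Band(center_hz=1.2, amplitude=1.0, jitter_sd=2.2),
        Band(
            center_hz=0.3,
            amplitude=1.4,
            jitter_sd=0.8,
            amp_delta=0.30,
            delta_channels=("COPy", "Fz"),
        ),
    ]


#: Channel operating point, dynamic gain, and noise share of the gain.
DEFAULT_CHANNEL_PROFILE = {
    "Fx": (1.0, 0.8, 0.5),
    "Fy": (-0.5, 0.8, 0.5),
    "Fz": (700.0, 2.0, 0.5),
    "COPx": (-1.1, 0.5, 0.5),
    "COPy": (0.1, 0.4, 0.5),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror a typical elderly balance study: 27 fallers vs 49
    non-fallers, 60 s trials at 100 Hz.  ``regularity_effect`` is the
    fractional reduction of the mid band's phase jitter in the fall group
    on ``regularity_channel`` (0 = no contrast; 0.5 = jitter halved, i.e.
    markedly more regular anteroposterior sway in fallers).
    """

    n_fall: int = 27
    n_nonfall: int = 49
    fs: float = 100.0
    duration: float = 60.0
    seed: int = 0
    bands: tuple[Band, ...] = field(default_factory=lambda: tuple(default_bands()))
    regularity_effect: float = 0.5
    regularity_channel: str = "COPx"
    regularity_band: int = 1
    noise_sd: float = 1.0
    am_depth: float = 0.25

    def __post_init__(self) -> None:
        if self.n_fall < 0 or self.n_nonfall < 0:
            raise ValidationError("group sizes must be non-negative")
        if self.fs <= 0 or self.duration <= 0:
            raise ValidationError("fs and duration must be positive")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("duration * fs must be an integer sample count")
        for b in self.bands:
            if not 0 < b.center_hz < self.fs / 2:
                raise ValidationError(
                    f"band center {b.center_hz} Hz outside (0, Nyquist={self.fs / 2})"
                )
        if not 0 <= self.regularity_effect < 1:
            raise ValidationError("regularity_effect must be in [0, 1)")
        if self.regularity_channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.regularity_channel!r}")
        if self.regularity_effect > 0 and not 0 <= self.regularity_band < len(self.bands):
            raise ValidationError("regularity_band index out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD noise with a 1/f amplitude spectrum (DC removed)."""
    nf = n // 2 + 1
    spec = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    f = np.fft.rfftfreq(n)
    w = np.zeros(nf)
    w[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * w, n)
    return x / np.std(x)


def _slow_modulation(rng: np.random.Generator, n: int, fs: float, depth: float) -> np.ndarray:
    """Amplitude envelope 1 + depth*z(t), z a smooth unit-SD slow process."""
    knot_every = int(round(5 * fs))  # one knot per 5 s
    n_knots = max(3, n // knot_every + 2)
    knots = rng.standard_normal(n_knots)
    t_knots = np.linspace(0, n - 1, n_knots)
    z = np.interp(np.arange(n), t_knots, knots)
    z = z - np.mean(z)
    sd = np.std(z)
    if sd > 0:
        z /= sd
    return 1.0 + depth * z


def generate_trial(
    spec: SyntheticCohortSpec, group: str, subject_seed: int
) -> TrialRecording:
    """One subject's five-channel recording, reproducible from the seeds."""
    if group not in ("fall", "non_fall"):
        raise ValidationError(f"unknown group {group!r}")
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    channels: dict[str, TrialSeries] = {}
    for ci, ch in enumerate(CHANNELS):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, subject_seed, ci])
        )
        offset, gain, noise_frac = DEFAULT_CHANNEL_PROFILE[ch]
        sig = np.zeros(n)
        for bi, band in enumerate(spec.bands):
            phase0 = rng.uniform(0, 2 * np.pi)
            # Wiener phase noise: variance grows linearly in time
            steps = rng.standard_normal(n)
            jitter_scale = band.jitter_sd / np.sqrt(spec.fs)
            am = _slow_modulation(rng, n, spec.fs, spec.am_depth)
            # group effects are deterministic multipliers applied after all
            # draws, so zero-effect groups are identically distributed
            if (
                group == "fall"
                and bi == spec.regularity_band
                and ch == spec.regularity_channel
            ):
                jitter_scale *= 1.0 - spec.regularity_effect
            amp = band.amplitude
            if group == "fall" and ch in band.delta_channels:
                amp *= 1.0 + band.amp_delta
            phase = 2 * np.pi * band.center_hz * t + phase0 + jitter_scale * np.cumsum(steps)
            sig += amp * am * np.sin(phase)
        noise = _pink_noise(rng, n)
        values = offset + gain * (sig + spec.noise_sd * noise_frac * noise)
        channels[ch] = TrialSeries(ch, spec.fs, values)
    sid = f"{'F' if group == 'fall' else 'N'}{subject_seed:05d}"
    return TrialRecording(subject_id=sid, group=group, channels=channels)


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """All subjects of a cohort plus their metadata table.

    Per-subject seeds are ``0..n_fall-1`` for fallers and
    ``NONFALL_SEED_OFFSET..`` for non-fallers, so the two groups never
    share random streams and cohorts are extendable without reshuffling.
    """
    if spec.n_fall + spec.n_nonfall == 0:
        raise ValidationError("cohort must contain at least one subject")
    recordings: list[TrialRecording] = []
    for i in range(spec.n_fall):
        recordings.append(generate_trial(spec, "fall", i))
    for j in range(spec.n_nonfall):
        recordings.append(generate_trial(spec, "non_fall", NONFALL_SEED_OFFSET + j))
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "group": [r.group for r in recordings],
        }
    )
    return recordings, meta


def null_spec(spec: SyntheticCohortSpec) -> SyntheticCohortSpec:
    """Copy of ``spec`` with every group contrast switched off."""
    bands = tuple(replace(b, amp_delta=0.0) for b in spec.bands)
    return replace(spec, bands=bands, regularity_effect=0.0)
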