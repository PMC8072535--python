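"""Reading, writing and preprocessing of quiet-standing force-plate trials.

A trial is five synchronized series sampled at a common rate: three ground
reaction forces (Fx, Fy, Fz, in N) and the center-of-pressure excursions in
the anteroposterior (COPx) and mediolateral (COPy) directions.  Files that
ship moments (Mx, My) instead of COP are supported: COP is derived from the
moment balance at ingestion.

Preprocessing follows the standard posturography convention: a low-pass
Butterworth filter applied forward and backward so the net phase shift is
zero ("zero-lag" filtering).  Public force-plate datasets are usually
distributed already filtered, so re-filtering is opt-in at the pipeline
level to avoid double smoothing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import (
    DegenerateLoadError,
    FormatError,
    LabelError,
    LengthError,
    ValidationError,
)

#: Canonical channel order used everywhere downstream.
CHANNELS = ("Fx", "Fy", "Fz", "COPx", "COPy")

GROUPS = ("fall", "non_fall")

#: Column-name aliases (lower-cased) accepted in trial files.
DEFAULT_ALIASES: Mapping[str, str] = {
    "fx": "Fx",
    "fy": "Fy",
    "fz": "Fz",
    "copx": "COPx",
    "cop_x": "COPx",
    "cop x": "COPx",
    "copap": "COPx",
    "cop_ap": "COPx",
    "copy": "COPy",
    "cop_y": "COPy",
    "cop y": "COPy",
    "copml": "COPy",
    "cop_ml": "COPy",
    "mx": "Mx",
    "my": "My",
    "mz": "Mz",
}


@dataclass(frozen=True)
class TrialSeries:
    """One channel of a trial: a finite real series at a fixed sampling rate."""

    channel: str
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if v.ndim != 1 or v.size < 2:
            raise ValidationError(
                f"channel {self.channel!r}: need a 1-D series of length >= 2"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"channel {self.channel!r}: non-finite samples")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class TrialRecording:
    """A subject's five synchronized channels plus their group label.

    ``group`` may be ``None`` until metadata is joined; cohort-level code
    requires it to be ``"fall"`` or ``"non_fall"``.
    """

    subject_id: str
    group: str | None
    channels: dict[str, TrialSeries]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise FormatError(f"missing channel(s): {', '.join(missing)}")
        fs = {s.fs for s in self.channels.values()}
        n = {len(s) for s in self.channels.values()}
        if len(fs) != 1 or len(n) != 1:
            raise FormatError("all channels must share sampling rate and length")
        if self.group is not None and self.group not in GROUPS:
            raise LabelError(f"unknown group label {self.group!r}")

    @property
    def fs(self) -> float:
        return self.channels[CHANNELS[0]].fs

    @property
    def n_samples(self) -> int:
        return len(self.channels[CHANNELS[0]])


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design applied with zero phase lag.

    ``order`` is the order of the one-pass design; forward–backward
    application doubles the effective magnitude roll-off.
    """

    cutoff: float = 10.0
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")


@dataclass(frozen=True)
class CsvDialect:
    """How trial files are laid out on disk.

    Delimited text with one header row; ``#``-prefixed comment lines may
    carry ``key=value`` metadata (``fs``, ``units``).  A time column, when
    present, is ignored in favor of the declared sampling rate.
    """

    delimiter: str = ","
    fs: float = 100.0
    cop_units: str = "cm"
    aliases: Mapping[str, str] = field(default_factory=lambda: DEFAULT_ALIASES)
    pad_height: float = 0.0


def compute_cop(
    fz: TrialSeries,
    mx: TrialSeries,
    my: TrialSeries,
    pad_height: float = 0.0,
    fx: TrialSeries | None = None,
    fy: TrialSeries | None = None,
) -> tuple[TrialSeries, TrialSeries]:
    """Derive COP excursions from the moment balance about the plate origin.

    COPx = -My/Fz (anteroposterior), COPy = Mx/Fz (mediolateral).  When the
    support surface sits ``pad_height`` meters above the plate origin (e.g.
    a foam balance pad), the shear forces contribute ``-Fx*h/Fz`` and
    ``-Fy*h/Fz`` correction terms; these require ``fx``/``fy``.
    Units follow the inputs: N and N*m give COP in m.
    """
    fzv = fz.values
    if np.any(fzv == 0.0):
        raise DegenerateLoadError("Fz contains zero samples; COP undefined")
    copx = -my.values / fzv
    copy = mx.values / fzv
    if pad_height != 0.0:
        if fx is None or fy is None:
            raise ValidationError("pad-height correction requires Fx and Fy")
        copx = copx - fx.values * pad_height / fzv
        copy = copy - fy.values * pad_height / fzv
    return (
        TrialSeries("COPx", fz.fs, copx),
        TrialSeries("COPy", fz.fs, copy),
    )


def zero_lag_lowpass(series: TrialSeries, spec: FilterSpec) -> TrialSeries:
    """Apply the low-pass Butterworth filter with zero net phase shift.

    The filter is designed at ``spec.order`` and run forward then backward
    (``sosfiltfilt``), so the magnitude response is squared and the phase
    response cancels.
    """
    if not 0 < spec.cutoff < series.fs / 2:
        raise ValidationError(
            f"cutoff {spec.cutoff} Hz not inside (0, fs/2) for fs={series.fs}"
        )
    sos = _sig.butter(spec.order, spec.cutoff, btype="low", fs=series.fs, output="sos")
    # sosfiltfilt needs samples beyond its edge padding to be stable
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(series) <= padlen:
        raise LengthError(
            f"series of length {len(series)} too short for order-{spec.order} "
            f"zero-lag filtering (needs > {padlen})"
        )
    if not spec.zero_lag:
        out = _sig.sosfilt(sos, series.values)
    else:
        out = _sig.sosfiltfilt(sos, series.values)
    return replace(series, values=np.asarray(out, dtype=float))


def _parse_header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_trial(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    subject_id: str | None = None,
    group: str | None = None,
) -> TrialRecording:
    """Read one trial file into a :class:`TrialRecording`.

    Columns are resolved case-insensitively through ``dialect.aliases``.
    Files must provide the five canonical channels directly, or
    Fx/Fy/Fz/Mx/My from which COP is derived via :func:`compute_cop`.
    A ``# fs=<Hz>`` comment line overrides ``dialect.fs``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such trial file: {path}")
    meta = _parse_header_meta(path)
    fs = float(meta.get("fs", dialect.fs))
    try:
        # round_trip parsing so write/read cycles are bit-identical
        df = pd.read_csv(
            path, sep=dialect.delimiter, comment="#", float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty trial file") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: trial file has no data rows")

    resolved: dict[str, np.ndarray] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        canon = dialect.aliases.get(key)
        if canon is not None and canon not in resolved:
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise FormatError(f"{path}: non-numeric values in column {col!r}")
            resolved[canon] = vals

    for name in ("Fx", "Fy", "Fz"):
        if name not in resolved:
            raise FormatError(f"{path}: missing required column {name!r}")

    series = {
        name: TrialSeries(name, fs, resolved[name]) for name in ("Fx", "Fy", "Fz")
    }
    if "COPx" in resolved and "COPy" in resolved:
        series["COPx"] = TrialSeries("COPx", fs, resolved["COPx"])
        series["COPy"] = TrialSeries("COPy", fs, resolved["COPy"])
    elif "Mx" in resolved and "My" in resolved:
        mx = TrialSeries("Mx", fs, resolved["Mx"])
        my = TrialSeries("My", fs, resolved["My"])
        series["COPx"], series["COPy"] = compute_cop(
            series["Fz"], mx, my, dialect.pad_height, series["Fx"], series["Fy"]
        )
    else:
        raise FormatError(
            f"{path}: missing column 'COPx'/'COPy' (or 'Mx'/'My' to derive them)"
        )

    sid = subject_id if subject_id is not None else path.stem
    return TrialRecording(subject_id=sid, group=group, channels=series)


def write_trial(
    rec: TrialRecording, path: str | Path, dialect: CsvDialect = CsvDialect()
) -> None:
    """Write the canonical five-channel trial CSV.

    Floats are formatted with 17 significant digits so a write/read cycle
    reproduces values bit-identically.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# fs={rec.fs!r}\n")
    buf.write(f"# cop_units={dialect.cop_units}\n")
    buf.write(dialect.delimiter.join(CHANNELS) + "\n")
    cols = [rec.channels[c].values for c in CHANNELS]
    for row in zip(*cols):
        buf.write(dialect.delimiter.join(f"{v:.17g}" for v in row) + "\n")
    path.write_text(buf.getvalue())


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata table (columns: subject_id, group, ...).

    Group labels are normalized (``nonfall``/``non-fall`` -> ``non_fall``)
    and validated.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such metadata file: {path}")
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    for need in ("subject_id", "group"):
        if need not in cols:
            raise FormatError(f"{path}: metadata lacks column {need!r}")
    df = df.rename(columns={cols["subject_id"]: "subject_id", cols["group"]: "group"})
    df["subject_id"] = df["subject_id"].astype(str)
    df["group"] = (
        df["group"].astype(str).str.strip().str.lower().str.replace("-", "_")
    )
    df.loc[df["group"] == "nonfall", "group"] = "non_fall"
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise LabelError(f"{path}: unknown group label(s) {bad}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"{path}: duplicate subject_id(s) {dupes}")
    return df
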