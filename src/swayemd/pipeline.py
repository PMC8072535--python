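"""End-to-end orchestration: ingest -> decompose -> extract -> compare.

Every stage boundary is a plain CSV so intermediates can be inspected and
re-run independently; floats are written with 17 significant digits so
reruns are byte-identical.  A run manifest (config, versions, seed, counts)
is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    ComparisonRow,
    FeatureTable,
    build_table,
    compare_groups,
    comparison_frame,
    significant_features,
)
from .emd import IMFSet, SiftConfig, decompose_recording
from .errors import SwayEMDError, ValidationError
from .features import EntropyParams, extract_features
from .trial_io import (
    CHANNELS,
    CsvDialect,
    FilterSpec,
    TrialRecording,
    read_metadata,
    read_trial,
    zero_lag_lowpass,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a cohort run, serializable to/from a YAML mapping."""

    filter: FilterSpec = FilterSpec()
    filter_enabled: bool = False  # public datasets usually ship pre-filtered
    sift: SiftConfig = SiftConfig()
    entropy: EntropyParams = EntropyParams()
    alpha: float = 0.05
    mean_mode: str = "abs"
    ttest_variant: str = "welch"
    bh_correct: bool = False
    dialect: CsvDialect = CsvDialect()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                    if f.name != "aliases"
                }
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "filter" in d:
            kwargs["filter"] = FilterSpec(**d.pop("filter"))
        if "sift" in d:
            kwargs["sift"] = SiftConfig(**d.pop("sift"))
        if "entropy" in d:
            kwargs["entropy"] = EntropyParams(**d.pop("entropy"))
        if "dialect" in d:
            kwargs["dialect"] = CsvDialect(**d.pop("dialect"))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def imfset_frame(imfset: IMFSet, max_imf: int) -> pd.DataFrame:
    """IMFs and residue as columns imf1..imfK, residue (missing levels NaN)."""
    data = {}
    for i in range(max_imf):
        if i < imfset.k:
            data[f"imf{i + 1}"] = imfset.imfs[i]
        else:
            data[f"imf{i + 1}"] = np.full(imfset.residue.size, np.nan)
    data["residue"] = imfset.residue
    return pd.DataFrame(data)


def process_recording(
    rec: TrialRecording, cfg: PipelineConfig
) -> tuple[dict[str, IMFSet], list]:
    """Decompose one recording and extract its feature records."""
    if cfg.filter_enabled:
        rec = TrialRecording(
            subject_id=rec.subject_id,
            group=rec.group,
            channels={
                name: zero_lag_lowpass(s, cfg.filter)
                for name, s in rec.channels.items()
            },
        )
    imfsets = decompose_recording(rec, cfg.sift)
    records = extract_features(
        rec, imfsets, cfg.entropy, cfg.mean_mode, cfg.sift.max_imf
    )
    return imfsets, records


def run_recordings(
    recordings: Sequence[TrialRecording],
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> tuple[FeatureTable, list[ComparisonRow], dict]:
    """Run decompose -> extract -> compare on in-memory recordings.

    When ``out_dir`` is given, per-channel IMF CSVs, long/wide feature
    tables, the comparison table and a run manifest are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "imf").mkdir(parents=True, exist_ok=True)

    all_records = []
    for rec in recordings:
        imfsets, records = process_recording(rec, cfg)
        all_records.extend(records)
        ks = {ch: imfsets[ch].k for ch in CHANNELS}
        log.info("subject %s: IMF counts %s", rec.subject_id, ks)
        if out is not None:
            for ch in CHANNELS:
                imfset_frame(imfsets[ch], cfg.sift.max_imf).to_csv(
                    out / "imf" / f"{rec.subject_id}_{ch}.csv",
                    index=False,
                    float_format=_FLOAT_FMT,
                )

    table = build_table(all_records)
    rows = compare_groups(table, cfg.alpha, cfg.ttest_variant, cfg.bh_correct)
    sig = significant_features(rows, cfg.alpha)
    summary = {
        "n_subjects": table.n_subjects,
        "n_features": table.n_features,
        "n_significant": len(sig),
        "significant_features": [r.feature for r in sig],
    }

    if out is not None:
        long_df = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in all_records],
                "group": [r.group for r in all_records],
                "feature": [r.name for r in all_records],
                "value": [r.value for r in all_records],
            }
        )
        long_df.to_csv(out / "features_long.csv", index=False, float_format=_FLOAT_FMT)
        wide = table.values.copy()
        wide.insert(0, "group", table.groups)
        wide.to_csv(out / "features_wide.csv", float_format=_FLOAT_FMT)
        comparison_frame(rows).to_csv(
            out / "comparison.csv", index=False, float_format=_FLOAT_FMT
        )
        manifest = {
            "package": "swayemd",
            "version": __version__,
            "python": platform.python_version(),
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            **{k: v for k, v in summary.items() if k != "significant_features"},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return table, rows, summary


def run_pipeline(
    trial_paths: Sequence[str | Path],
    metadata_path: str | Path,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """File-based end-to-end run; returns the summary counts."""
    meta = read_metadata(metadata_path)
    groups = dict(zip(meta["subject_id"], meta["group"]))
    recordings = []
    for p in sorted(Path(p) for p in trial_paths):
        sid = p.stem
        if sid not in groups:
            raise SwayEMDError(f"ingest: subject {sid!r} not in metadata")
        recordings.append(
            read_trial(p, cfg.dialect, subject_id=sid, group=groups[sid])
        )
    if not recordings:
        raise SwayEMDError("ingest: no trial files matched")
    _, _, summary = run_recordings(recordings, cfg, out_dir)
    return summary
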