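"""Cohort aggregation and per-feature two-group screening.

Feature records are assembled into a wide subjects-by-features table and
each feature is tested for a fall vs non-fall difference with a two-sample
t-test (Welch by default; pooled-variance Student's optional).  Missing
values are dropped pairwise per feature.  Significance is strict
``p < alpha`` with the usual star convention (* p < 0.05, ** p < 0.01).
No multiple-testing correction is applied by default; an optional
Benjamini–Hochberg adjustment is available for users who want it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import IntegrityError, LabelError, ValidationError
from .features import FEATURE_NAMES, FeatureRecord
from .trial_io import GROUPS

log = logging.getLogger(__name__)

#: Table ordering convention: time-domain features first, then entropies.
_FEATURE_RANK = {name: i for i, name in enumerate(FEATURE_NAMES)}


@dataclass
class FeatureTable:
    """Wide cohort table: one row per subject, one column per feature."""

    values: pd.DataFrame  # index: subject_id, columns: feature names
    groups: pd.Series  # index: subject_id -> "fall" | "non_fall"

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ComparisonRow:
    """Per-feature group descriptives and test result."""

    feature: str
    fall_mean: float
    fall_sd: float
    nonfall_mean: float
    nonfall_sd: float
    t_stat: float
    p_value: float
    significant: bool
    stars: str


def build_table(records: Iterable[FeatureRecord]) -> FeatureTable:
    """Pivot long feature records into a wide table, validating integrity."""
    recs = list(records)
    if not recs:
        raise IntegrityError("no feature records")
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recs],
            "group": [r.group for r in recs],
            "feature": [r.name for r in recs],
            "value": [r.value for r in recs],
        }
    )
    dup = df.duplicated(subset=["subject_id", "feature"])
    if dup.any():
        pair = df.loc[dup, ["subject_id", "feature"]].iloc[0]
        raise IntegrityError(
            f"duplicate record for subject {pair.subject_id!r}, "
            f"feature {pair.feature!r}"
        )
    groups = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
    bad = sorted(set(groups) - set(GROUPS))
    if bad:
        raise LabelError(f"unknown group label(s): {bad}")
    wide = df.pivot(index="subject_id", columns="feature", values="value")
    # preserve first-seen feature order rather than pandas' lexicographic one
    order = list(dict.fromkeys(df["feature"]))
    wide = wide[order]
    wide.columns.name = None
    return FeatureTable(values=wide, groups=groups.loc[wide.index])


def _stars(p: float) -> str:
    if not math.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    table: FeatureTable,
    alpha: float = 0.05,
    variant: str = "welch",
    bh_correct: bool = False,
) -> list[ComparisonRow]:
    """Two-sample t-test of fall vs non-fall for every feature.

    Features with fewer than two non-missing values in a group, or zero
    variance in both groups, get a missing (NaN) p-value and a warning
    rather than aborting the run.  ``bh_correct`` replaces raw p-values
    with Benjamini–Hochberg adjusted ones before flagging.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if variant not in ("welch", "student"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    fall_mask = (table.groups == "fall").to_numpy()
    non_mask = (table.groups == "non_fall").to_numpy()
    a = table.values.to_numpy(dtype=float)[fall_mask]  # fall x features
    b = table.values.to_numpy(dtype=float)[non_mask]

    with np.errstate(invalid="ignore", divide="ignore"):
        na = np.sum(np.isfinite(a), axis=0)
        nb = np.sum(np.isfinite(b), axis=0)
        fm = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=0)
        nm = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=0)
        fsd = np.full(a.shape[1], math.nan)
        nsd = np.full(b.shape[1], math.nan)
        fsd[na > 1] = np.nanstd(a[:, na > 1], axis=0, ddof=1)
        nsd[nb > 1] = np.nanstd(b[:, nb > 1], axis=0, ddof=1)
        res = _stats.ttest_ind(
            a, b, axis=0, equal_var=(variant == "student"), nan_policy="omit"
        )
        tstats = np.asarray(res.statistic, dtype=float).copy()
        pvals = np.asarray(res.pvalue, dtype=float).copy()

    feats = list(table.values.columns)
    too_few = (na < 2) | (nb < 2)
    degenerate = ~too_few & (fsd == 0.0) & (nsd == 0.0)
    for i in np.flatnonzero(too_few):
        log.warning("feature %s: <2 values in a group; p recorded missing", feats[i])
    for i in np.flatnonzero(degenerate):
        log.warning("feature %s: zero variance in both groups", feats[i])
    bad = too_few | degenerate
    tstats[bad] = math.nan
    pvals[bad] = math.nan

    if bh_correct:
        pvals = np.asarray(_bh_adjust(pvals))

    rows: list[ComparisonRow] = []
    for i, feat in enumerate(feats):
        p = float(pvals[i])
        rows.append(
            ComparisonRow(
                feature=feat,
                fall_mean=float(fm[i]),
                fall_sd=float(fsd[i]),
                nonfall_mean=float(nm[i]),
                nonfall_sd=float(nsd[i]),
                t_stat=float(tstats[i]),
                p_value=p,
                significant=bool(math.isfinite(p) and p < alpha),
                stars=_stars(p),
            )
        )
    return rows


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    mask = np.isfinite(p)
    out = p.copy()
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out.tolist()


def _row_sort_key(row: ComparisonRow):
    feat_type = row.feature.rsplit("_", 1)[-1] if "_" in row.feature else row.feature
    return (_FEATURE_RANK.get(feat_type, len(_FEATURE_RANK)), row.feature)


def significant_features(
    rows: Sequence[ComparisonRow], alpha: float = 0.05
) -> list[ComparisonRow]:
    """Rows with p < alpha, time-domain features listed before entropies."""
    hits = [r for r in rows if math.isfinite(r.p_value) and r.p_value < alpha]
    return sorted(hits, key=_row_sort_key)


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a tidy DataFrame (one row per feature)."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "fall_mean": [r.fall_mean for r in rows],
            "fall_sd": [r.fall_sd for r in rows],
            "nonfall_mean": [r.nonfall_mean for r in rows],
            "nonfall_sd": [r.nonfall_sd for r in rows],
            "t": [r.t_stat for r in rows],
            "p": [r.p_value for r in rows],
            "stars": [r.stars for r in rows],
        }
    )


def report_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Publication-style report: "mean (sd)" strings per group plus p."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "fall": [f"{r.fall_mean:.3f} ({r.fall_sd:.3f})" for r in rows],
            "non_fall": [f"{r.nonfall_mean:.3f} ({r.nonfall_sd:.3f})" for r in rows],
            "p": [
                f"{r.p_value:.3f} {r.stars}".strip() if math.isfinite(r.p_value) else ""
                for r in rows
            ],
        }
    )
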