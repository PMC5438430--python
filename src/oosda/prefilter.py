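"""Contaminant, batch-specific, outlier and replicate-concordance filters.

These are the early pipeline stages that discard unreliable features and
samples before any normalization or latent-variable modeling.  Filters only
remove rows/columns; surviving values are never modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FeatureTable, ValidationError, align_metadata

__all__ = [
    "FilterReport",
    "blank_filter",
    "remove_batch_specific",
    "log2_transform",
    "tic_outlier_filter",
    "replicate_concordance_filter",
]


@dataclass
class FilterReport:
    """Record of one filtering step: what was removed and why."""

    step_name: str
    removed_ids: list[str] = field(default_factory=list)
    criterion_values: dict[str, float] = field(default_factory=dict)
    threshold_used: float = float("nan")
    flagged_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step_name,
                "id": self.removed_ids,
                "statistic": [
                    self.criterion_values.get(i, float("nan"))
                    for i in self.removed_ids
                ],
                "threshold": self.threshold_used,
            }
        )


def blank_filter(
    table: FeatureTable, samples: pd.DataFrame, ratio: float = 0.01
) -> tuple[FeatureTable, FilterReport]:
    """Remove contaminant features using solvent-blank injections.

    A feature is a contaminant when its median intensity over blank samples
    exceeds ``ratio`` (default 1%) of its maximum intensity over all other
    samples.  Blank non-detections count as 0 (absence in a blank is
    evidence of absence); non-blank missing cells are ignored when taking
    the maximum.  Operates on raw intensities only.
    """
    if table.scale != "raw":
        raise ValidationError("blank_filter is defined on raw intensities")
    meta = align_metadata(table, samples)
    is_blank = (meta["sample_type"] == "blank").to_numpy()
    if not is_blank.any():
        raise ValidationError(
            "no blank samples present; skip the blank filter explicitly"
        )
    if is_blank.all():
        raise ValidationError("no non-blank samples present")
    blanks = np.nan_to_num(table.values[:, is_blank], nan=0.0)
    blank_median = np.median(blanks, axis=1)
    others = table.values[:, ~is_blank]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        other_max = np.nanmax(others, axis=1)
    other_max = np.nan_to_num(other_max, nan=0.0)
    contaminant = blank_median > ratio * other_max
    report = FilterReport(
        "blank_filter",
        [f for f, c in zip(table.feature_ids, contaminant) if c],
        {
            f: float(m)
            for f, m, c in zip(table.feature_ids, blank_median, contaminant)
            if c
        },
        threshold_used=ratio,
    )
    return table.select_features(~contaminant), report


def remove_batch_specific(
    table: FeatureTable,
    samples: pd.DataFrame,
    min_batches: int = 2,
) -> tuple[FeatureTable, FilterReport]:
    """Remove features detected in fewer than ``min_batches`` batches.

    With the default of 2 this drops features whose every detection among
    non-blank samples falls in a single batch — the conservative reading of
    "batch specific".  Features with no detections at all are removed too.
    """
    meta = align_metadata(table, samples)
    nonblank = (meta["sample_type"] != "blank").to_numpy()
    batches = meta["batch"].to_numpy()[nonblank]
    uniq = np.unique(batches)
    if len(uniq) < 2:
        warnings.warn(
            "fewer than two batches among non-blank samples; "
            "batch-specific filter is a no-op",
            stacklevel=2,
        )
        return table, FilterReport("remove_batch_specific", threshold_used=min_batches)
    detected = ~np.isnan(table.values[:, nonblank])
    # per-feature census of batches with >=1 detection
    n_batches = np.zeros(table.n_features, dtype=int)
    for b in uniq:
        n_batches += detected[:, batches == b].any(axis=1)
    remove = n_batches < min_batches
    report = FilterReport(
        "remove_batch_specific",
        [f for f, r in zip(table.feature_ids, remove) if r],
        {
            f: float(n)
            for f, n, r in zip(table.feature_ids, n_batches, remove)
            if r
        },
        threshold_used=min_batches,
    )
    return table.select_features(~remove), report


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Replace every detected intensity x by log2(x); keeps the raw matrix
    alongside so ion-count statistics (TIC) remain available."""
    if table.scale != "raw":
        raise ValidationError("table is already on the log2 scale")
    bad = np.nonzero(table.values <= 0)
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise ValidationError(
            "non-positive intensity at feature "
            f"{table.feature_ids[r]!r}, sample {table.sample_ids[c]!r}; "
            "zeros must be masked at read time"
        )
    out = table.copy()
    out.raw_values = table.values.copy()
    out.values = np.log2(out.values)
    out.scale = "log2"
    return out


def tic_outlier_filter(
    table: FeatureTable, samples: pd.DataFrame, fraction: float = 0.7
) -> tuple[FeatureTable, FilterReport]:
    """Drop failed injections by total ion count.

    TIC is the per-sample sum of detected raw-scale intensities (the raw
    matrix is used even after the log2 transform).  A non-blank sample is
    removed when its TIC is below ``fraction`` (default 70%) of the mean
    TIC over all non-blank samples, outliers included.  Blanks are exempt.
    """
    raw = table.raw_values if table.scale == "log2" else table.values
    if raw is None:
        raise ValidationError("raw intensities unavailable for TIC")
    meta = align_metadata(table, samples)
    nonblank = (meta["sample_type"] != "blank").to_numpy()
    if nonblank.sum() < 2:
        raise ValidationError("need at least two non-blank samples")
    tic = np.nansum(np.where(np.isnan(raw), 0.0, raw), axis=0)
    cutoff = fraction * tic[nonblank].mean()
    low = (tic < cutoff) & nonblank
    if low.sum() == nonblank.sum():
        raise ValidationError("TIC filter would remove every sample")
    removed = [s for s, r in zip(table.sample_ids, low) if r]
    report = FilterReport(
        "tic_outlier_filter",
        removed,
        {s: float(t) for s, t, r in zip(table.sample_ids, tic, low) if r},
        threshold_used=float(cutoff),
    )
    keep = [s for s in table.sample_ids if s not in set(removed)]
    return table.select_samples(keep), report


def replicate_concordance_filter(
    table: FeatureTable,
    samples: pd.DataFrame,
    r_min: float = 0.8,
    min_shared: int = 3,
) -> tuple[FeatureTable, FilterReport]:
    """Remove replicate spectra that agree with none of their siblings.

    Within each replicate group, a spectrum is kept iff its best Pearson
    correlation against any other member of the (original) group exceeds
    ``r_min``.  Correlations use features detected in both spectra; pairs
    sharing fewer than ``min_shared`` features yield an undefined r and the
    sample is flagged rather than removed.  The pass is non-cascading:
    removals do not change the comparison set.
    """
    if table.scale != "log2":
        raise ValidationError("replicate filter expects log2 intensities")
    meta = align_metadata(table, samples)
    report = FilterReport("replicate_concordance", threshold_used=r_min)
    drop: set[str] = set()
    nonblank = meta[meta["sample_type"] != "blank"]
    for group, members in nonblank.groupby("replicate_group", sort=False):
        ids = [s for s in members["sample_id"] if s in set(table.sample_ids)]
        if len(ids) < 2:
            if ids:
                warnings.warn(
                    f"replicate group {group!r} has a single member; kept",
                    stacklevel=2,
                )
            continue
        cols = {s: table.sample_ids.index(s) for s in ids}
        for s in ids:
            best = -np.inf
            defined = False
            x = table.values[:, cols[s]]
            for t in ids:
                if t == s:
                    continue
                y = table.values[:, cols[t]]
                shared = ~np.isnan(x) & ~np.isnan(y)
                if shared.sum() < min_shared:
                    continue
                xs, ys = x[shared], y[shared]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                defined = True
                best = max(best, float(np.corrcoef(xs, ys)[0, 1]))
            if not defined:
                report.flagged_ids.append(s)
            elif best <= r_min:
                drop.add(s)
                report.criterion_values[s] = best
    report.removed_ids = [s for s in table.sample_ids if s in drop]
    keep = [s for s in table.sample_ids if s not in drop]
    return table.select_samples(keep), report
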