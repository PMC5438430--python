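"""Core data containers and delimited-text I/O for LC-MS feature tables.

A feature table holds per-feature intensities across samples (features are
rows, samples are columns, matching the convention that each column is one
MS spectrum).  Missing values (features not detected / not linked in a
sample) are encoded as NaN in the value matrix; every downstream statistic
ignores NaN cells unless it states otherwise.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "ValidationError",
    "SAMPLE_TYPES",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "validate_sample_metadata",
    "drop_uncharged_features",
]

#: canonical sample-type vocabulary: solvent blanks, vehicle controls,
#: compound-treated samples and pooled QC injections.
SAMPLE_TYPES = ("blank", "control", "treated", "qc")

FEATURE_META_COLUMNS = ("feature_id", "mz", "rt", "charge")
SAMPLE_META_COLUMNS = (
    "sample_id",
    "sample_type",
    "batch",
    "injection_order",
    "replicate_group",
    "compound",
    "class_label",
)


class ValidationError(ValueError):
    """An input table or metadata file violates a documented contract."""


@dataclass
class FeatureTable:
    """Feature-by-sample intensity matrix with metadata.

    Parameters
    ----------
    values : ndarray, shape (n_features, n_samples)
        Intensities; NaN marks a missing (not-detected) cell.  Non-negative
        on the raw scale; unrestricted after log2 transform.
    feature_meta : DataFrame
        One row per feature with columns ``feature_id`` (unique), ``mz``
        (Da), ``rt`` (seconds) and ``charge`` (0 = unestablished).
    sample_ids : list of str
        Column labels, in column order.
    scale : {"raw", "log2"}
        Current intensity scale.  The raw->log2 transition happens exactly
        once per pipeline run.
    raw_values : ndarray, optional
        Raw-scale matrix retained after the log2 transform so that
        ion-count statistics (TIC) stay defined on raw intensities.
    """

    values: np.ndarray
    feature_meta: pd.DataFrame
    sample_ids: list[str]
    scale: str = "raw"
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.sample_ids = list(self.sample_ids)
        n_feat, n_samp = self.values.shape
        if len(self.sample_ids) != n_samp:
            raise ValidationError(
                f"{n_samp} columns but {len(self.sample_ids)} sample ids"
            )
        if len(self.feature_meta) != n_feat:
            raise ValidationError(
                f"{n_feat} rows but {len(self.feature_meta)} feature records"
            )
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        dup = pd.Index(self.sample_ids)[pd.Index(self.sample_ids).duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample id(s): {sorted(set(dup))}")
        fid = self.feature_meta["feature_id"]
        if fid.duplicated().any():
            raise ValidationError(
                f"duplicate feature_id(s): {sorted(fid[fid.duplicated()].unique())}"
            )
        if self.scale == "raw":
            with np.errstate(invalid="ignore"):
                bad = np.nonzero(self.values < 0)
            if bad[0].size:
                r, c = bad[0][0], bad[1][0]
                raise ValidationError(
                    "negative intensity at feature "
                    f"{fid.iloc[r]!r}, sample {self.sample_ids[c]!r}"
                )

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.feature_meta["feature_id"])

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            self.feature_meta.copy().reset_index(drop=True),
            list(self.sample_ids),
            self.scale,
            None if self.raw_values is None else self.raw_values.copy(),
        )

    def select_features(self, keep: np.ndarray) -> "FeatureTable":
        """Return a table restricted to the rows flagged in ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        else:
            idx = keep
        return FeatureTable(
            self.values[idx],
            self.feature_meta.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
            self.scale,
            None if self.raw_values is None else self.raw_values[idx],
        )

    def select_samples(self, keep_ids: Iterable[str]) -> "FeatureTable":
        """Return a table restricted to the given sample ids (in table order)."""
        keep = set(keep_ids)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return FeatureTable(
            self.values[:, idx],
            self.feature_meta.copy().reset_index(drop=True),
            [self.sample_ids[i] for i in idx],
            self.scale,
            None if self.raw_values is None else self.raw_values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame (features x samples)."""
        return pd.DataFrame(
            self.values, index=self.feature_meta["feature_id"].to_numpy(),
            columns=self.sample_ids,
        )


# ----------------------------------------------------------------------
# Reading / writing


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_feature_table(
    path: str | Path,
    dialect: str = "tsv",
    na_sentinel: str = "NA",
    zero_is_missing: bool = True,
) -> FeatureTable:
    """Read a delimited feature table.

    Layout: optional ``# scale=...`` comment line, then a header of
    ``feature_id, mz, rt, charge, <sample ids...>``.  Empty cells and the
    ``na_sentinel`` become missing.  With ``zero_is_missing`` (the default,
    appropriate for feature-linker exports where 0 denotes a failed link)
    literal zeros are masked as well.
    """
    path = Path(path)
    scale = "raw"
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "scale=" in first:
                scale = first.split("scale=")[1].strip()
            text = fh.read()
        else:
            text = first + fh.read()
    raw_header = text.split("\n", 1)[0].rstrip("\r").split(_sep(dialect))
    if raw_header[:4] != list(FEATURE_META_COLUMNS):
        raise ValidationError(
            f"expected leading columns {FEATURE_META_COLUMNS}, "
            f"got {raw_header[:4]}"
        )
    sample_ids = raw_header[4:]
    dup = [s for s in set(sample_ids) if sample_ids.count(s) > 1]
    if dup:
        raise ValidationError(f"duplicate sample id(s) in header: {sorted(dup)}")
    df = pd.read_csv(
        io.StringIO(text), sep=_sep(dialect), na_values=[na_sentinel],
        keep_default_na=False, dtype={"feature_id": str},
    )
    df.columns = raw_header
    meta = df[list(FEATURE_META_COLUMNS)].copy()
    meta["charge"] = meta["charge"].astype(int)
    values = df[sample_ids].to_numpy(dtype=float)
    if zero_is_missing and scale == "raw":
        values[values == 0] = np.nan
    table = FeatureTable(values, meta.reset_index(drop=True), sample_ids, scale)
    return table


def write_feature_table(
    table: FeatureTable, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a feature table; missing cells serialize as ``NA`` and the
    scale is recorded in a leading ``# scale=`` comment line."""
    sep = _sep(dialect)
    out = table.feature_meta[list(FEATURE_META_COLUMNS)].copy()
    frame = pd.DataFrame(table.values, columns=table.sample_ids)
    out = pd.concat([out.reset_index(drop=True), frame], axis=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scale={table.scale}\n")
        out.to_csv(fh, sep=sep, index=False, na_rep="NA")


# ----------------------------------------------------------------------
# Sample metadata


def read_sample_metadata(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read and validate per-sample annotations.

    Required columns: sample_id, sample_type, batch, injection_order,
    replicate_group, compound, class_label.  Returns a DataFrame indexed by
    sample_id with ``sample_type`` normalized to lower case.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    return validate_sample_metadata(df)


def validate_sample_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample metadata missing column(s): {missing}")
    df = df[list(SAMPLE_META_COLUMNS)].copy()
    df["sample_type"] = df["sample_type"].str.strip().str.lower()
    bad = sorted(set(df["sample_type"]) - set(SAMPLE_TYPES))
    if bad:
        raise ValidationError(
            f"unknown sample_type(s) {bad}; allowed: {list(SAMPLE_TYPES)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id(s): {dup}")
    df["injection_order"] = df["injection_order"].astype(int)
    if (df["injection_order"] < 1).any():
        raise ValidationError("injection_order must be >= 1 (1-based)")
    if df["injection_order"].duplicated().any():
        dup = df.loc[df["injection_order"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate injection_order for sample(s): {dup}")
    nonblank = df["sample_type"] != "blank"
    empty_rep = nonblank & (df["replicate_group"].str.strip() == "")
    if empty_rep.any():
        names = df.loc[empty_rep, "sample_id"].tolist()
        raise ValidationError(
            f"missing replicate_group for non-blank sample(s): {names}"
        )
    return df.set_index("sample_id", drop=False)


def align_metadata(table: FeatureTable, samples: pd.DataFrame) -> pd.DataFrame:
    """Metadata rows matching the table's columns, in column order."""
    missing = [s for s in table.sample_ids if s not in samples.index]
    if missing:
        raise ValidationError(f"no metadata for sample(s): {missing}")
    return samples.loc[table.sample_ids]


# ----------------------------------------------------------------------
# Charge filter


def drop_uncharged_features(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Remove features whose charge state was never established (charge 0).

    Feature linking upstream is charge-agnostic, so uncharged entries are
    typically unreliable; they are dropped before any statistics.
    Returns the filtered table and the removed feature ids.
    """
    charge = table.feature_meta["charge"].to_numpy()
    keep = charge >= 1
    removed = [fid for fid, k in zip(table.feature_ids, keep) if not k]
    out = table.select_features(keep)
    if out.n_features == 0:
        warnings.warn("all features removed by the charge filter", stacklevel=2)
    return out, removed
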