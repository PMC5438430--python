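"""End-to-end pipeline orchestration.

Fixed stage order (skippable, never reorderable):

1. charge filter  2. blank filter (+ drop blanks)  3. batch-specific filter
4. log2 transform  5. TIC outlier filter + replicate concordance
6. cyclic LOESS  7. shift removal (OOS-DA)  8. batch removal (OOS-DA)
9. replicate merging

Each run writes the corrected table, per-step filter reports and a JSON
manifest sufficient to re-execute identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import correct_unwanted_variation, merge_replicates, pca_subtract
from .normalize import cyclic_loess
from .prefilter import (
    blank_filter,
    log2_transform,
    remove_batch_specific,
    replicate_concordance_filter,
    tic_outlier_filter,
)
from .table import (
    FeatureTable,
    ValidationError,
    drop_uncharged_features,
    read_feature_table,
    read_sample_metadata,
    write_feature_table,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "PIPELINE_STEPS"]

PIPELINE_STEPS = (
    "charge_filter",
    "blank_filter",
    "batch_specific",
    "log2",
    "tic_outlier",
    "replicate_concordance",
    "cyclic_loess",
    "correct_shift",
    "correct_batch",
    "merge_replicates",
)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their default values."""

    blank_ratio: float = 0.01
    tic_fraction: float = 0.7
    replicate_r_min: float = 0.8
    batch_specific_min_batches: int = 2
    loess_span: float = 0.7
    loess_iterations: int = 3
    k_shift: int = 2
    k_batch: int = 8
    shift_break: int = 55
    anchor_compound: str = "Mebendazole"
    d_shift: int | str = "auto"
    d_batch: int | str = "auto"
    d_max: int | None = None
    d_rel_tol: float = 0.01
    pca_subtract_q: int = 3
    n_perm: int = 10000
    sep_dims: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.blank_ratio < 1:
            raise ValidationError("blank_ratio must be in (0, 1)")
        if not 0 < self.tic_fraction < 1:
            raise ValidationError("tic_fraction must be in (0, 1)")
        if not -1 <= self.replicate_r_min <= 1:
            raise ValidationError("replicate_r_min must be in [-1, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    version: str = __version__
    started: str = ""
    finished: str = ""
    steps: list = field(default_factory=list)
    tuning: dict = field(default_factory=dict)

    def log_step(self, name: str, n_feat: int, n_samp: int, removed: int) -> None:
        self.steps.append(
            {
                "step": name,
                "n_features": n_feat,
                "n_samples": n_samp,
                "n_removed": removed,
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2), encoding="utf-8"
        )


def run_pipeline(
    table: FeatureTable | str | Path,
    samples: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    skip: set[str] | None = None,
    use_pca_subtraction: bool = False,
) -> tuple[FeatureTable, pd.DataFrame, RunManifest]:
    """Run the full correction pipeline.

    Accepts in-memory objects or file paths.  ``skip`` names stages from
    :data:`PIPELINE_STEPS` to leave out.  With ``use_pca_subtraction`` the
    two supervised removal stages are replaced by the unsupervised
    top-q-principal-component subtraction (comparison mode).
    Returns the final table, the metadata of surviving samples, and the
    run manifest; writes outputs when ``out_dir`` is given.
    """
    cfg = config or PipelineConfig()
    skip = set(skip or ())
    unknown = skip - set(PIPELINE_STEPS)
    if unknown:
        raise ValidationError(f"unknown step name(s) in skip: {sorted(unknown)}")
    if isinstance(samples, (str, Path)):
        samples = read_sample_metadata(samples)
    if isinstance(table, (str, Path)):
        table = read_feature_table(table)

    manifest = RunManifest(config=asdict(cfg))
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    reports = []

    def log(name: str, before: FeatureTable, after: FeatureTable) -> None:
        removed = (before.n_features - after.n_features) + (
            before.n_samples - after.n_samples
        )
        manifest.log_step(name, after.n_features, after.n_samples, removed)

    current = table
    try:
        if "charge_filter" not in skip:
            prev = current
            current, removed = drop_uncharged_features(current)
            log("charge_filter", prev, current)

        if "blank_filter" not in skip:
            prev = current
            current, rep = blank_filter(current, samples, cfg.blank_ratio)
            reports.append(rep)
            # blanks have served their purpose; later stages are blank-free
            nonblank = samples.loc[
                samples["sample_type"] != "blank", "sample_id"
            ]
            current = current.select_samples(nonblank)
            log("blank_filter", prev, current)

        if "batch_specific" not in skip:
            prev = current
            current, rep = remove_batch_specific(
                current, samples, cfg.batch_specific_min_batches
            )
            reports.append(rep)
            log("batch_specific", prev, current)

        if "log2" not in skip:
            current = log2_transform(current)
            manifest.log_step("log2", current.n_features, current.n_samples, 0)

        if "tic_outlier" not in skip:
            prev = current
            current, rep = tic_outlier_filter(current, samples, cfg.tic_fraction)
            reports.append(rep)
            log("tic_outlier", prev, current)

        if "replicate_concordance" not in skip:
            prev = current
            current, rep = replicate_concordance_filter(
                current, samples, cfg.replicate_r_min
            )
            reports.append(rep)
            log("replicate_concordance", prev, current)

        if "cyclic_loess" not in skip:
            current = cyclic_loess(
                current, cfg.loess_span, cfg.loess_iterations
            )
            manifest.log_step(
                "cyclic_loess", current.n_features, current.n_samples, 0
            )

        if use_pca_subtraction:
            if "correct_shift" not in skip or "correct_batch" not in skip:
                current = pca_subtract(current, cfg.pca_subtract_q)
                manifest.log_step(
                    "pca_subtract", current.n_features, current.n_samples, 0
                )
        else:
            if "correct_shift" not in skip:
                current, corr = correct_unwanted_variation(
                    current, samples, nuisance="shift", k=cfg.k_shift,
                    d=cfg.d_shift, anchor_compound=cfg.anchor_compound,
                    shift_break=cfg.shift_break, d_max=cfg.d_max,
                    rel_tol=cfg.d_rel_tol,
                )
                manifest.tuning["shift"] = {
                    "d": int(corr.d_), "k": int(corr.k_used_),
                    "b_curve": None if corr.tuning_curve_ is None
                    else corr.tuning_curve_.b_values.tolist(),
                }
                manifest.log_step(
                    "correct_shift", current.n_features, current.n_samples, 0
                )

            if "correct_batch" not in skip:
                current, corr = correct_unwanted_variation(
                    current, samples, nuisance="batch", k=cfg.k_batch,
                    d=cfg.d_batch, anchor_compound=cfg.anchor_compound,
                    d_max=cfg.d_max, rel_tol=cfg.d_rel_tol,
                )
                manifest.tuning["batch"] = {
                    "d": int(corr.d_), "k": int(corr.k_used_),
                    "b_curve": None if corr.tuning_curve_ is None
                    else corr.tuning_curve_.b_values.tolist(),
                }
                manifest.log_step(
                    "correct_batch", current.n_features, current.n_samples, 0
                )

        out_samples = samples.loc[
            [s for s in samples["sample_id"] if s in set(current.sample_ids)]
        ]
        if "merge_replicates" not in skip:
            current, out_samples = merge_replicates(current, samples)
            manifest.log_step(
                "merge_replicates", current.n_features, current.n_samples, 0
            )
    except Exception as err:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            manifest.write(out_dir / "manifest.json")
        raise RuntimeError(
            f"pipeline aborted in stage "
            f"{manifest.steps[-1]['step'] if manifest.steps else 'input'}: {err}"
        ) from err

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_feature_table(current, out_dir / "corrected_table.tsv")
        out_samples.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
        if reports:
            pd.concat([r.to_frame() for r in reports]).to_csv(
                out_dir / "filter_report.tsv", sep="\t", index=False
            )
        manifest.write(out_dir / "manifest.json")
    return current, out_samples, manifest
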