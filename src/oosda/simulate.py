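"""Synthetic multi-batch LC-MS-like experiments with known ground truth.

The generator emulates a cell-exposure metabolomics design: several
compounds from a few pharmacological classes measured in biological
replicates, one anchor compound replicated in every preparation batch,
vehicle controls, and solvent blanks.  On top of a clean log2 signal it
layers the technical artifacts the pipeline is built to remove: additive
low-rank batch offsets, a step shift at a known injection-order index,
linear intensity decay over the injection sequence, contaminant features
visible in blanks, and intensity-dependent missingness (cells below a raw
detection threshold are masked).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .table import FeatureTable, validate_sample_metadata

__all__ = ["SimConfig", "SimTruth", "simulate_experiment", "evaluate_recovery"]

ANCHOR_COMPOUND = "Mebendazole"

#: balanced +-1 design rows for up to 4 batches x 3 latent directions;
#: columns are mutually orthogonal and centered, so a rank-q batch effect
#: built from the first q columns is exactly rank q.
_BATCH_DESIGN = np.array(
    [
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, -1.0],
        [1.0, -1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]
)


@dataclass
class SimConfig:
    """Parameters of a simulated experiment.

    Defaults mirror a four-batch pilot design: 27 compounds x 3 biological
    replicates, 3 anchor replicates + 3 controls + 6 blanks per batch
    (129 injections total) and ~3800 features.  Effect sizes are per-feature
    root-mean-square shifts in log2 units.
    """

    n_features: int = 3800
    n_compounds: int = 27
    n_replicates: int = 3
    n_batches: int = 4
    anchors_per_batch: int = 3
    n_controls_per_batch: int = 3
    n_blanks_per_batch: int = 6
    n_classes: int = 5
    base_log_mean: float = 18.0
    base_log_sd: float = 2.5
    bio_sd: float = 0.2
    class_effect_size: float = 1.0
    class_effect_fraction: float = 0.1
    batch_effect_rank: int = 2
    batch_effect_size: float = 0.6
    batch_coeff_jitter: float = 0.15
    shift_injection_index: int = 55
    shift_size: float = 0.8
    decay_rate: float = 0.005
    contaminant_fraction: float = 0.02
    blank_level_drop: float = 8.0
    missing_threshold: float = 2.0**11
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_features", "n_compounds", "n_replicates", "n_batches",
            "anchors_per_batch", "n_controls_per_batch", "n_blanks_per_batch",
            "n_classes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("class_effect_fraction", "contaminant_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 1 <= self.batch_effect_rank <= 3:
            raise ValueError("batch_effect_rank must be 1, 2 or 3")
        if self.n_batches > _BATCH_DESIGN.shape[0]:
            raise ValueError("at most 4 batches supported by the batch design")

    @property
    def n_samples(self) -> int:
        return (
            self.n_compounds * self.n_replicates
            + self.n_batches
            * (self.anchors_per_batch + self.n_controls_per_batch
               + self.n_blanks_per_batch)
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment: everything needed to
    reconstruct the observed matrix from the clean one."""

    clean_log2: np.ndarray                 # p x N, technical-artifact-free
    technical_log2: np.ndarray             # p x N additive technical part
    batch_directions: np.ndarray           # q x p unit vectors
    batch_coefficients: np.ndarray         # n_batches x q
    shift_direction: np.ndarray            # p-vector (unit)
    shift_magnitude: float
    class_effect_features: dict = field(default_factory=dict)
    contaminant_features: list = field(default_factory=list)
    decay_per_injection: float = 0.0
    missing_mask: np.ndarray | None = None
    config: SimConfig | None = None

    def observed_log2(self) -> np.ndarray:
        return self.clean_log2 + self.technical_log2


def _sample_layout(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    class_names = [f"class_{c + 1}" for c in range(cfg.n_classes)]
    # treated compounds, replicates spread across batches
    for ci in range(cfg.n_compounds):
        compound = f"Compound{ci + 1:02d}"
        label = class_names[ci % cfg.n_classes]
        for r in range(cfg.n_replicates):
            batch = (ci + r) % cfg.n_batches + 1
            rows.append(
                dict(
                    sample_id=f"{compound}_r{r + 1}",
                    sample_type="treated", batch=f"B{batch}",
                    replicate_group=f"rg_{compound}", compound=compound,
                    class_label=label,
                )
            )
    # anchor replicates in every batch
    for b in range(cfg.n_batches):
        for r in range(cfg.anchors_per_batch):
            rows.append(
                dict(
                    sample_id=f"Meb_b{b + 1}_r{r + 1}",
                    sample_type="treated", batch=f"B{b + 1}",
                    replicate_group=f"rg_{ANCHOR_COMPOUND}",
                    compound=ANCHOR_COMPOUND, class_label="anchor",
                )
            )
    # vehicle controls, replicate trios spanning batches
    n_ctrl = cfg.n_batches * cfg.n_controls_per_batch
    for j in range(n_ctrl):
        rows.append(
            dict(
                sample_id=f"Ctrl_{j + 1:02d}",
                sample_type="control", batch=f"B{j % cfg.n_batches + 1}",
                replicate_group=f"rg_ctrl_{j // cfg.n_batches + 1}",
                compound="DMSO", class_label="control",
            )
        )
    # solvent blanks
    for b in range(cfg.n_batches):
        for j in range(cfg.n_blanks_per_batch):
            rows.append(
                dict(
                    sample_id=f"Blank_b{b + 1}_{j + 1}",
                    sample_type="blank", batch=f"B{b + 1}",
                    replicate_group="", compound="DMSO", class_label="blank",
                )
            )
    meta = pd.DataFrame(rows)
    meta["injection_order"] = rng.permutation(len(meta)) + 1
    return validate_sample_metadata(meta)


def simulate_experiment(
    cfg: SimConfig | None = None, **overrides
) -> tuple[FeatureTable, pd.DataFrame, SimTruth]:
    """Generate one synthetic experiment.

    Returns the observed raw-scale feature table (with intensity-dependent
    missingness applied), the sample metadata, and the ground truth.
    Deterministic under ``cfg.seed``.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = SimConfig(**{**asdict(cfg), **overrides})
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_features
    meta = _sample_layout(cfg, rng)
    N = len(meta)
    is_blank = (meta["sample_type"] == "blank").to_numpy()
    order = meta["injection_order"].to_numpy()
    batch_idx = meta["batch"].str.lstrip("B").astype(int).to_numpy() - 1

    # ---- clean biological signal (log2)
    baseline = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=p)
    clean = np.tile(baseline[:, None], (1, N))
    contam = rng.random(p) < cfg.contaminant_fraction
    # blanks carry solvent background only, except for contaminants which
    # appear at full strength in every injection
    clean[:, is_blank] -= np.where(contam, 0.0, cfg.blank_level_drop)[:, None]

    class_features: dict[str, dict] = {}
    labels = meta["class_label"].to_numpy()
    for cname in sorted(set(labels) - {"blank", "control", "anchor"}):
        affected = np.nonzero(rng.random(p) < cfg.class_effect_fraction)[0]
        signs = rng.choice([-1.0, 1.0], size=len(affected))
        cols = np.nonzero(labels == cname)[0]
        clean[np.ix_(affected, cols)] += (
            cfg.class_effect_size * signs[:, None]
        )
        class_features[cname] = {
            "features": affected.tolist(), "signs": signs.tolist()
        }
    clean += rng.normal(0.0, cfg.bio_sd, size=(p, N))

    # ---- technical artifacts (additive in log2)
    q = cfg.batch_effect_rank
    V = rng.normal(size=(q, p))
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    C = _BATCH_DESIGN[: cfg.n_batches, :q].copy()
    C += cfg.batch_coeff_jitter * rng.normal(size=C.shape)
    scale = cfg.batch_effect_size * np.sqrt(p / q)
    batch_offsets = scale * (C @ V)  # n_batches x p
    technical = batch_offsets[batch_idx].T  # p x N

    u = rng.normal(size=p)
    u /= np.linalg.norm(u)
    shift_mag = cfg.shift_size * np.sqrt(p)
    post = order > cfg.shift_injection_index
    technical[:, post] += shift_mag * u[:, None]

    technical -= cfg.decay_rate * (order - 1)[None, :]
    technical += rng.normal(0.0, cfg.noise_sd, size=(p, N))

    observed = clean + technical
    raw = np.power(2.0, observed)
    mask = raw < cfg.missing_threshold
    raw = np.where(mask, np.nan, raw)

    feature_meta = pd.DataFrame(
        {
            "feature_id": [f"F{i + 1:05d}" for i in range(p)],
            "mz": np.round(rng.uniform(130.0, 900.0, size=p), 4),
            "rt": np.round(rng.uniform(0.0, 1500.0, size=p), 2),
            "charge": rng.choice([0, 1, 1, 1, 2], size=p),
        }
    )
    table = FeatureTable(raw, feature_meta, list(meta["sample_id"]), "raw")
    truth = SimTruth(
        clean_log2=clean,
        technical_log2=technical,
        batch_directions=V,
        batch_coefficients=C,
        shift_direction=u,
        shift_magnitude=float(shift_mag),
        class_effect_features=class_features,
        contaminant_features=feature_meta.loc[contam, "feature_id"].tolist(),
        decay_per_injection=cfg.decay_rate,
        missing_mask=mask,
        config=cfg,
    )
    return table, meta, truth


# ----------------------------------------------------------------------
# Recovery evaluation


def _direct_s_sep(values: np.ndarray, labels: np.ndarray) -> float:
    """Separation score in feature space; masked cells are imputed to the
    per-feature mean so the missingness pattern itself carries no signal."""
    from .septest import separation_score

    means = np.nanmean(values, axis=1, keepdims=True)
    means = np.where(np.isnan(means), 0.0, means)
    X = np.where(np.isnan(values), means, values)
    return separation_score(X, labels)


def _null_s_sep(
    values: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
    n_perm: int = 200,
) -> float:
    return float(
        np.median(
            [_direct_s_sep(values, rng.permutation(labels)) for _ in range(n_perm)]
        )
    )


def evaluate_recovery(
    corrected: FeatureTable,
    observed: FeatureTable,
    samples: pd.DataFrame,
    truth: SimTruth,
    seed: int = 0,
) -> dict:
    """Quantify how much nuisance structure a correction removed and how
    much class signal it kept.

    Separation scores are evaluated directly in the (zero-imputed) feature
    space for batch labels, shift labels and true class labels, before
    (``observed``) and after (``corrected``); null levels come from label
    permutations on the corrected data.  RMSE against the clean matrix is
    computed on cells detected in both tables.  All tables must share the
    same scale and be restricted to non-blank samples of the simulation.
    """
    if corrected.values.shape != observed.values.shape:
        raise ValueError("corrected and observed tables must be aligned")
    meta = samples.loc[corrected.sample_ids]
    cfg = truth.config
    labels = {
        "batch": meta["batch"].to_numpy(),
        "shift": np.where(
            meta["injection_order"].to_numpy() <= cfg.shift_injection_index,
            "pre", "post",
        ),
        "class": meta["class_label"].to_numpy(),
    }
    rng = np.random.default_rng(seed)
    report: dict = {}
    for name, y in labels.items():
        before = _direct_s_sep(observed.values, y)
        after = _direct_s_sep(corrected.values, y)
        null = _null_s_sep(corrected.values, y, rng)
        entry = {"before": before, "after": after, "null": null}
        if before > null:
            entry["reduction_toward_null"] = (before - after) / (before - null)
        report[f"s_sep_{name}"] = entry

    # feature-level RMSE vs the clean matrix on mutually detected cells;
    # rows/columns mapped back into the full truth matrix by id
    full_idx = {
        f"F{i + 1:05d}": i for i in range(truth.clean_log2.shape[0])
    }
    truth_rows = [full_idx[f] for f in corrected.feature_ids]
    sample_idx = {s: i for i, s in enumerate(samples["sample_id"])}
    truth_cols = [sample_idx[s] for s in corrected.sample_ids]
    clean_sub = truth.clean_log2[np.ix_(truth_rows, truth_cols)]
    det = ~np.isnan(corrected.values)
    diff = corrected.values - clean_sub
    # remove per-feature offsets: normalization/correction may shift
    # absolute levels without harming relative structure
    diff = diff - np.nanmean(np.where(det, diff, np.nan), axis=1, keepdims=True)
    report["rmse_vs_clean"] = float(np.sqrt(np.nanmean(diff[det] ** 2)))
    return report
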