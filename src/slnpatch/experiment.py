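"""Experiment orchestration: the dataset x augmentation grid, dual-phase
testing, aggregation tables, and the domain-shift headline experiment.

The grid trains one model per (dataset design, augmentation on/off) cell —
eight cells with the four standard designs — evaluates each on a held-out
patch split (patch-based testing) and on whole slides that contributed no
training patches (whole-slide testing), then aggregates whole-slide metrics
across slides per model and across models per slide.

The domain-shift experiment trains {local-only, mixed 50/50 local+external}
x {augmentation off, on} arms over several replicate seeds and scores them
on unseen slides from the *external* staining domain, probing whether
multi-source training data and color augmentation buy cross-domain
robustness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentationConfig
from .inference import aggregate_reports, grid_ground_truth, predict_slide, slide_confusion, threshold_matrix
from .metrics import MetricsReport, UndefinedMetricError, compute_metrics, roc_auc
from .model import BackboneSpec, PatchClassifier, TrainConfig, build_model, evaluate_patches, train
from .patches import DESIGNS, DatasetDesign, DatasetManifest, GridSpec, build_dataset, split_manifest
from .synthetic import (
    EXTERNAL_STYLE,
    LOCAL_STYLE,
    COHORT_TUMOR_FRACTIONS,
    SlideSpec,
    generate_cohort,
)

logger = logging.getLogger("slnpatch")

__all__ = [
    "ExperimentConfig",
    "GridResults",
    "config_hash",
    "make_training_slides",
    "make_eval_slides",
    "whole_slide_report",
    "run_grid",
    "domain_shift_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one grid or shift experiment."""

    seed: int = 0
    patch_size: int = 90
    train_slide_px: int = 1260
    eval_slide_px: int = 2700
    train_tumor_fractions: tuple[float, ...] = (0.10, 0.15, 0.22, 0.28)
    n_train_negatives: int = 2
    eval_tumor_fractions: tuple[float, ...] = COHORT_TUMOR_FRACTIONS
    n_eval_negatives: int = 2
    tissue_fraction: float = 0.9
    designs: tuple[str, ...] = ("Tumor", "TumorFIB", "TumorExtended", "Interhospital")
    augment_arms: tuple[bool, ...] = (False, True)
    theta_pos: float = 0.20
    theta_gt: float = 0.20
    tau: float = 0.5
    expansion_stride: int = 30
    train: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    backbone: str = "tiny-cnn"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict()))
        return path

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "train" in payload:
            payload["train"] = TrainConfig(**payload["train"])
        if "augmentation" in payload:
            aug = payload["augmentation"]
            for key, val in list(aug.items()):
                if isinstance(val, list):
                    aug[key] = tuple(val)
            payload["augmentation"] = AugmentationConfig(**aug)
        for key, val in list(payload.items()):
            if isinstance(val, list):
                payload[key] = tuple(val)
        return cls(**payload)


def config_hash(config: ExperimentConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:12]


def _spawn(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_training_slides(config: ExperimentConfig, style, seed: int):
    """Positive slides at the configured training burdens plus negatives."""
    base = SlideSpec(
        width_px=config.train_slide_px,
        height_px=config.train_slide_px,
        domain=style,
        seed=0,
        tissue_fraction=config.tissue_fraction,
    )
    fractions = list(config.train_tumor_fractions) + [0.0] * config.n_train_negatives
    return generate_cohort(fractions, [style], base, seed=seed)


def make_eval_slides(config: ExperimentConfig, style, seed: int):
    """The whole-slide testing cohort: five positives spanning the study's
    burden range plus negatives, on slides large enough that even the 0.03%
    lesion occupies at least one grid cell above the ground-truth rule."""
    base = SlideSpec(
        width_px=config.eval_slide_px,
        height_px=config.eval_slide_px,
        domain=style,
        seed=0,
        tissue_fraction=config.tissue_fraction,
    )
    fractions = list(config.eval_tumor_fractions) + [0.0] * config.n_eval_negatives
    return generate_cohort(fractions, [style], base, seed=seed)


def whole_slide_report(
    model, slide, theta_gt: float = 0.20, tau: float = 0.5, grid_spec: GridSpec | None = None
) -> MetricsReport:
    """Sliding-window prediction, thresholding and scoring of one slide."""
    grid_spec = grid_spec or GridSpec()
    pm = predict_slide(model, slide, grid_spec)
    gt = grid_ground_truth(slide.tumor_mask, grid_spec, theta_gt=theta_gt)
    counts = slide_confusion(threshold_matrix(pm, tau), gt)
    try:
        auc = roc_auc(pm.grid.ravel(), gt.grid.ravel())[0]
    except UndefinedMetricError:
        auc = None
    return compute_metrics(counts, auc=auc)


@dataclass
class GridResults:
    config: ExperimentConfig
    patch_reports: dict
    slide_reports: list
    by_model: pd.DataFrame
    by_slide: pd.DataFrame
    histories: dict
    manifests: dict
    failures: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        chash = config_hash(self.config)
        self.config.to_yaml(out / "config.yaml")
        rows = []
        for (design, aug), report in self.patch_reports.items():
            rows.append(
                {
                    "design": design,
                    "augmented": aug,
                    "seed": self.config.seed,
                    "config_hash": chash,
                    "accuracy": report.accuracy,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "precision": report.precision,
                    "f1": report.f1,
                    "weighted_f1": report.weighted_f1,
                    "auc": report.auc,
                }
            )
        pd.DataFrame(rows).to_csv(out / "patch_reports.csv", index=False)
        rows = []
        for model_id, slide_id, report in self.slide_reports:
            rows.append(
                {
                    "model": model_id,
                    "slide": slide_id,
                    "seed": self.config.seed,
                    "config_hash": chash,
                    "accuracy": report.accuracy,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "f1": report.f1,
                    "weighted_f1": report.weighted_f1,
                    "auc": report.auc,
                }
            )
        pd.DataFrame(rows).to_csv(out / "slide_reports.csv", index=False)
        self.by_model.to_csv(out / "metrics_by_model.csv", index=False)
        self.by_slide.to_csv(out / "metrics_by_slide.csv", index=False)
        for (design, aug), history in self.histories.items():
            history.to_csv(out / f"history_{design}_{'aug' if aug else 'noaug'}.csv", index=False)
        for (design, aug), manifest in self.manifests.items():
            manifest.save_csv(out / f"manifest_{design}_{'aug' if aug else 'noaug'}.csv")


def _make_design(config: ExperimentConfig, design_id: str) -> DatasetDesign:
    design = DESIGNS[design_id]
    return dataclasses.replace(
        design,
        theta_pos=config.theta_pos,
        expansion_stride=config.expansion_stride if design_id == "TumorExtended" else None,
    )


def _train_cell(
    config: ExperimentConfig,
    design_id: str,
    augmented: bool,
    local_slides,
    external_slides,
    cell_seed: int,
) -> tuple[PatchClassifier, DatasetManifest, pd.DataFrame, dict]:
    design = _make_design(config, design_id)
    slides_by_id = {s.slide_id: s for s in local_slides + external_slides}
    manifest = build_dataset(
        design,
        local_slides,
        external_slides=external_slides if design_id == "Interhospital" else None,
        seed=cell_seed,
    )
    manifest = split_manifest(manifest, train_fraction=0.7, seed=cell_seed)
    train_cfg = dataclasses.replace(config.train, seed=cell_seed)
    model = build_model(BackboneSpec(name=config.backbone), train_cfg)
    aug_cfg = dataclasses.replace(config.augmentation, seed=cell_seed) if augmented else None
    history = train(model, manifest, slides_by_id, augmentation=aug_cfg)
    return model, manifest, history, slides_by_id


def run_grid(config: ExperimentConfig, out_dir=None) -> GridResults:
    """Train and doubly evaluate every (design, augmentation) cell.

    Cell failures are recorded and the grid continues; the held-out
    whole-slide cohort shares no slide ids with any training manifest.
    """
    local_slides = make_training_slides(config, LOCAL_STYLE, _spawn(config.seed, "train-local"))
    external_slides = make_training_slides(
        config, EXTERNAL_STYLE, _spawn(config.seed, "train-external")
    )
    eval_slides = make_eval_slides(config, LOCAL_STYLE, _spawn(config.seed, "eval"))
    train_ids = {s.slide_id for s in local_slides + external_slides}
    eval_ids = {s.slide_id for s in eval_slides}
    overlap = train_ids & eval_ids
    if overlap:
        raise RuntimeError(f"evaluation slides leak into training: {sorted(overlap)}")

    patch_reports: dict = {}
    slide_reports: list = []
    histories: dict = {}
    manifests: dict = {}
    failures: dict = {}
    for design_id in config.designs:
        for augmented in config.augment_arms:
            cell = (design_id, augmented)
            cell_seed = _spawn(config.seed, f"cell:{design_id}:{augmented}")
            try:
                logger.info("grid cell %s aug=%s", design_id, augmented)
                model, manifest, history, slides_by_id = _train_cell(
                    config, design_id, augmented, local_slides, external_slides, cell_seed
                )
                manifests[cell] = manifest
                histories[cell] = history
                patch_reports[cell] = evaluate_patches(model, manifest, slides_by_id)
                model_id = f"{design_id}{'+aug' if augmented else ''}"
                for slide in eval_slides:
                    report = whole_slide_report(
                        model, slide, theta_gt=config.theta_gt, tau=config.tau
                    )
                    slide_reports.append((model_id, slide.slide_id, report))
            except Exception as exc:  # noqa: BLE001 - grid continues past cell failures
                logger.exception("grid cell %s failed", cell)
                failures[cell] = str(exc)
    by_model = aggregate_reports(slide_reports, "model") if slide_reports else pd.DataFrame()
    by_slide = aggregate_reports(slide_reports, "slide") if slide_reports else pd.DataFrame()
    results = GridResults(
        config=config,
        patch_reports=patch_reports,
        slide_reports=slide_reports,
        by_model=by_model,
        by_slide=by_slide,
        histories=histories,
        manifests=manifests,
        failures=failures,
    )
    if out_dir is not None:
        results.save(out_dir)
    return results


def domain_shift_experiment(
    config: ExperimentConfig, replicates: int = 3, out_dir=None
) -> pd.DataFrame:
    """Train {local-only, mixed} x {aug off, aug on}; test on unseen shifted slides.

    Returns one row per arm with the mean and sample SD of the whole-slide
    weighted F1 across replicate seeds, plus per-replicate values. Refuses
    fewer than 2 replicates (the SD would be undefined).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for a meaningful SD")
    arms = [("local", False), ("local", True), ("mixed", False), ("mixed", True)]
    per_arm: dict = {arm: [] for arm in arms}
    for rep in range(replicates):
        rep_seed = _spawn(config.seed, f"shift-rep{rep}")
        local_slides = make_training_slides(config, LOCAL_STYLE, _spawn(rep_seed, "train-local"))
        external_slides = make_training_slides(
            config, EXTERNAL_STYLE, _spawn(rep_seed, "train-external")
        )
        shifted_eval = make_eval_slides(config, EXTERNAL_STYLE, _spawn(rep_seed, "eval-shifted"))
        assert not (
            {s.slide_id for s in shifted_eval}
            & {s.slide_id for s in local_slides + external_slides}
        )
        for arm in arms:
            source, augmented = arm
            design_id = "Interhospital" if source == "mixed" else "Tumor"
            model, _, _, _ = _train_cell(
                config,
                design_id,
                augmented,
                local_slides,
                external_slides if source == "mixed" else [],
                _spawn(rep_seed, f"arm:{source}:{augmented}"),
            )
            f1s = [
                whole_slide_report(model, s, theta_gt=config.theta_gt, tau=config.tau).weighted_f1
                for s in shifted_eval
            ]
            per_arm[arm].append(float(np.mean(f1s)))
            logger.info("shift rep %d arm %s: F1=%.3f", rep, arm, per_arm[arm][-1])
    rows = []
    for (source, augmented), vals in per_arm.items():
        arr = np.asarray(vals)
        rows.append(
            {
                "arm": source,
                "augmented": augmented,
                "f1_mean": float(arr.mean()),
                "f1_sd": float(arr.std(ddof=1)),
                "f1_per_seed": json.dumps([round(v, 6) for v in vals]),
                "replicates": replicates,
                "config_hash": config_hash(config),
            }
        )
    summary = pd.DataFrame(rows)
    # directional comparisons per replicate (mixed vs local at equal augmentation)
    for augmented in (False, True):
        mixed = per_arm[("mixed", augmented)]
        local = per_arm[("local", augmented)]
        wins = sum(m >= l for m, l in zip(mixed, local))
        summary.attrs[f"mixed_ge_local_aug{int(augmented)}"] = f"{wins}/{replicates}"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "shift_summary.csv", index=False)
    return summary
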