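"""End-to-end experiment driver: synthesise, partition, train, evaluate.

A single :class:`RunConfig` drives the whole pipeline: synthetic dataset
generation, six-zone extraction, per-zone resize policies (computed on each
fold's training split), per-zone per-fold model training, and zone- plus
image-level evaluation with fold means and standard deviations (reported as
percentages). Listing several attention variants produces an ablation
comparison in the same report. All randomness derives from the config
seeds, and a locked copy of the config is written into the run directory,
so every artifact is reproducible from the locked config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .classifier import (
    BackboneSpec,
    TrainConfig,
    ZoneSamples,
    predict_zone_batch,
    stratified_folds,
    train_zone_model,
)
from .errors import DlaError
from .evaluation import binary_report, evaluate_run, summarize_folds
from .preprocess import compute_zone_aspects, resize_zone
from .synthetic import SyntheticConfig, demo_config, generate_dataset, load_image
from .zones import ZONE_NAMES, extract_zones

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    out_dir: str = "runs/experiment"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=demo_config)
    target_height: int = 48
    interpolation: str = "bilinear"
    variants: Tuple[str, ...] = ("sequential",)
    ratio: int = 16
    backbone: str = "tiny"
    train: TrainConfig = field(default_factory=lambda: TrainConfig(learning_rate=1e-3, n_folds=2, max_epochs=10))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "synthetic" in payload:
            syn = dict(payload["synthetic"])
            for key in ("blob_count_ranges", "blob_radius_range", "blob_contrast_range", "category_weights"):
                if key in syn and syn[key] is not None:
                    val = syn[key]
                    syn[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in val)
            payload["synthetic"] = SyntheticConfig(**syn)
        if "train" in payload:
            payload["train"] = TrainConfig(**payload["train"])
        if "variants" in payload:
            payload["variants"] = tuple(payload["variants"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _derived_seed(*parts: int) -> int:
    """Stable sub-seed below 2**31 from integer parts."""
    return int(np.random.SeedSequence(tuple(parts)).generate_state(1)[0] % (2**31))


def _collect_zone_crops(dataset_dir: Path, manifest: pd.DataFrame):
    """Raw (unresized) crops and labels per zone, in manifest order."""
    crops: Dict[str, List[np.ndarray]] = {z: [] for z in ZONE_NAMES}
    for _, row in manifest.iterrows():
        image = load_image(dataset_dir, row["image_path"])
        mask = load_image(dataset_dir, row["mask_path"]) > 0.5
        zone_set = extract_zones(image, mask)
        for z in ZONE_NAMES:
            crops[z].append(zone_set[z].pixels)
    return crops


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the report dict (also written to disk)."""
    run_dir = Path(out_dir if out_dir is not None else config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("dlanet")
    root.addHandler(handler)
    try:
        config.to_yaml(run_dir / "config.lock.yaml")
        report = _run_stages(config, run_dir)
        (run_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    except DlaError as err:
        logger.error("run aborted: %s", err)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, run_dir: Path) -> dict:
    logger.info("stage=synth n_images=%d", config.synthetic.n_images)
    data_dir = run_dir / "data"
    manifest = generate_dataset(config.synthetic, data_dir)

    logger.info("stage=zones")
    raw_crops = _collect_zone_crops(data_dir, manifest)
    image_ids = manifest["image_id"].to_numpy()

    n_folds = config.train.n_folds
    folds = stratified_folds(manifest, n_folds=n_folds, seed=config.seed)

    # Resized arrays per (zone, fold): the resize policy is fitted on the
    # training split of each fold, then applied to every crop of the zone.
    resized: Dict[Tuple[str, int], ZoneSamples] = {}
    for fold in range(n_folds):
        train_mask = folds != fold
        shapes = {
            z: [c.shape for c, keep in zip(raw_crops[z], train_mask) if keep] for z in ZONE_NAMES
        }
        policy = compute_zone_aspects(shapes, target_height=config.target_height,
                                      interpolation=config.interpolation)
        if fold == 0:
            policy.to_yaml(run_dir / "resize_policy.fold0.yaml")
        for z in ZONE_NAMES:
            arr = np.stack([resize_zone(c, z, policy) for c in raw_crops[z]])
            resized[(z, fold)] = ZoneSamples(
                zone_name=z, images=arr, labels=manifest[z].to_numpy(dtype=int), image_ids=image_ids
            )

    backbone = BackboneSpec(name=config.backbone)
    report: dict = {"n_images": int(len(manifest)), "n_folds": n_folds, "variants": {}}
    for vi, variant in enumerate(config.variants):
        logger.info("stage=train variant=%s", variant)
        fold_zone_reports: Dict[str, list] = {z: [] for z in ZONE_NAMES}
        fold_image_reports = []
        fold_binary_reports = []
        pred_dir = run_dir / "predictions" / variant
        pred_dir.mkdir(parents=True, exist_ok=True)
        pooled: Dict[str, List[pd.DataFrame]] = {z: [] for z in ZONE_NAMES}
        for fold in range(n_folds):
            zone_preds = {}
            for zi, zone in enumerate(ZONE_NAMES):
                task_cfg = dataclasses.replace(
                    config.train, seed=_derived_seed(config.seed, vi, zi)
                )
                samples = resized[(zone, fold)]
                model, history = train_zone_model(
                    samples, folds, fold, task_cfg,
                    backbone=backbone, variant=variant, ratio=config.ratio,
                )
                logger.info(
                    "trained zone=%s fold=%d epochs=%d best_val_loss=%.4f",
                    zone, fold, len(history), history["val_loss"].min(),
                )
                val_idx = np.where(folds == fold)[0]
                frame = predict_zone_batch(model, samples, val_idx)
                zone_preds[zone] = frame
                pooled[zone].append(frame)
            sub_manifest = manifest[np.isin(manifest["image_id"], zone_preds[ZONE_NAMES[0]]["image_id"])]
            zone_reports, image_report = evaluate_run(zone_preds, sub_manifest)
            for z in ZONE_NAMES:
                fold_zone_reports[z].append(zone_reports[z])
            fold_image_reports.append(image_report)

            image_true = sub_manifest.set_index("image_id")["image_label"]
            order = zone_preds[ZONE_NAMES[0]]["image_id"].to_numpy()
            preds = np.max(
                np.stack([zone_preds[z].set_index("image_id").loc[order, "predicted"].to_numpy() for z in ZONE_NAMES]),
                axis=0,
            )
            fold_binary_reports.append(binary_report(image_true.loc[order].to_numpy(), preds))

        for z in ZONE_NAMES:
            pd.concat(pooled[z], ignore_index=True).to_csv(pred_dir / f"{z}.csv", index=False)
        report["variants"][variant] = {
            "zone_level": {z: summarize_folds(fold_zone_reports[z]) for z in ZONE_NAMES},
            "image_level": summarize_folds(fold_image_reports),
            "binary_detection": summarize_folds(fold_binary_reports),
        }
    return report
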