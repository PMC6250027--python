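"""End-to-end orchestration of the seven-stage screening pipeline.

Every stage is a pure function of (inputs, config, seed); a run writes
its intermediate artefacts (preprocessed images, masks, per-nucleus
feature CSVs) plus a manifest with the config and seeds, so any stage
can be re-run or audited in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import classify, features, overlap, postprocess, preprocess, segment
from .classify import compute_metrics, counts_from_labels, predict, train_ecbdt
from .config import PipelineConfig
from .fixtures import SceneSpec, generate_scene, write_scene
from .select import anneal

log = logging.getLogger("cytodx")

__all__ = ["run_pipeline", "generate_scenes", "process_image", "label_nuclei"]


def generate_scenes(outdir: str | Path, n_scenes: int, base: SceneSpec) -> list[Path]:
    """Render a batch of scenes with per-scene seeds derived from the spec."""
    outdir = Path(outdir)
    paths = []
    for k in range(n_scenes):
        spec = dataclasses.replace(base, seed=(base.seed * 1000 + k) % (2**31 - 1))
        img, gt = generate_scene(spec)
        written = write_scene(outdir, f"scene_{k:03d}", img, gt)
        paths.append(written["image"])
    return paths


def process_image(img: np.ndarray, cfg: PipelineConfig, svm=None):
    """preprocess -> segment -> postprocess -> overlap for one image.

    Returns (working image, instance label mask, per-nucleus ellipse table).
    """
    pre = preprocess.run(img, cfg.preprocess)
    raw_mask = segment.run(pre, cfg.segment)
    refined = postprocess.refine_multiscale(raw_mask, cfg.postprocess)
    labels, table = overlap.resolve_overlaps(refined, svm, cfg.overlap, svm_seed=cfg.seed)
    return pre, labels, table


def label_nuclei(
    label_mask: np.ndarray, gt_nuclei: pd.DataFrame, scale: tuple[float, float] = (1.0, 1.0)
) -> dict[int, str]:
    """Assign each detected nucleus the class of the ground-truth nucleus
    whose recorded center (scaled into working coordinates) falls inside it;
    unmatched nuclei stay unlabeled."""
    sy, sx = scale
    out: dict[int, str] = {}
    for _, row in gt_nuclei.iterrows():
        x = int(round(row["cx"] * sx))
        y = int(round(row["cy"] * sy))
        if 0 <= y < label_mask.shape[0] and 0 <= x < label_mask.shape[1]:
            lab = int(label_mask[y, x])
            if lab > 0 and lab not in out:
                out[lab] = str(row["class"])
    return out


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage over the images of ``cfg.input_dir``.

    Expects PNG scene images (optionally with ``<stem>_nuclei.csv`` ground
    truth next to them, as written by the scene generator).  Produces in
    ``cfg.output_dir``: per-image instance masks and nucleus tables, the
    combined feature table, and — when ground-truth labels are available —
    a trained ensemble, per-nucleus predictions and metrics JSON computed
    on an image-level held-out split.
    """
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    images = sorted(p for p in indir.glob("*.png") if not p.stem.endswith("_mask"))
    if not images:
        raise FileNotFoundError(f"no input images found in {indir}")
    outdir.mkdir(parents=True, exist_ok=True)

    svm = overlap.default_overlap_svm(seed=cfg.seed)
    tables = []
    for path in images:
        t0 = time.time()
        img = preprocess.load_image(path)
        try:
            pre, labels, nuc_table = process_image(img, cfg, svm)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed on image {path.stem}: {exc}") from exc
        iio.imwrite(outdir / f"{path.stem}_instances.png", labels.astype(np.uint16))
        nuc_table.to_csv(outdir / f"{path.stem}_nuclei.csv", index=False)
        gt_csv = indir / f"{path.stem}_nuclei.csv"
        label_map: dict[int, str] = {}
        if gt_csv.exists():
            gt = pd.read_csv(gt_csv)
            sy = pre.shape[0] / img.shape[0]
            sx = pre.shape[1] / img.shape[1]
            label_map = label_nuclei(labels, gt, scale=(sy, sx))
        feats = features.extract_table(pre, labels, image_id=path.stem, labels=label_map)
        tables.append(feats)
        log.info("%s: %d nuclei in %.1fs", path.stem, labels.max(), time.time() - t0)

    table = pd.concat(tables, ignore_index=True)
    table.to_csv(outdir / "features.csv", index=False)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "n_images": len(images),
        "n_nuclei": int(len(table)),
    }

    labelled = table[table["label"] != "unlabeled"]
    if len(labelled) and labelled["label"].nunique() == 2:
        rng = np.random.default_rng(cfg.seed)
        ids = sorted(labelled["image_id"].unique())
        n_train = max(1, int(round(cfg.train_fraction * len(ids))))
        perm = rng.permutation(len(ids))
        train_ids = {ids[i] for i in perm[:n_train]}
        train = labelled[labelled["image_id"].isin(train_ids)]
        test = labelled[~labelled["image_id"].isin(train_ids)]

        selected = list(features.FEATURE_CODES)
        if cfg.run_selection:
            result = anneal(train, cfg.select)
            selected = result.best.codes()
            pd.Series(selected, name="code").to_csv(outdir / "selected_features.csv", index=False)
            result.trace.to_csv(outdir / "selection_trace.csv", index=False)
        model = train_ecbdt(train, selected, cfg.classify)
        manifest["cv_accuracy_mean"] = float(model.cv_report["accuracy"].mean())

        if len(test) and test["label"].nunique() == 2:
            pred = predict(model, test)
            out = test[["image_id", "nucleus_id", "label"]].copy()
            out["prediction"] = pred
            out.to_csv(outdir / "predictions.csv", index=False)
            metrics = compute_metrics(counts_from_labels(test["label"].to_numpy(), pred))
            with open(outdir / "metrics.json", "w") as fh:
                json.dump(metrics.as_dict(), fh, indent=2)
            manifest["test_metrics"] = metrics.as_dict()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
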