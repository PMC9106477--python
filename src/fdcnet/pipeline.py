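"""End-to-end orchestration: preprocess -> segment -> features -> classify
-> metrics, with a reproducible run manifest.

Inputs are either a directory of images (PNG/NIfTI, with an optional
``labels.csv`` of ``filename,label`` rows) or an internally generated
synthetic phantom set.  Every stage is a pure function of (inputs,
config, seed); the manifest records a content hash over everything
except wall-clock timings, so identical runs hash identically.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .eigen import EigenFeatureExtractor
from .image import Preprocessor, PreprocessConfig, RawImage, load_image, save_image
from .metrics import (
    MetricsReport,
    macro_sensitivity,
    mse,
    multiclass_accuracy,
    psnr,
    roc_auc_multiclass,
    snr,
)
from .morphology import FractalSegmenter, StructuringElement
from .network import FDCNetClassifier, FDCNetConfig, TrainConfig, train
from .phantoms import generate_dataset, PhantomSpec

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("fdcnet.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage
        self.detail = detail


@dataclass
class PipelineConfig:
    """Everything a run needs; see ``from_yaml`` for the file layout."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: FDCNetConfig = field(default_factory=FDCNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    se_size: int = 3
    eigen_components: Optional[int] = None
    eigen_variance: float = 0.95
    seed: int = 0
    input_dir: Optional[str] = None
    input_glob: str = "*.png"
    labels_csv: str = "labels.csv"
    synth_n: int = 0
    synth_shape: tuple = (64, 64)
    out_dir: str = "fdcnet_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: Dict = {}
        if "preprocess" in raw:
            kw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "model" in raw:
            m = dict(raw["model"])
            if "input_shape" in m:
                m["input_shape"] = tuple(m["input_shape"])
            kw["model"] = FDCNetConfig(**m)
        if "train" in raw:
            kw["train"] = TrainConfig(**raw["train"])
        io = raw.get("io", {})
        for k in ("input_dir", "input_glob", "labels_csv", "out_dir"):
            if k in io:
                kw[k] = io[k]
        synth = raw.get("synth", {})
        if "n" in synth:
            kw["synth_n"] = int(synth["n"])
        if "shape" in synth:
            kw["synth_shape"] = tuple(synth["shape"])
        for k in ("se_size", "eigen_components", "eigen_variance", "seed"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)

    def echo(self) -> Dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


def _content_hash(payload: Dict) -> str:
    payload = dict(payload)
    cfg = dict(payload.get("config") or {})
    for k in ("out_dir", "input_dir"):  # paths do not affect the results
        cfg.pop(k, None)
    payload["config"] = cfg
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages and return (and write) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d out=%s", config.seed, out_dir)

    timings: Dict[str, float] = {}
    manifest: Dict = {"config": config.echo(), "seed": config.seed}

    # ---- stage: load ---------------------------------------------------
    t0 = time.perf_counter()
    images: List[RawImage] = []
    masks: List[Optional[np.ndarray]] = []
    labels: List[Optional[str]] = []
    names: List[str] = []
    stage = "load"
    try:
        if config.synth_n > 0:
            base = PhantomSpec(shape=tuple(config.synth_shape))
            dataset = generate_dataset(config.synth_n, base_spec=base,
                                       seed=config.seed)
            for i, s in enumerate(dataset):
                images.append(s.image)
                masks.append(s.mask)
                labels.append(s.label)
                names.append(f"phantom_{i:04d}")
        elif config.input_dir:
            paths = sorted(Path(config.input_dir).glob(config.input_glob))
            label_map: Dict[str, str] = {}
            csv_path = Path(config.input_dir) / config.labels_csv
            if csv_path.exists():
                with open(csv_path) as fh:
                    for row in csv.DictReader(fh):
                        label_map[row["filename"]] = row["label"]
            for p in paths:
                images.append(load_image(p))
                masks.append(None)
                labels.append(label_map.get(p.name))
                names.append(p.name)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    timings[stage] = time.perf_counter() - t0

    if not images:
        warnings.warn("pipeline received no inputs; writing empty manifest")
        manifest.update(n_items=0, stages=[], metrics=None)
        manifest["content_hash"] = _content_hash(
            {k: v for k, v in manifest.items() if k != "content_hash"})
        manifest["timings"] = timings
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))
        return manifest

    # ---- stage: preprocess --------------------------------------------
    stage = "preprocess"
    t0 = time.perf_counter()
    try:
        pre = Preprocessor(config.preprocess)
        processed = [pre.run(im) for im in images]
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    timings[stage] = time.perf_counter() - t0

    # ---- stage: segment ------------------------------------------------
    stage = "segment"
    t0 = time.perf_counter()
    try:
        nd = processed[0].data.ndim
        se = StructuringElement.box(ndim=nd, size=config.se_size)
        segmenter = FractalSegmenter(se)
        seg_results = [segmenter.segment(im) for im in processed]
        mask_dir = out_dir / "masks"
        mask_dir.mkdir(exist_ok=True)
        ious = []
        for name, res, gt in zip(names, seg_results, masks):
            if nd == 2:
                save_image(RawImage(res.mask.astype(float) * 255.0),
                           mask_dir / f"{name}_mask.png")
            if gt is not None:
                union = np.logical_or(res.mask, gt).sum()
                inter = np.logical_and(res.mask, gt).sum()
                ious.append(float(inter / union) if union else 1.0)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    timings[stage] = time.perf_counter() - t0

    # ---- stage: features ----------------------------------------------
    stage = "features"
    t0 = time.perf_counter()
    try:
        flat = np.stack([im.data.ravel() for im in processed])
        extractor = EigenFeatureExtractor(
            n_components=config.eigen_components,
            variance_threshold=config.eigen_variance)
        feats = extractor.fit(flat).transform(flat)
        np.savez(out_dir / "eigen_model.npz", mean=extractor.mean_,
                 components=extractor.components_,
                 eigenvalues=extractor.eigenvalues_)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    timings[stage] = time.perf_counter() - t0

    # ---- stage: classify ----------------------------------------------
    stage = "classify"
    t0 = time.perf_counter()
    report = None
    try:
        have_labels = all(l is not None for l in labels)
        if have_labels and len(set(labels)) >= 2:
            shape = processed[0].data.shape
            X = np.concatenate([flat, feats], axis=1)
            y = np.asarray(labels)
            clf = FDCNetClassifier(
                image_shape=shape,
                conv_channels=config.model.conv_channels,
                filter_size=config.model.filter_size,
                rate_conv=config.model.rate_conv,
                rate_fuzzy=config.model.rate_fuzzy,
                rate_pool=config.model.rate_pool,
                fuzzy_units=config.model.fuzzy_units,
                pool_layers=config.model.pool_layers,
                random_state=config.train.seed,
            )
            clf, info = train(clf, X, y, config.train)
            te = info["test_idx"]
            y_pred = clf.predict(X[te])
            probs = clf.predict_proba(X[te])
            acc = multiclass_accuracy(y[te], y_pred)
            sens = macro_sensitivity(y[te], y_pred)
            auc = roc_auc_multiclass(probs, y[te], classes=clf.classes_)
            pairs = [(masks[i].astype(float), seg_results[i].mask.astype(float))
                     for i in te if masks[i] is not None]
            if pairs:
                m = float(np.mean([mse(a, b) for a, b in pairs]))
                p = float(np.mean([psnr(a, b, 1.0) for a, b in pairs]))
                s = float(np.mean([snr(a, b) for a, b in pairs]))
            else:
                ref = [(images[i].data, processed[i].data) for i in te]
                m = float(np.mean([mse(a, b) for a, b in ref]))
                p = float(np.mean([psnr(a, b) for a, b in ref]))
                s = float(np.mean([snr(a, b) for a, b in ref]))
            report = MetricsReport(accuracy=acc, sensitivity=sens, mse=m,
                                   psnr=p, snr=s, auc=auc)
            report.to_json(out_dir / "metrics.json")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    timings[stage] = time.perf_counter() - t0

    manifest.update(
        n_items=len(images),
        stages=list(timings),
        mean_iou=float(np.mean(ious)) if ious else None,
        metrics=None if report is None else json.loads(report.to_json()),
    )
    manifest["content_hash"] = _content_hash(
        {k: v for k, v in manifest.items() if k != "content_hash"})
    manifest["timings"] = timings
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    log.info("pipeline done: %d items", len(images))
    return manifest
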