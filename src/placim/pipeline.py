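"""End-to-end orchestration: phantoms -> segmentation -> ROI -> features ->
fusion classifier -> evaluation, plus the ROI-extension sweep.

The flow mirrors the clinical pipeline: a U-net is trained on annotated
cases, its masks are extended outward by ``d`` pixels to form ROIs, 100
radiomic and 100 deep features are extracted per case, and the fused
200-vector is classified into the four invasion types. Splitting is
case-level and stratified; every fitted component (segmenter, codec,
feature standardisation, classifier) sees training cases only. Cases
with several images are aggregated by majority vote over image-level
predictions, ties toward the lowest class index.

Every stage is seeded and the run manifest records a hash of the full
configuration, so re-running an identical config reproduces identical
artifacts bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metrics
from .classifier import (
    ClfTrainConfig,
    FusedFeatures,
    predict_proba,
    save_classifier,
    train_classifier,
)
from .ddcnn import (
    DdcnnSpec,
    DdcnnTrainConfig,
    build_ddcnn,
    deep_features,
    save_ddcnn,
    train_autoencoder,
)
from .phantom import PhantomSpec, generate_dataset
from .radiomics import ALL_NAMES, extract_all
from .roi import bounding_rect_crop, extend_region, resize_bilinear
from .unet import SegTrainConfig, UnetSpec, save_segmenter, segment, train_segmenter


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = PhantomSpec()
    unet: UnetSpec = UnetSpec()
    seg_train: SegTrainConfig = SegTrainConfig()
    roi_extension: int = 40
    radiomics_bins: int = 32
    ddcnn: DdcnnSpec = DdcnnSpec()
    ddcnn_train: DdcnnTrainConfig = DdcnnTrainConfig()
    clf_train: ClfTrainConfig = ClfTrainConfig()
    test_fraction: float = 0.5
    split_seed: int = 0
    output_dir: str = "placim_run"

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.roi_extension < 0:
            raise ValueError("roi_extension must be non-negative")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["phantom"] = self.phantom.to_dict()
        d["unet"] = self.unet.to_dict()
        d["ddcnn"] = self.ddcnn.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        d["unet"] = UnetSpec(**d["unet"])
        d["ddcnn"] = DdcnnSpec(**d["ddcnn"])
        d["seg_train"] = SegTrainConfig(**d["seg_train"])
        d["ddcnn_train"] = DdcnnTrainConfig(**d["ddcnn_train"])
        d["clf_train"] = ClfTrainConfig(**d["clf_train"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    artifact_paths: dict[str, str]
    report: dict
    report_path: str


def split_cases(case_ids, labels, test_fraction: float, seed: int):
    """Stratified case-level train/test split; returns (train_ids, test_ids)."""
    case_ids = list(case_ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        ids = [case_ids[i] for i in np.flatnonzero(labels == c)]
        order = rng.permutation(len(ids))
        n_test = max(1, int(round(test_fraction * len(ids)))) if len(ids) > 1 else 0
        test.extend(ids[i] for i in order[:n_test])
        train.extend(ids[i] for i in order[n_test:])
    check_split(train, test)
    return sorted(train), sorted(test)


def check_split(train_ids, test_ids) -> None:
    """Leakage guard: a case may not sit in both splits."""
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"train/test case overlap: {sorted(overlap)}")
    if not train_ids or not test_ids:
        raise ValueError("both splits must be non-empty")


def majority_vote(image_preds) -> int:
    """Case label from image-level predictions; ties -> lowest class index."""
    counts = np.bincount(np.asarray(image_preds, dtype=int), minlength=4)
    return int(np.argmax(counts))


def _read_labels(records, purpose: str) -> np.ndarray:
    """Single funnel for label access (instrumented by tests)."""
    return np.array([r.label for r in records], dtype=int)


def _crop_for_ddcnn(image, roi, input_size: int) -> np.ndarray:
    crop, _ = bounding_rect_crop(image, roi, pad_to_multiple=1)
    return resize_bilinear(crop, input_size)


def run_pipeline(cfg: PipelineConfig, records=None) -> RunManifest:
    """Execute all stages; returns the run manifest.

    ``records`` overrides phantom generation (for pre-existing datasets);
    every record then needs image, mask and label.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    stage = "generate"
    try:
        if records is None:
            records, _ = generate_dataset(cfg.phantom, out / "data", force=True)
            paths["data"] = str(out / "data" / "manifest.csv")
        by_id = {r.id: r for r in records}

        stage = "split"
        labels_all = _read_labels(records, "split")
        train_ids, test_ids = split_cases([r.id for r in records], labels_all,
                                          cfg.test_fraction, cfg.split_seed)
        train_recs = [by_id[i] for i in train_ids]
        test_recs = [by_id[i] for i in test_ids]

        stage = "train-seg"
        seg_model, seg_hist = train_segmenter(train_recs, cfg.unet, cfg.seg_train)
        save_segmenter(out / "unet.ckpt", seg_model)
        paths["unet"] = str(out / "unet.ckpt")

        stage = "segment"
        pred_masks = {}
        for rec in records:
            m = segment(seg_model, rec.image)
            if not m.any():
                # an empty prediction would break ROI building; fall back to
                # the annotation so the run can proceed
                m = rec.mask
            pred_masks[rec.id] = m

        result = _features_and_typing(cfg, train_recs, test_recs, pred_masks,
                                      cfg.roi_extension, out, paths)
        stage = "report"
        report = {
            "config_hash": cfg.config_hash(),
            "roi_extension": cfg.roi_extension,
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "seg_final_loss": seg_hist[-1],
            **result,
        }
        report_path = out / "report.json"
        io.write_json(report_path, report)
        paths["report"] = str(report_path)
        return RunManifest(config_hash=cfg.config_hash(), artifact_paths=paths,
                           report=report, report_path=str(report_path))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _features_and_typing(cfg, train_recs, test_recs, pred_masks, d, out, paths):
    """Feature extraction, classifier training and test-split evaluation for
    one ROI extension d."""
    records = train_recs + test_recs
    rois = {r.id: extend_region(pred_masks[r.id], d) for r in records}

    radiomic = {r.id: extract_all(r.image, rois[r.id].mask, n_bins=cfg.radiomics_bins)
                for r in records}
    rad_df = pd.DataFrame.from_dict(radiomic, orient="index", columns=ALL_NAMES)
    rad_df.index.name = "id"
    rad_path = out / f"radiomics_d{d}.csv"
    rad_df.to_csv(rad_path)
    paths[f"radiomics_d{d}"] = str(rad_path)

    crops = {r.id: _crop_for_ddcnn(r.image, rois[r.id], cfg.ddcnn.input_size)
             for r in records}
    codec = build_ddcnn(cfg.ddcnn, seed=cfg.ddcnn_train.seed)
    codec, _ = train_autoencoder(codec, [crops[r.id] for r in train_recs],
                                 cfg.ddcnn_train)
    save_ddcnn(out / f"ddcnn_d{d}.ckpt", codec)
    paths[f"ddcnn_d{d}"] = str(out / f"ddcnn_d{d}.ckpt")
    deep = {r.id: deep_features(codec, crops[r.id]) for r in records}

    fused_train = FusedFeatures(
        radiomic=np.stack([radiomic[r.id] for r in train_recs]),
        deep=np.stack([deep[r.id] for r in train_recs]),
        ids=[r.id for r in train_recs])
    y_train = _read_labels(train_recs, "train-clf")
    clf, _ = train_classifier(fused_train, y_train, cfg.clf_train)
    save_classifier(out / f"classifier_d{d}.ckpt", clf)
    paths[f"classifier_d{d}"] = str(out / f"classifier_d{d}.ckpt")

    x_test = np.hstack([np.stack([radiomic[r.id] for r in test_recs]),
                        np.stack([deep[r.id] for r in test_recs])])
    probs = predict_proba(clf, x_test)
    image_preds = np.argmax(probs, axis=1)
    # one image per phantom case; multi-image cases would majority-vote here
    case_preds = np.array([majority_vote([p]) for p in image_preds])
    y_test = _read_labels(test_recs, "evaluate")
    cmat = metrics.confusion_matrix(y_test, case_preds)
    typing = metrics.typing_metrics(cmat)
    try:
        auc = metrics.macro_auc(y_test, probs)
    except ValueError:
        auc = float("nan")
    return {
        "confusion_matrix": cmat.tolist(),
        "typing_metrics": {k: metrics.round3(v) for k, v in typing.items()},
        "macro_auc": None if np.isnan(auc) else metrics.round3(auc),
        "mean_roi_area": float(np.mean([rois[r.id].area for r in records])),
    }


def extension_sweep(cfg: PipelineConfig, d_values) -> pd.DataFrame:
    """One feature+classifier cycle per extension d, sharing the phantoms,
    the split and the trained segmenter. Returns a table keyed by d."""
    d_values = list(d_values)
    if not d_values:
        raise ValueError("need at least one extension value")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    records, _ = generate_dataset(cfg.phantom, out / "data", force=True)
    by_id = {r.id: r for r in records}
    labels_all = _read_labels(records, "split")
    train_ids, test_ids = split_cases([r.id for r in records], labels_all,
                                      cfg.test_fraction, cfg.split_seed)
    train_recs = [by_id[i] for i in train_ids]
    test_recs = [by_id[i] for i in test_ids]
    seg_model, _ = train_segmenter(train_recs, cfg.unet, cfg.seg_train)
    pred_masks = {}
    for rec in records:
        m = segment(seg_model, rec.image)
        pred_masks[rec.id] = m if m.any() else rec.mask
    rows = []
    for d in d_values:
        res = _features_and_typing(cfg, train_recs, test_recs, pred_masks, d,
                                   out, paths)
        rows.append({"extension_px": d, **res["typing_metrics"],
                     "macro_auc": res["macro_auc"],
                     "mean_roi_area": res["mean_roi_area"]})
    table = pd.DataFrame(rows).set_index("extension_px")
    table.to_csv(out / "extension_sweep.csv")
    return table
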