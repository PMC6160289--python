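"""End-to-end orchestration of the four-stage recognition pipeline.

Stage chain per frame:

1. RGB → HLS, interval-threshold vegetation mask (global segmentation);
2. linear SVM per-pixel classification of the vegetation into ROI / N-ROI
   (local segmentation);
3. area filtering + erosion of the SVM mask (post-processing);
4. gray-threshold center detection on the post-processed ROI.

``run_pipeline`` processes one frame against a trained model and records
every intermediate mask; ``run_batch`` walks a directory of frames,
evaluating Qseg and the recognition rate whenever ground-truth files sit
alongside the images.  Configuration is a single dataclass tree that
round-trips through YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .center_detection import DEFAULT_GRAY_THRESHOLD, CenterResult, detect_center
from .evaluation import (
    DEFAULT_CENTER_TOLERANCE,
    QsegReport,
    RecognitionReport,
    qseg,
    recognition_rate,
    scaled_tolerance,
    summarize_quality,
)
from .hls_segmentation import HlsThresholds, compute_hls_mask, extract_vegetation
from .imaging_core import (
    BinaryMask,
    PixelCoord,
    RgbImage,
    apply_mask,
    rgb_to_gray,
    rgb_to_hls,
)
from .postprocessing import area_filter, erode, ErosionKernel
from .svm_segmentation import (
    LinearSvmModel,
    SvmConfig,
    TrainingSet,
    fit_linear_svm,
    predict_mask,
    sample_training_pixels,
)
from .synthetic_fixtures import CanopyGroundTruth, training_nroi_mask

__all__ = [
    "PostConfig",
    "PipelineConfig",
    "PipelineResult",
    "BatchResult",
    "PipelineStageError",
    "run_pipeline",
    "run_batch",
    "train_from_fixtures",
    "save_fixtures",
    "load_truth",
]

logger = logging.getLogger("canopycenter")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PostConfig:
    connectivity: int = 8
    area_policy: str = "keep-largest"
    min_area: int = 64
    erosion_passes: int = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the four stages, with the standard defaults baked in
    (hue window 35–99, C = 0.1, gray threshold 30, tolerance 20 px at the
    1242×931 reference frame)."""

    hls: HlsThresholds = field(default_factory=HlsThresholds)
    svm: SvmConfig = field(default_factory=SvmConfig)
    post: PostConfig = field(default_factory=PostConfig)
    gray_threshold: float = DEFAULT_GRAY_THRESHOLD
    adaptive_threshold: bool = False
    center_tolerance: float = DEFAULT_CENTER_TOLERANCE

    def to_dict(self) -> dict:
        return {
            "hls": asdict(self.hls),
            "svm": asdict(self.svm),
            "post": asdict(self.post),
            "gray_threshold": self.gray_threshold,
            "adaptive_threshold": self.adaptive_threshold,
            "center_tolerance": self.center_tolerance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            hls=HlsThresholds(**d.get("hls", {})),
            svm=SvmConfig(**d.get("svm", {})),
            post=PostConfig(**d.get("post", {})),
            gray_threshold=d.get("gray_threshold", DEFAULT_GRAY_THRESHOLD),
            adaptive_threshold=d.get("adaptive_threshold", False),
            center_tolerance=d.get("center_tolerance", DEFAULT_CENTER_TOLERANCE),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True, eq=False)
class PipelineResult:
    """Per-frame record: the mask after every stage plus the center result."""

    hls_mask: BinaryMask
    svm_mask: BinaryMask
    post_mask: BinaryMask
    center: CenterResult
    diagnostics: dict


def run_pipeline(
    img: RgbImage,
    model: LinearSvmModel,
    cfg: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full stage chain on one frame.

    An empty ROI after post-processing yields ``found=False`` rather than
    an exception; genuine stage failures raise :class:`PipelineStageError`
    naming the stage.
    """
    diagnostics = {}
    try:
        hls = rgb_to_hls(img)
        hls_mask = compute_hls_mask(hls, cfg.hls)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineStageError("hls_segmentation", e) from e
    diagnostics["hls_pixels"] = hls_mask.area

    try:
        veg = extract_vegetation(hls, hls_mask)
        svm_mask = predict_mask(model, veg, hls_mask)
    except Exception as e:
        raise PipelineStageError("svm_segmentation", e) from e
    diagnostics["svm_pixels"] = svm_mask.area

    try:
        post = area_filter(
            svm_mask,
            policy=cfg.post.area_policy,
            min_area=cfg.post.min_area,
            connectivity=cfg.post.connectivity,
        )
        post = erode(post, ErosionKernel(), passes=cfg.post.erosion_passes)
    except Exception as e:
        raise PipelineStageError("postprocessing", e) from e
    diagnostics["post_pixels"] = post.area

    try:
        if post.area == 0:
            center = CenterResult(found=False)
        else:
            gray = rgb_to_gray(apply_mask(img, post))
            center = detect_center(
                gray, post, T=cfg.gray_threshold, adaptive=cfg.adaptive_threshold
            )
    except Exception as e:
        raise PipelineStageError("center_detection", e) from e
    diagnostics["center_found"] = center.found

    logger.debug(
        "pipeline: hls=%d svm=%d post=%d found=%s",
        diagnostics["hls_pixels"],
        diagnostics["svm_pixels"],
        diagnostics["post_pixels"],
        center.found,
    )
    return PipelineResult(
        hls_mask=hls_mask, svm_mask=svm_mask, post_mask=post, center=center, diagnostics=diagnostics
    )


# ---------------------------------------------------------------------------
# Training helpers
# ---------------------------------------------------------------------------

def train_from_fixtures(
    fixtures: Sequence[Tuple[RgbImage, CanopyGroundTruth]],
    cfg: SvmConfig = SvmConfig(),
) -> LinearSvmModel:
    """Fit the pixel classifier on candidate regions pooled from fixtures.

    Each fixture contributes an equal share of the ``cfg.sample_size``
    training pixels (50/50 ROI vs. N-ROI); the N-ROI candidate region
    excludes weeds, mirroring manual candidate selection.
    """
    if not fixtures:
        raise ValueError("train_from_fixtures: no fixtures given")
    per_fix = max(2, int(np.ceil(cfg.sample_size / len(fixtures) / 2)) * 2)
    feats, labels = [], []
    for i, (img, truth) in enumerate(fixtures):
        hls = rgb_to_hls(img)
        ts = sample_training_pixels(
            hls,
            truth.roi,
            training_nroi_mask(truth),
            n=per_fix,
            seed=cfg.seed + i,
        )
        feats.append(ts.features)
        labels.append(ts.labels)
    X = np.concatenate(feats)[: cfg.sample_size]
    y = np.concatenate(labels)[: cfg.sample_size]
    return fit_linear_svm(TrainingSet(X, y), cfg)


# ---------------------------------------------------------------------------
# Fixture persistence and batch processing
# ---------------------------------------------------------------------------

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")
_TRUTH_TAGS = ("_veg", "_roi", "_overlay", "_mask")


def save_fixtures(
    fixtures: Sequence[Tuple[RgbImage, CanopyGroundTruth]],
    out_dir: Union[str, Path],
    manifest: Optional[pd.DataFrame] = None,
) -> None:
    """Write fixtures as PNG images plus truth masks and center JSONs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (img, truth) in enumerate(fixtures):
        stem = f"img_{i:04d}"
        img.save(out / f"{stem}.png")
        truth.vegetation.save(out / f"{stem}_veg.png")
        truth.roi.save(out / f"{stem}_roi.png")
        (out / f"{stem}_truth.json").write_text(
            json.dumps({"center": {"x": truth.center.x, "y": truth.center.y}})
        )
    if manifest is not None:
        manifest.to_csv(out / "manifest.csv", index=False)


def load_truth(image_path: Path):
    """Load the (roi mask, center) truth next to an image, if present."""
    stem = image_path.with_suffix("")
    roi_path = Path(f"{stem}_roi.png")
    center_path = Path(f"{stem}_truth.json")
    roi = BinaryMask.open(roi_path) if roi_path.exists() else None
    center = None
    if center_path.exists():
        d = json.loads(center_path.read_text())
        center = PixelCoord(x=int(d["center"]["x"]), y=int(d["center"]["y"]))
    return roi, center


@dataclass(frozen=True, eq=False)
class BatchResult:
    frames: pd.DataFrame
    qseg_report: Optional[QsegReport]
    recognition_report: Optional[RecognitionReport]
    n_failed: int

    @property
    def exit_code(self) -> int:
        return 0 if self.n_failed == 0 else 2


def _discover_images(directory: Path) -> List[Path]:
    paths = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in IMAGE_SUFFIXES and not any(p.stem.endswith(t) for t in _TRUTH_TAGS):
            paths.append(p)
    return paths


def run_batch(
    directory: Union[str, Path],
    model: LinearSvmModel,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Union[str, Path]] = None,
) -> BatchResult:
    """Process every image in a directory, in deterministic filename order.

    When truth masks/centers sit alongside the images, per-frame Qseg
    (post-processed mask vs. truth ROI) and the recognition rate at the
    size-scaled tolerance are also reported.  Unreadable images are logged
    and skipped; their count drives a nonzero exit code in the CLI.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValueError(f"run_batch: {directory} is not a directory")
    rows = []
    qsegs: List[float] = []
    detected: List[CenterResult] = []
    truth_centers: List[PixelCoord] = []
    n_failed = 0
    tol = None
    for path in _discover_images(directory):
        try:
            img = RgbImage.open(path)
        except Exception as e:  # noqa: BLE001 - skip-and-log contract
            logger.warning("skipping unreadable image %s: %s", path, e)
            n_failed += 1
            continue
        res = run_pipeline(img, model, cfg)
        if tol is None:
            tol = scaled_tolerance(img.shape, cfg.center_tolerance)
        row = {
            "image": path.name,
            "found": res.center.found,
            "x": res.center.center.x if res.center.found else None,
            "y": res.center.center.y if res.center.found else None,
            **res.diagnostics,
        }
        roi_truth, center_truth = load_truth(path)
        if roi_truth is not None:
            q = qseg(res.post_mask, roi_truth)
            qsegs.append(q)
            row["qseg"] = q
        if center_truth is not None:
            detected.append(res.center)
            truth_centers.append(center_truth)
            d = (
                res.center.center.distance_to(center_truth)
                if res.center.found
                else float("inf")
            )
            row["distance"] = d
            row["recognized"] = d <= tol
        rows.append(row)
    frames = pd.DataFrame(rows)
    q_report = summarize_quality(qsegs) if qsegs else None
    r_report = (
        recognition_rate(detected, truth_centers, tol=tol) if truth_centers else None
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames.to_csv(out / "results.csv", index=False)
        summary = _summary_text(q_report, r_report, n_failed)
        (out / "summary.txt").write_text(summary)
    return BatchResult(frames=frames, qseg_report=q_report, recognition_report=r_report, n_failed=n_failed)


def _summary_text(q: Optional[QsegReport], r: Optional[RecognitionReport], n_failed: int) -> str:
    lines = []
    if q is not None:
        lines.append(f"Segmentation quality: mean {q.mean_pct:.2f}% SD {q.sd_pct:.2f}% (n={q.n})")
    if r is not None:
        lines.append(f"Recognition rate: {r.rate_pct:.2f}% ({r.recognized}/{r.n})")
    if n_failed:
        lines.append(f"Unreadable images skipped: {n_failed}")
    if not lines:
        lines.append("No frames evaluated.")
    return "\n".join(lines) + "\n"
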