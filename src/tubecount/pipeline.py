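"""Batch quantification: the two-stage workflow over many images."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import RunConfig
from .segment import segment_foreground
from .tubes import QuantifyResult, quantify_tubes

logger = logging.getLogger("tubecount")


@dataclass
class QuantifyReport:
    """Per-image statistics plus per-tube detail for a batch run."""

    per_image: pd.DataFrame
    per_tube: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)  # (image, error)

    @property
    def ok(self) -> bool:
        return not self.failures


def quantify_image(
    img: np.ndarray,
    tube_endpoints: list[tuple[tuple[int, int], tuple[int, int]]],
    cfg: RunConfig,
) -> tuple[np.ndarray, QuantifyResult]:
    """Segment one image and quantify its annotated tubes."""
    mask = segment_foreground(img, cfg.segment, cfg.enhance)
    result = quantify_tubes(
        mask,
        tube_endpoints,
        snap_radius=cfg.tubes.snap_radius,
        merge_eps=cfg.tubes.merge_eps,
        pixel_size=cfg.pixel_size,
    )
    return mask, result


def run_quantify(
    image_paths: list[str | Path],
    annotation_paths: list[str | Path],
    cfg: RunConfig,
    out_dir: str | Path | None = None,
) -> QuantifyReport:
    """Quantify a batch of annotated images.

    Writes, when ``out_dir`` is given: the foreground mask per image, a
    per-image statistics CSV and a per-tube CSV.  A missing or corrupt
    image is recorded as a failure and the run continues.
    """
    if len(image_paths) != len(annotation_paths):
        raise ValueError("need exactly one annotation file per image")
    cfg.validate()

    image_rows, tube_rows, failures = [], [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for img_path, ann_path in zip(image_paths, annotation_paths):
        name = Path(img_path).name
        try:
            img = tio.read_image(img_path)
            _, endpoints = tio.read_annotation(ann_path)
            mask, result = quantify_image(img, endpoints, cfg)
        except Exception as exc:  # per-file failure must not abort the batch
            logger.error("failed on %s: %s", img_path, exc)
            failures.append((str(img_path), str(exc)))
            continue
        row = {"image": name, **result.stats.as_dict(),
               "n_annotated": len(endpoints), "n_skipped": len(result.skipped)}
        image_rows.append(row)
        for k, path in enumerate(result.paths):
            tube_rows.append({
                "image": name,
                "tube": k,
                "length": path.length * (cfg.pixel_size or 1.0),
                "mean_width": path.mean_width * (cfg.pixel_size or 1.0),
                "area": path.area_px * (cfg.pixel_size or 1.0) ** 2,
                "start_row": path.start[0], "start_col": path.start[1],
                "end_row": path.end[0], "end_col": path.end[1],
            })
        for idx, reason in result.skipped:
            logger.warning("%s: tube %d skipped: %s", name, idx, reason)
        if out_dir is not None:
            tio.write_mask(out_dir / f"{Path(img_path).stem}_mask.png", mask)

    stat_cols = ["image", "total_length", "average_length", "average_width",
                 "n_tubes", "n_branching_points", "total_tube_area",
                 "n_annotated", "n_skipped"]
    per_image = pd.DataFrame(image_rows, columns=stat_cols)
    per_tube = pd.DataFrame(
        tube_rows,
        columns=["image", "tube", "length", "mean_width", "area",
                 "start_row", "start_col", "end_row", "end_col"],
    )
    if out_dir is not None:
        per_image.to_csv(out_dir / "stats.csv", index=False)
        per_tube.to_csv(out_dir / "tubes.csv", index=False)
    return QuantifyReport(per_image=per_image, per_tube=per_tube, failures=failures)
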