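"""Reading and writing of images, masks, annotations and CT tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger("tubecount")

_RGB_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as float64.

    RGB(A) inputs are converted by Rec.709 luminance (logged); intensity
    values keep their stored scale (0..255 or 0..65535).
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] == 3:
            logger.info("converting RGB image %s to grayscale by luminance", path)
            arr = arr.astype(np.float64) @ _RGB_LUMA
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_image(path: str | Path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write a grayscale image, quantising with round-half-to-even."""
    path = Path(path)
    if bit_depth == 8:
        out = np.round(np.clip(img, 0, 255)).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(np.clip(img, 0, 65535)).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(path, out)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 mask back as boolean (any nonzero pixel is foreground)."""
    return read_image(path) > 0


def read_annotation(path: str | Path) -> tuple[str, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Read a tube-endpoint annotation file.

    Format: ``{"image": str, "tubes": [[[x1, y1], [x2, y2]], ...]}`` with
    x = column and y = row, as an operator clicking on screen would
    produce.  Returns the image id and (row, col) endpoint pairs.
    """
    with open(path) as fh:
        doc = json.load(fh)
    tubes = []
    for pair in doc.get("tubes", []):
        (x1, y1), (x2, y2) = pair
        tubes.append(((int(y1), int(x1)), (int(y2), int(x2))))
    return doc.get("image", ""), tubes


def write_annotation(
    path: str | Path,
    image_id: str,
    tubes: list[tuple[tuple[int, int], tuple[int, int]]],
) -> None:
    """Write endpoint pairs (given as (row, col)) in the x/y annotation format."""
    doc = {
        "image": image_id,
        "tubes": [[[int(c1), int(r1)], [int(c2), int(r2)]] for (r1, c1), (r2, c2) in tubes],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR CT table (CSV with sample_id, condition, gene, ct)."""
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CT table {path} is missing columns: {sorted(missing)}")
    return df
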