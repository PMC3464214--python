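"""Stage-1 automated segmentation of phase-contrast micrographs.

The foreground (cell/tube) mask is the intersection of two independent
cues, both computed on the enhanced image:

* **multi-scale local-mean thresholding** — a pixel is a foreground
  candidate only if it is darker than the average intensity of its
  surrounding window *for every window size* in a multi-scale set; and
* **edge evidence** — Sobel gradient magnitudes are thresholded, the
  resulting edge fragments are connected by morphological closing,
  enclosed holes are filled, and small specks are discarded, yielding a
  bitmap of objects with distinct boundaries.

Pixels dark at all scales *and* inside an edge-bounded object form the
final mask.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .enhance import EnhanceConfig, _as_float_image, enhance

# slack for strict "< local mean" comparisons so that exact ties produced
# by floating-point moving sums (e.g. on a constant image) never count
_MEAN_TIE_EPS = 1e-9


@dataclass(frozen=True)
class SegmentConfig:
    """Parameters of the segmentation stage.

    Attributes
    ----------
    windows : tuple of int
        Odd side lengths (pixels) of the local-mean averaging windows.
        The defaults span sub-tube to super-tube scales on ~1 Mpx
        micrographs so the intersection rule has force.
    threshold_offset : float
        A pixel counts as dark only if below ``local mean - offset``;
        0 is the literal darker-than-average rule.
    edge_percentile : float
        Percentile of the gradient-magnitude distribution used as the
        edge threshold (scale-free across bit depths).
    connect_radius : int
        Disk radius (pixels) of the morphological closing that connects
        neighbouring edge fragments.
    min_object_px : int
        Connected components (8-connectivity) smaller than this are
        dropped from the edge-object bitmap and from the final mask.
    """

    windows: tuple[int, ...] = (15, 31, 63)
    threshold_offset: float = 0.0
    edge_percentile: float = 75.0
    connect_radius: int = 3
    min_object_px: int = 64

    def validate(self) -> None:
        if not self.windows:
            raise ValueError("windows list must be non-empty")
        if any(w < 3 or w % 2 == 0 for w in self.windows):
            raise ValueError(f"all windows must be odd and >= 3, got {self.windows}")
        if not 0 < self.edge_percentile < 100:
            raise ValueError(f"edge_percentile must be in (0, 100), got {self.edge_percentile}")
        if self.connect_radius < 0:
            raise ValueError("connect_radius must be >= 0")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")


def local_mean_threshold(img: np.ndarray, window: int, offset: float = 0.0) -> np.ndarray:
    """Mark pixels strictly darker than their windowed mean minus ``offset``.

    The mean is taken over a ``window``x``window`` neighbourhood with
    edge replication.  On a uniform image nothing is strictly below its
    own mean, so the mask is empty.
    """
    arr = _as_float_image(img)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > max(arr.shape):
        raise ValueError(f"window {window} larger than both image dimensions {arr.shape}")
    local_mean = ndimage.uniform_filter(arr, size=window, mode="nearest")
    scale = max(1.0, float(np.abs(arr).max()))
    return (local_mean - arr) > (offset + _MEAN_TIE_EPS * scale)


def multiscale_threshold(
    img: np.ndarray, windows: tuple[int, ...], offset: float = 0.0
) -> np.ndarray:
    """Pixels darker than their local mean at *every* window size.

    Pixelwise AND of :func:`local_mean_threshold` across the window set:
    only pixels that show below-average intensity regardless of
    averaging scale survive.
    """
    if not windows:
        raise ValueError("windows list must be non-empty")
    arr = _as_float_image(img)
    mask = np.ones(arr.shape, dtype=bool)
    for w in windows:
        mask &= local_mean_threshold(arr, w, offset)
    return mask


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) from the standard 3x3 Sobel
    kernels, with edge-replicated borders."""
    arr = _as_float_image(img)
    gy = ndimage.sobel(arr, axis=0, mode="nearest")
    gx = ndimage.sobel(arr, axis=1, mode="nearest")
    return np.hypot(gx, gy)


def sobel_edge_mask(
    img: np.ndarray, edge_percentile: float = 75.0, noise_floor: float = 3.0
) -> np.ndarray:
    """Threshold Sobel gradient magnitudes at a percentile.

    Foreground pixels have magnitude at or above the given percentile of
    all magnitudes, and also above ``noise_floor`` times the median
    magnitude: a fixed percentile alone would mark the top quantile of
    *any* gradient field, including one containing nothing but sensor
    noise, whereas real cell boundaries stand far above the median.
    Zero-gradient pixels never count as edges, so a constant image
    yields an empty mask rather than an error.
    """
    if not 0 < edge_percentile < 100:
        raise ValueError(f"edge_percentile must be in (0, 100), got {edge_percentile}")
    mag = sobel_magnitude(img)
    if mag.max() == 0.0:
        return np.zeros(mag.shape, dtype=bool)
    thr = max(np.percentile(mag, edge_percentile), noise_floor * np.median(mag))
    return (mag >= thr) & (mag > 0)


def _remove_small_objects(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_px`` pixels."""
    if min_px <= 0 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    counts = np.bincount(labels.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[labels]


def fill_connect(
    edges: np.ndarray, connect_radius: int = 3, min_object_px: int = 64
) -> np.ndarray:
    """Turn edge fragments into solid objects.

    Morphological closing with a disk of ``connect_radius`` bridges gaps
    between neighbouring edges, enclosed holes are flood-filled
    (background 4-connectivity), and 8-connected components smaller than
    ``min_object_px`` are removed.
    """
    mask = np.asarray(edges, dtype=bool)
    if connect_radius < 0:
        raise ValueError("connect_radius must be >= 0")
    if connect_radius > 0:
        # pad by the radius so the closing behaves as on an infinite
        # background plane: the dilation may spill past the frame and the
        # erosion must still see that spill, otherwise border pixels are
        # clipped (scipy) or invented (reflect-padded) incorrectly
        footprint = morphology.disk(connect_radius).astype(bool)
        padded = np.pad(mask, connect_radius)
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(padded, structure=footprint), structure=footprint,
            border_value=0,
        )
        mask = closed[connect_radius:-connect_radius, connect_radius:-connect_radius]
    mask = ndimage.binary_fill_holes(mask)
    return _remove_small_objects(mask, min_object_px)


def segment_foreground(
    img: np.ndarray,
    cfg: SegmentConfig | None = None,
    enh_cfg: EnhanceConfig | None = None,
) -> np.ndarray:
    """Full stage-1 pipeline: enhance, then intersect the two cues.

    The result is contained in both the multi-scale threshold mask and
    the filled edge-object mask; small residual components are removed
    afterwards.
    """
    cfg = cfg or SegmentConfig()
    cfg.validate()
    enhanced = enhance(img, enh_cfg)
    dark = multiscale_threshold(enhanced, cfg.windows, cfg.threshold_offset)
    edge_objects = fill_connect(
        sobel_edge_mask(enhanced, cfg.edge_percentile),
        cfg.connect_radius,
        cfg.min_object_px,
    )
    mask = dark & edge_objects
    return _remove_small_objects(mask, cfg.min_object_px)


def scaled_windows(
    shape: tuple[int, int], base: tuple[int, ...] = (15, 31, 63), base_min_dim: int = 1024
) -> tuple[int, ...]:
    """Scale the default window set to an image size, keeping sizes odd >= 3."""
    factor = min(shape) / base_min_dim
    out = []
    for w in base:
        s = max(3, int(round(w * factor)))
        if s % 2 == 0:
            s += 1
        out.append(s)
    return tuple(dict.fromkeys(out))
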