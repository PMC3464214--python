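"""Seeded synthetic-image generators with exact ground truth.

Real tube-formation, scratch-wound and single-cell micrographs are not
redistributable, so every processing stage is exercised on synthetic
images that emulate their defining features:

* tube networks — dark, well-edged elongated structures on a brighter
  background with a multiplicative illumination ramp and additive
  Gaussian noise (the phase-contrast appearance the segmentation
  assumes);
* wound series — a textured cell monolayer with a centred cell-free
  vertical band that shrinks over time;
* cell shapes — single silhouettes with analytic area and perimeter.

Shapes are rendered with 4x supersampling; the ground-truth mask is the
majority vote of the subpixels under each full-resolution pixel.  Every
generator is a pure function of its spec (seed included): identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special
from skimage import draw

from .tubes import TubeStats

_SUPERSAMPLE = 4


class GenerationError(RuntimeError):
    """The requested fixture cannot be realised (tubes do not fit, ...)."""


@dataclass(frozen=True)
class TubeNetworkSpec:
    """Conditions of a synthetic tube-formation image.

    Defaults emulate a typical phase-contrast field: dark tubes
    (~80/255) on a bright (~200/255) background, a ±20% left-to-right
    illumination ramp, and Gaussian noise at 2% of the intensity range.
    """

    image_size: tuple[int, int] = (256, 256)
    n_tubes: int = 8
    width_range: tuple[float, float] = (4.0, 8.0)
    intensity_tube: float = 80.0
    intensity_bg: float = 200.0
    illumination_ramp: tuple[float, float] = (0.8, 1.2)
    noise_sigma: float = 0.02  # fraction of the 255 range
    branch_prob: float = 0.3
    seed: int = 0
    min_tube_length: float = 50.0
    margin: int = 16
    endpoint_separation: float = 30.0  # between distinct junctions

    def validate(self) -> None:
        if min(self.width_range) < 2:
            raise ValueError("tube widths must be >= 2 px")
        if not 0 <= self.noise_sigma < 0.2:
            raise ValueError("noise_sigma must be in [0, 0.2)")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be >= 0")


@dataclass
class GroundTruth:
    """Exact truth accompanying a generated tube-network image."""

    mask: np.ndarray  # full-resolution boolean mask
    lengths: list[float]  # per-tube Euclidean centerline lengths (px)
    widths: list[float]  # per-tube widths (px)
    endpoints: list[tuple[tuple[float, float], tuple[float, float]]]
    n_branching_points: int
    stats: TubeStats = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.lengths)
        total_len = float(sum(self.lengths))
        if n:
            weights = np.array([l * w for l, w in zip(self.lengths, self.widths)])
            avg_width = float(np.average(self.widths, weights=weights))
        else:
            avg_width = 0.0
        self.stats = TubeStats(
            total_length=total_len,
            average_length=total_len / n if n else 0.0,
            average_width=avg_width,
            n_tubes=n,
            n_branching_points=self.n_branching_points,
            total_tube_area=float(self.mask.sum()),
        )


def _segment_mask_ss(
    shape_ss: tuple[int, int], p0: np.ndarray, p1: np.ndarray, width: float
) -> np.ndarray:
    """Supersampled mask of a thick segment (capsule), coordinates in px units."""
    s = _SUPERSAMPLE
    h_ss, w_ss = shape_ss
    half = width / 2.0
    pad = half + 2.0
    r_lo = max(0, int((min(p0[0], p1[0]) - pad) * s))
    r_hi = min(h_ss, int((max(p0[0], p1[0]) + pad) * s) + 1)
    c_lo = max(0, int((min(p0[1], p1[1]) - pad) * s))
    c_hi = min(w_ss, int((max(p0[1], p1[1]) + pad) * s) + 1)
    mask = np.zeros(shape_ss, dtype=bool)
    if r_hi <= r_lo or c_hi <= c_lo:
        return mask
    rr = (np.arange(r_lo, r_hi) + 0.5) / s - 0.5
    cc = (np.arange(c_lo, c_hi) + 0.5) / s - 0.5
    Y, X = np.meshgrid(rr, cc, indexing="ij")
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.hypot(Y - p0[0], X - p0[1])
    else:
        t = ((Y - p0[0]) * d[0] + (X - p0[1]) * d[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(Y - (p0[0] + t * d[0]), X - (p0[1] + t * d[1]))
    mask[r_lo:r_hi, c_lo:c_hi] = dist <= half
    return mask


def _downsample_majority(mask_ss: np.ndarray) -> np.ndarray:
    s = _SUPERSAMPLE
    h, w = mask_ss.shape[0] // s, mask_ss.shape[1] // s
    blocks = mask_ss.reshape(h, s, w, s).mean(axis=(1, 3))
    return blocks >= 0.5


def _downsample_mean(arr_ss: np.ndarray) -> np.ndarray:
    s = _SUPERSAMPLE
    h, w = arr_ss.shape[0] // s, arr_ss.shape[1] // s
    return arr_ss.reshape(h, s, w, s).mean(axis=(1, 3))


def generate_tube_network(
    spec: TubeNetworkSpec,
) -> tuple[np.ndarray, GroundTruth, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Render a tube network and return (image, ground truth, annotation).

    Tubes are straight thick segments; with probability ``branch_prob`` a
    new tube starts exactly at the endpoint of an earlier tube, so
    junction nodes with three or more incident tubes are true branching
    points.  The annotation lists the integer endpoint pairs an operator
    would click.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    m = spec.margin
    if h - 2 * m <= spec.min_tube_length / 2 or w - 2 * m <= spec.min_tube_length / 2:
        raise GenerationError(f"image {spec.image_size} too small for tubes of "
                              f"length >= {spec.min_tube_length}")

    def rand_point() -> np.ndarray:
        return np.array([rng.uniform(m, h - m), rng.uniform(m, w - m)])

    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    endpoints_flat: list[np.ndarray] = []

    max_attempts = 2000
    attempts = 0
    while len(segments) < spec.n_tubes:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {spec.n_tubes} tubes in {spec.image_size} "
                f"after {max_attempts} attempts"
            )
        branch = segments and rng.random() < spec.branch_prob
        if branch:
            p0 = endpoints_flat[rng.integers(len(endpoints_flat))].copy()
        else:
            p0 = rand_point()
        p1 = rand_point()
        length = float(np.hypot(*(p1 - p0)))
        if length < spec.min_tube_length:
            continue
        # keep distinct junctions separated so the annotated topology is unambiguous
        sep = spec.endpoint_separation
        ok = True
        for q in endpoints_flat:
            d0 = float(np.hypot(*(p0 - q)))
            d1 = float(np.hypot(*(p1 - q)))
            if (0 < d0 < sep) or (d1 < sep):
                ok = False
                break
        if not ok:
            continue
        width = float(rng.uniform(*spec.width_range))
        segments.append((p0, p1, width))
        endpoints_flat.extend([p0, p1])

    shape_ss = (h * _SUPERSAMPLE, w * _SUPERSAMPLE)
    union_ss = np.zeros(shape_ss, dtype=bool)
    for p0, p1, width in segments:
        union_ss |= _segment_mask_ss(shape_ss, p0, p1, width)
    mask = _downsample_majority(union_ss)
    coverage = _downsample_mean(union_ss.astype(np.float64))

    img = spec.intensity_bg + (spec.intensity_tube - spec.intensity_bg) * coverage
    ramp = np.linspace(spec.illumination_ramp[0], spec.illumination_ramp[1], w)
    img = img * ramp[None, :]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma * 255.0, size=img.shape)
    img = np.clip(img, 0.0, 255.0)

    # branching points: cluster exactly-coincident endpoints, count degree >= 3
    n_branch = 0
    if segments:
        keys = {}
        degree: dict[int, int] = {}
        next_id = 0
        for p0, p1, _ in segments:
            for p in (p0, p1):
                key = (round(float(p[0]), 6), round(float(p[1]), 6))
                if key not in keys:
                    keys[key] = next_id
                    next_id += 1
                degree[keys[key]] = degree.get(keys[key], 0) + 1
        n_branch = sum(1 for d in degree.values() if d >= 3)

    truth = GroundTruth(
        mask=mask,
        lengths=[float(np.hypot(*(p1 - p0))) for p0, p1, _ in segments],
        widths=[width for _, _, width in segments],
        endpoints=[(tuple(p0), tuple(p1)) for p0, p1, _ in segments],
        n_branching_points=n_branch,
    )
    annotation = [
        (
            (int(round(p0[0])), int(round(p0[1]))),
            (int(round(p1[0])), int(round(p1[1]))),
        )
        for p0, p1, _ in segments
    ]
    return img, truth, annotation


def generate_wound_series(
    image_size: tuple[int, int],
    band_widths_px: list[int],
    seed: int = 0,
    intensity_bg: float = 200.0,
    intensity_cell: float = 110.0,
    noise_sigma: float = 0.02,
    cell_diameter_px: float = 15.0,
    seam_width_px: float = 2.0,
) -> tuple[list[np.ndarray], list[np.ndarray], list[float]]:
    """Synthetic scratch-wound time series.

    Returns ``(images, cell_masks, open_fractions_pct)``: one textured
    monolayer image per band width, with a centred cell-free vertical
    band; the true open fraction is ``band_width / image_width * 100``.
    Band widths must be non-increasing (wounds close, they do not open).

    The monolayer is a confluent tessellation of dark polygonal cells
    (mean diameter ``cell_diameter_px``) separated by thin bright seams —
    the Voronoi-like appearance of a phase-contrast monolayer, where each
    cell is outlined by a bright halo at its boundary.
    """
    h, w = image_size
    if any(b > w for b in band_widths_px):
        raise ValueError("band wider than the image")
    if any(b < 0 for b in band_widths_px):
        raise ValueError("band widths must be >= 0")
    if any(b1 > b0 for b0, b1 in zip(band_widths_px, band_widths_px[1:])):
        raise ValueError("band widths must be non-increasing over time")
    rng = np.random.default_rng(seed)
    images, masks, fractions = [], [], []
    # one fixed monolayer texture reused across time points, like the same
    # field imaged repeatedly as cells migrate into the shrinking band
    from scipy.spatial import cKDTree

    # jittered grid keeps neighbouring nuclei separated (cells do not
    # overlap); fully random centers would create near-coincident pairs
    # whose equidistance band blows up into large bright patches
    d = cell_diameter_px
    gy = np.arange(d / 2, h, d)
    gx = np.arange(d / 2, w, d)
    grid = np.array([[y, x] for y in gy for x in gx])
    centers = grid + rng.uniform(-0.35 * d, 0.35 * d, size=grid.shape)
    yy, xx = np.mgrid[0:h, 0:w]
    dists, _ = cKDTree(centers).query(np.column_stack([yy.ravel(), xx.ravel()]), k=2)
    # bright seam where the two nearest cell centers are nearly equidistant
    seam = (dists[:, 1] - dists[:, 0]).reshape(h, w) < seam_width_px
    texture = np.where(seam, intensity_bg, intensity_cell)
    for band in band_widths_px:
        c0 = (w - band) // 2
        cell_mask = np.ones((h, w), dtype=bool)
        cell_mask[:, c0 : c0 + band] = False
        img = np.where(cell_mask, texture, intensity_bg)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma * 255.0, size=img.shape)
        images.append(np.clip(img, 0.0, 255.0))
        masks.append(cell_mask)
        fractions.append(100.0 * band / w)
    return images, masks, fractions


def _ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter 4 a E(e^2) via the complete elliptic integral."""
    a, b = max(a, b), min(a, b)
    e2 = 1.0 - (b / a) ** 2
    return 4.0 * a * float(special.ellipe(e2))


def _star_polygon(n_points: int, r_outer: float, r_inner: float,
                  center: tuple[float, float]) -> np.ndarray:
    angles = np.arange(2 * n_points) * math.pi / n_points - math.pi / 2
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return np.column_stack([rows, cols])


def _polygon_area_perimeter(verts: np.ndarray) -> tuple[float, float]:
    closed = np.vstack([verts, verts[:1]])
    d = closed[1:] - closed[:-1]
    perimeter = float(np.hypot(d[:, 0], d[:, 1]).sum())
    x, y = closed[:, 1], closed[:, 0]
    area = 0.5 * abs(float(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])))
    return area, perimeter


def generate_cell_shapes(
    shape_list: list[tuple[str, dict]], seed: int = 0
) -> list[tuple[np.ndarray, dict]]:
    """Render single-cell silhouettes with analytic shape truth.

    ``shape_list`` holds ``(kind, params)`` with kinds ``disk`` (r),
    ``ellipse`` (a, b), ``rectangle`` (width, height) and ``star``
    (n_points, r_outer, r_inner).  Returns, per shape, the 0/255 image
    and a truth dict with analytic area, perimeter and circularity.
    """
    out = []
    s = _SUPERSAMPLE
    for kind, params in shape_list:
        if kind == "disk":
            r = float(params["r"])
            half = int(math.ceil(r)) + 4
            size = 2 * half
            cy = cx = half - 0.5
            yy = (np.arange(size * s) + 0.5) / s - 0.5
            Y, X = np.meshgrid(yy, yy, indexing="ij")
            mask_ss = (Y - cy) ** 2 + (X - cx) ** 2 <= r * r
            area, perim = math.pi * r * r, 2 * math.pi * r
        elif kind == "ellipse":
            a, b = float(params["a"]), float(params["b"])
            half = int(math.ceil(max(a, b))) + 4
            size = 2 * half
            cy = cx = half - 0.5
            yy = (np.arange(size * s) + 0.5) / s - 0.5
            Y, X = np.meshgrid(yy, yy, indexing="ij")
            mask_ss = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
            area, perim = math.pi * a * b, _ellipse_perimeter(a, b)
        elif kind == "rectangle":
            rw, rh = float(params["width"]), float(params["height"])
            size = int(math.ceil(max(rw, rh))) + 8
            cy = cx = size / 2 - 0.5
            yy = (np.arange(size * s) + 0.5) / s - 0.5
            Y, X = np.meshgrid(yy, yy, indexing="ij")
            mask_ss = (np.abs(X - cx) <= rw / 2) & (np.abs(Y - cy) <= rh / 2)
            area, perim = rw * rh, 2 * (rw + rh)
        elif kind == "star":
            n_pts = int(params.get("n_points", 5))
            r_out, r_in = float(params["r_outer"]), float(params["r_inner"])
            size = 2 * (int(math.ceil(r_out)) + 4)
            verts = _star_polygon(n_pts, r_out, r_in, (size / 2 - 0.5, size / 2 - 0.5))
            area, perim = _polygon_area_perimeter(verts)
            rr, cc = draw.polygon((verts[:, 0] + 0.5) * s - 0.5,
                                  (verts[:, 1] + 0.5) * s - 0.5,
                                  shape=(size * s, size * s))
            mask_ss = np.zeros((size * s, size * s), dtype=bool)
            mask_ss[rr, cc] = True
        else:
            raise ValueError(f"unknown shape kind {kind!r}")
        mask = _downsample_majority(mask_ss)
        image = np.where(mask, 255.0, 0.0)
        truth = {
            "kind": kind,
            "area": area,
            "perimeter": perim,
            "circularity": perim * perim / (4.0 * math.pi * area),
            "mask": mask,
        }
        out.append((image, truth))
    return out
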