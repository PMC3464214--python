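"""Stage-1 image quality enhancement for phase-contrast micrographs.

Phase-contrast images of cells on Matrigel show dark, well-edged cell
bodies on a brighter background that is typically corrupted by a smooth
multiplicative illumination gradient (uneven lamp field) and shot-like
noise.  The enhancement stage prepares such an image for intensity-based
segmentation by

1. removing impulse noise with a median filter,
2. flattening the illumination field with a homomorphic (log-domain
   frequency) filter, and
3. stretching the contrast so the thresholding stage sees the full
   dynamic range.

All arithmetic is done in float64; quantisation back to the storage bit
depth happens only at I/O boundaries (see :mod:`tubecount.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the enhancement pipeline.

    Attributes
    ----------
    median_window : int
        Side of the square median-filter window, odd, >= 1 (pixels).
    hp_cutoff : float
        Cutoff of the homomorphic high-emphasis filter as a fraction of
        the image diagonal in frequency units, in (0, 1).
    gain_low, gain_high : float
        Transfer-function gains at DC and far above the cutoff;
        ``gain_high >= gain_low > 0``.  Values below 1 at DC attenuate
        the (multiplicative) illumination field.
    stretch_low_pct, stretch_high_pct : float
        Percentiles mapped to the range minimum / maximum by the final
        contrast stretch.
    """

    median_window: int = 3
    hp_cutoff: float = 0.05
    gain_low: float = 0.5
    gain_high: float = 1.5
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0

    def validate(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError(f"median_window must be odd and >= 1, got {self.median_window}")
        if not 0 < self.hp_cutoff < 1:
            raise ValueError(f"hp_cutoff must be in (0, 1), got {self.hp_cutoff}")
        if not (self.gain_high >= self.gain_low > 0):
            raise ValueError(
                f"need gain_high >= gain_low > 0, got {self.gain_low}, {self.gain_high}"
            )
        if not 0 <= self.stretch_low_pct < self.stretch_high_pct <= 100:
            raise ValueError(
                "need 0 <= stretch_low_pct < stretch_high_pct <= 100, got "
                f"({self.stretch_low_pct}, {self.stretch_high_pct})"
            )


def _as_float_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def median_denoise(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with a ``window``x``window`` neighbourhood.

    Borders are handled by edge replication, so a constant image is a
    fixed point and output values never leave the input's [min, max].
    """
    arr = _as_float_image(img)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"median window must be odd and positive, got {window}")
    if window == 1:
        return arr.copy()
    return ndimage.median_filter(arr, size=window, mode="nearest")


def homomorphic_filter(
    img: np.ndarray,
    gain_low: float = 0.5,
    gain_high: float = 1.5,
    hp_cutoff: float = 0.05,
) -> np.ndarray:
    """Suppress multiplicative illumination gradients.

    The image is taken to be ``illumination x reflectance``.  After
    ``log(1 + I)`` the product becomes a sum; low spatial frequencies
    (the illumination field) are attenuated by a Gaussian high-emphasis
    transfer function

        H(f) = gain_low + (gain_high - gain_low) * (1 - exp(-f^2 / (2 fc^2)))

    with ``fc = hp_cutoff * sqrt(h^2 + w^2)`` in DFT index units, and the
    result is exponentiated back and rescaled to the input's [min, max].
    With ``gain_low == gain_high == 1`` the operator is the identity (up
    to round-trip error).

    The image is mirror-padded before the transform: the DFT is cyclic,
    and without padding an illumination gradient wraps around the border
    and rings back into the image as spurious dark/bright bands.
    """
    arr = _as_float_image(img)
    if np.any(arr < 0):
        raise ValueError("homomorphic filter requires non-negative intensities")
    if not (gain_high >= gain_low > 0):
        raise ValueError("need gain_high >= gain_low > 0")
    if not 0 < hp_cutoff < 1:
        raise ValueError("hp_cutoff must be in (0, 1)")

    in_min, in_max = float(arr.min()), float(arr.max())

    h, w = arr.shape
    pad_h = h // 2 if h > 1 else 0
    pad_w = w // 2 if w > 1 else 0
    log_img = np.pad(np.log1p(arr), ((pad_h, pad_h), (pad_w, pad_w)), mode="reflect")
    spectrum = np.fft.fft2(log_img)

    ph, pw = log_img.shape
    fy = np.fft.fftfreq(ph, d=1.0 / ph)  # DFT index units
    fx = np.fft.fftfreq(pw, d=1.0 / pw)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    # cutoff scales with the padded grid so one hp_cutoff value means the
    # same spatial scale regardless of padding
    fc = hp_cutoff * float(np.hypot(ph, pw))
    transfer = gain_low + (gain_high - gain_low) * (1.0 - np.exp(-f2 / (2.0 * fc * fc)))

    filtered = np.real(np.fft.ifft2(spectrum * transfer))
    filtered = filtered[pad_h : pad_h + h, pad_w : pad_w + w]
    out = np.expm1(filtered)

    out_min, out_max = float(out.min()), float(out.max())
    if out_max - out_min <= 1e-12 * max(1.0, abs(out_max)):
        # no spatial structure survived (constant input) -- keep level
        return np.full_like(arr, (in_min + in_max) / 2.0)
    if in_max > in_min:
        out = in_min + (out - out_min) * (in_max - in_min) / (out_max - out_min)
    return out


def contrast_stretch(
    img: np.ndarray,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    out_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Percentile-based linear contrast stretch with clipping.

    Intensities at or below the ``low_pct`` percentile map to
    ``out_range[0]``, at or above ``high_pct`` to ``out_range[1]``,
    linearly in between.  A constant image is returned unchanged with a
    warning (the stretch is undefined there).
    """
    arr = _as_float_image(img)
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    lo = float(np.percentile(arr, low_pct))
    hi = float(np.percentile(arr, high_pct))
    if hi <= lo:
        warnings.warn(
            "contrast_stretch: degenerate percentile band (constant or near-constant "
            "image); returning input unchanged",
            stacklevel=2,
        )
        return arr.copy()
    out_lo, out_hi = out_range
    out = (np.clip(arr, lo, hi) - lo) * ((out_hi - out_lo) / (hi - lo)) + out_lo
    return out


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Full stage-1 enhancement: median -> homomorphic -> stretch.

    Impulses are removed before the frequency-domain filter so they do
    not leak into the spectrum, and the stretch comes last so the
    thresholding stage sees the full dynamic range.  Deterministic.
    """
    cfg = cfg or EnhanceConfig()
    cfg.validate()
    arr = _as_float_image(img)
    arr = median_denoise(arr, cfg.median_window)
    arr = np.maximum(arr, 0.0)
    arr = homomorphic_filter(arr, cfg.gain_low, cfg.gain_high, cfg.hp_cutoff)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant image passes through silently here
        arr = contrast_stretch(arr, cfg.stretch_low_pct, cfg.stretch_high_pct)
    return arr
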