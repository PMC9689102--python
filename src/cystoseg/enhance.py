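"""Pre-processing for cystoscopy frames.

The pipeline runs four stages in order:

1. **Guided filtering** — edge-preserving noise reduction with the image
   as its own guide, per channel. The urologist-facing strength dial
   ``r`` (0..5) maps linearly to the box-window half-width.
2. **Unsharp masking on luminance** — contrast enhancement that sharpens
   only the luminance channel, so pixel hues are preserved. With
   luminance approximated as the channel mean, each pixel is scaled by
   ``1 + lam * (1 - lum(filtered) / lum(input))``. Inside the pipeline
   the sharpening stage receives the noise-reduced frame and estimates
   its low-pass with a fixed-strength guided filter
   (``usm_lowpass_r``), independent of the ``r`` dial — so ``r`` and
   ``lam`` act as two independent controls and all four of
   original / filtered / sharpened / enhanced are distinct frames.
3. **Crop + resize** — optional margin crop, then bilinear resize to a
   square model input (default 160 x 160).
4. **Standardization** — zero mean, unit standard deviation over the
   whole frame (all channels pooled), as the network input convention.

Images are H x W x 3 float arrays in [0, 1]; 8-bit files map to [0, 1]
by division with 255 (see :mod:`cystoseg.imgio`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _replace

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: luminance below this is treated as black: sharpening is skipped there
ZERO_LUM_GUARD = 1e-6

#: dial-to-window mapping: box half-width = round(r * R_TO_HALFWIDTH)
R_TO_HALFWIDTH = 2


@dataclass
class EnhanceParams:
    """Enhancement settings.

    Parameters
    ----------
    r : float
        Guided-filter strength in [0, 5]; 0 disables filtering exactly,
        5 is strong blurring. The box-window half-width is
        ``round(2 * r)`` pixels.
    lam : float
        Unsharp-masking strength (the λ of ``R = P + λU``) in [0, 5];
        0 disables sharpening exactly.
    target_size : int
        Side length of the square model input, default 160.
    eps : float
        Guided-filter edge regularizer on the [0, 1] intensity scale.
        Smaller values preserve more edges.
    usm_lowpass_r : float
        Strength of the fixed guided filter that estimates the
        low-pass image for the unsharp-masking stage of the pipeline.
        Deliberately decoupled from ``r`` so sharpening works even when
        noise reduction is off.
    """

    r: float = 5.0
    lam: float = 5.0
    target_size: int = 160
    eps: float = 1e-3
    usm_lowpass_r: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 5.0:
            raise ValueError(f"r must be in [0, 5], got {self.r}")
        if not 0.0 <= self.lam <= 5.0:
            raise ValueError(f"lam must be in [0, 5], got {self.lam}")
        if self.target_size < 8:
            raise ValueError(f"target_size must be >= 8, got {self.target_size}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"image sides must be >= 8, got {img.shape[:2]}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixel values")
    return img


def box_mean(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Mean over the (2w+1)^2 box clipped to the image.

    Near the border the mean is taken over the pixels that actually fall
    inside the image (no padding bias), which keeps smoothing unbiased
    in the dark vignetted corners.
    """
    if halfwidth == 0:
        return x.astype(np.float64, copy=True)
    w = halfwidth
    # integral-image sums over the clipped window, then divide by count
    def _sums(a: np.ndarray) -> np.ndarray:
        c = np.cumsum(np.cumsum(a, axis=0), axis=1)
        c = np.pad(c, ((1, 0), (1, 0)))
        h, wd = a.shape
        r0 = np.clip(np.arange(h) - w, 0, h)
        r1 = np.clip(np.arange(h) + w + 1, 0, h)
        c0 = np.clip(np.arange(wd) - w, 0, wd)
        c1 = np.clip(np.arange(wd) + w + 1, 0, wd)
        return (c[np.ix_(r1, c1)] - c[np.ix_(r0, c1)]
                - c[np.ix_(r1, c0)] + c[np.ix_(r0, c0)])

    counts = _sums(np.ones(x.shape, dtype=np.float64))
    return _sums(np.asarray(x, dtype=np.float64)) / counts


def guided_filter(img: np.ndarray, params: EnhanceParams) -> np.ndarray:
    """Edge-preserving smoothing with the image as its own guide.

    Per channel, the output is the local linear model
    ``q = mean(a) * I + mean(b)`` with ``a = var / (var + eps)`` and
    ``b = (1 - a) * mean(I)`` computed over box windows. ``r = 0``
    returns the input unchanged.
    """
    img = _check_image(img)
    w = int(round(params.r * R_TO_HALFWIDTH))
    if w == 0:
        return img.copy()
    out = np.empty_like(img)
    for ch in range(3):
        i = img[:, :, ch]
        mean_i = box_mean(i, w)
        var_i = box_mean(i * i, w) - mean_i * mean_i
        var_i = np.maximum(var_i, 0.0)  # numerical floor
        a = var_i / (var_i + params.eps)
        b = (1.0 - a) * mean_i
        out[:, :, ch] = box_mean(a, w) * i + box_mean(b, w)
    return out


def luminance(img: np.ndarray) -> np.ndarray:
    """Luminance approximated as the mean of the R, G, B intensities."""
    img = _check_image(img)
    return img.mean(axis=2)


def unsharp_mask(img: np.ndarray, filtered: np.ndarray,
                 params: EnhanceParams) -> np.ndarray:
    """Hue-preserving sharpening applied to the luminance channel only.

    Each pixel is scaled by ``1 + lam * (1 - lum(filtered)/lum(input))``
    and clamped to [0, 1]. Scaling all three channels by one factor
    leaves the channel ratios (the hue) unchanged wherever no clamping
    occurs. Pixels with luminance below ``ZERO_LUM_GUARD`` (black
    vignette corners) are passed through untouched.
    """
    img = _check_image(img)
    filtered = _check_image(filtered)
    if img.shape != filtered.shape:
        raise ValueError("img and filtered must share dimensions")
    if params.lam == 0.0:
        return img.copy()
    lum_p = luminance(img)
    lum_f = luminance(filtered)
    safe = lum_p >= ZERO_LUM_GUARD
    scale = np.ones_like(lum_p)
    np.divide(lum_f, lum_p, out=scale, where=safe)
    factor = np.where(safe, 1.0 + params.lam * (1.0 - scale), 1.0)
    return np.clip(img * factor[:, :, None], 0.0, 1.0)


def crop_resize(img: np.ndarray, params: EnhanceParams,
                crop_box: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """Crop margins (optional) and bilinearly resize to a square.

    ``crop_box`` is ``(row0, col0, row1, col1)`` with exclusive ends.
    Resampling is bilinear with the half-pixel-centre convention:
    output pixel centre ``u`` maps to input ``(u + 0.5) * scale - 0.5``,
    clamped at the border. Deterministic.
    """
    img = _check_image(img)
    if crop_box is not None:
        r0, c0, r1, c1 = crop_box
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ValueError(f"crop box {crop_box} invalid for shape {img.shape[:2]}")
        img = img[r0:r1, c0:c1]
    size = params.target_size
    h, w = img.shape[:2]
    if (h, w) == (size, size):
        return img.copy()
    rows = np.clip((np.arange(size) + 0.5) * (h / size) - 0.5, 0, h - 1)
    cols = np.clip((np.arange(size) + 0.5) * (w / size) - 0.5, 0, w - 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((size, size, 3), dtype=np.float64)
    for ch in range(3):
        out[:, :, ch] = ndimage.map_coordinates(
            img[:, :, ch], [rr, cc], order=1, mode="nearest")
    return out


def standardize(img: np.ndarray) -> np.ndarray:
    """Shift/scale the frame to zero mean and unit standard deviation.

    One mean and one standard deviation are computed over all pixels and
    channels pooled (population denominator). A constant frame has no
    scale; it maps to all zeros and a warning is logged.
    """
    img = _check_image(img)
    mu = img.mean()
    sigma = img.std()
    if sigma == 0.0:
        log.warning("standardize: constant image, returning zeros")
        return np.zeros_like(img)
    return (img - mu) / sigma


def usm_lowpass(img: np.ndarray, params: EnhanceParams) -> np.ndarray:
    """Low-pass estimate feeding the unsharp mask (fixed-strength filter)."""
    return guided_filter(img, _replace(params, r=params.usm_lowpass_r))


def enhance_pipeline(img: np.ndarray, params: EnhanceParams,
                     crop_box: tuple[int, int, int, int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Full pre-processing: filter, sharpen, crop/resize, standardize.

    The sharpening stage operates on the noise-reduced frame, with a
    fixed-strength low-pass for the mask, so ``r = 0`` / ``lam = 0``
    disable exactly their own stage and (r, lam) settings
    (0,0) / (5,0) / (0,5) / (5,5) give the original / filtered /
    sharpened / enhanced variants.

    Returns ``(display, model_input)``: the enhanced image in [0, 1] for
    display and overlays, and its standardized version for the network.
    """
    filtered = guided_filter(img, params)
    if params.lam > 0.0:
        sharpened = unsharp_mask(filtered, usm_lowpass(filtered, params), params)
    else:
        sharpened = filtered
    display = crop_resize(sharpened, params, crop_box)
    return display, standardize(display)
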