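"""Synthetic cystoscopy-like scenes with exact ground-truth masks.

The generator emulates the gross appearance of white-light cystoscopy
frames well enough to exercise every pipeline stage: a reddish-pink
mucosal background with smooth low-frequency texture and a dark radial
vignette, carrying up to four mutually disjoint blobby elliptical
"lesions" with class-characteristic colour shifts and speckle. The
mask is the exact rasterized generator geometry, so ground truth is
correct by construction. No attempt is made at photorealism, specular
optics or clinically plausible morphology.

The module also implements the study-style dataset plumbing: each
scene is saved in four pre-processing versions (original / filtered /
sharpened / enhanced, quadrupling the sample count), split 90:5:5 into
train/validation/test by scene so all four versions of a scene share a
split, plus the on-the-fly augmentation suite (intensity jitter, noise,
blur, sharpening, flips, rotation, 8 x 8 dropout squares).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from . import imgio
from .enhance import EnhanceParams, guided_filter, unsharp_mask, usm_lowpass
from .scheme import (AIR_BUBBLE, ARTIFACT, BCG_CYSTITIS, CANCER, NORMAL,
                     TURBT_SCAR, URETERIC_ORIFICE)

log = logging.getLogger(__name__)

LESION_CLASSES = (CANCER, BCG_CYSTITIS, TURBT_SCAR,
                  URETERIC_ORIFICE, AIR_BUBBLE, ARTIFACT)

#: per-class lesion base colour (RGB in [0, 1]); rough visual archetypes
_LESION_COLOR = {
    CANCER: (0.80, 0.30, 0.28),           # papillary, red-brown
    BCG_CYSTITIS: (0.88, 0.52, 0.30),     # inflamed orange patch
    TURBT_SCAR: (0.86, 0.80, 0.74),       # pale fibrotic tissue
    URETERIC_ORIFICE: (0.38, 0.14, 0.20), # dark slit
    AIR_BUBBLE: (0.95, 0.92, 0.88),       # bright rounded highlight
    ARTIFACT: (0.42, 0.72, 0.46),         # instrument/overlay green
}

_BACKGROUND_RGB = (0.74, 0.44, 0.46)


@dataclass
class SceneSpec:
    """Parameters of one synthetic frame.

    Lesion areas are enforced by pixel count (rejection sampling), the
    lesions are mutually disjoint, and their total area stays below
    half the frame.
    """

    image_size: int = 160
    n_lesions: int = 2
    class_pool: tuple[int, ...] = LESION_CLASSES
    lesion_area_range: tuple[int, int] = (200, 1200)
    vignette_strength: float = 0.5
    base_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_lesions <= 4:
            raise ValueError("n_lesions must be in 0..4")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if any(c == NORMAL or not 0 < c <= 6 for c in self.class_pool):
            raise ValueError("class_pool must hold lesion classes 1..6")
        lo, hi = self.lesion_area_range
        if not 0 < lo <= hi:
            raise ValueError("bad lesion_area_range")
        if self.n_lesions * hi > 0.5 * self.image_size ** 2:
            raise ValueError("requested lesions would exceed half the frame")


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    return field_ / (np.abs(field_).max() + 1e-12)


def _blob_mask(rng: np.random.Generator, size: int,
               area: float) -> np.ndarray | None:
    """Rasterize one randomly oriented blobby ellipse of ~given area."""
    ratio = rng.uniform(0.6, 1.6)
    a = np.sqrt(area / np.pi * ratio)
    b = np.sqrt(area / np.pi / ratio)
    phi = rng.uniform(0.0, np.pi)
    k = rng.integers(3, 6)
    amp = rng.uniform(0.05, 0.15)
    phase = rng.uniform(0.0, 2 * np.pi)
    margin = max(a, b) * (1 + amp) + 1
    if 2 * margin >= size:
        return None
    cr = rng.uniform(margin, size - margin)
    cc = rng.uniform(margin, size - margin)
    rr, cc_grid = np.mgrid[0:size, 0:size]
    dr, dc = rr - cr, cc_grid - cc
    u = np.cos(phi) * dc + np.sin(phi) * dr
    v = -np.sin(phi) * dc + np.cos(phi) * dr
    theta = np.arctan2(v, u)
    wobble = 1.0 + amp * np.sin(k * theta + phase)
    return (u / a) ** 2 + (v / b) ** 2 <= wobble ** 2


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image, mask) pair; deterministic given the seed.

    Lesions whose placement keeps failing (overlap or out-of-range
    rasterized area) are skipped after bounded retries, so a scene may
    carry fewer lesions than requested (logged).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    img = np.empty((n, n, 3))
    tex = _smooth_noise(rng, n, n / 10)
    for ch, base in enumerate(_BACKGROUND_RGB):
        img[:, :, ch] = base + 0.05 * tex + 0.02 * _smooth_noise(rng, n, n / 16)
    # radial vignette, dark corners
    rr, cc = np.mgrid[0:n, 0:n]
    d2 = ((rr - (n - 1) / 2) ** 2 + (cc - (n - 1) / 2) ** 2) / (2 * ((n - 1) / 2) ** 2)
    img *= (1.0 - spec.vignette_strength * d2)[:, :, None]

    mask = np.full((n, n), NORMAL, dtype=np.int64)
    occupied = np.zeros((n, n), dtype=bool)
    placed = 0
    for _ in range(spec.n_lesions):
        ok = False
        for _retry in range(30):
            area = rng.uniform(*spec.lesion_area_range)
            blob = _blob_mask(rng, n, area)
            if blob is None:
                continue
            lo, hi = spec.lesion_area_range
            if not lo <= int(blob.sum()) <= hi:
                continue
            if (blob & occupied).any():
                continue
            cls = int(rng.choice(spec.class_pool))
            base = np.array(_LESION_COLOR[cls])
            speckle = _smooth_noise(rng, n, 1.5)
            alpha = 0.75
            for ch in range(3):
                channel = img[:, :, ch]
                channel[blob] = ((1 - alpha) * channel[blob]
                                 + alpha * (base[ch] + 0.06 * speckle[blob]))
            mask[blob] = cls
            occupied |= blob
            placed += 1
            ok = True
            break
        if not ok:
            log.warning("make_scene: lesion placement failed, scene %d keeps "
                        "%d lesions", spec.seed, placed)
    img += rng.normal(0.0, spec.base_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


VERSION_NAMES = ("original", "filtered", "sharpened", "enhanced")


def four_versions(img: np.ndarray,
                  params: EnhanceParams | None = None) -> dict[str, np.ndarray]:
    """The study's four pre-processing versions of one frame.

    ``original`` is the input; ``filtered`` applies only guided
    filtering (r = 5); ``sharpened`` applies only unsharp masking
    (λ = 5, with its fixed low-pass); ``enhanced`` applies both in
    order. One input therefore becomes four samples.
    """
    params = params or EnhanceParams()
    strong = EnhanceParams(r=5.0, lam=5.0, target_size=params.target_size,
                           eps=params.eps, usm_lowpass_r=params.usm_lowpass_r)
    filtered = guided_filter(img, strong)
    sharpened = unsharp_mask(img, usm_lowpass(img, strong), strong)
    enhanced = unsharp_mask(filtered, usm_lowpass(filtered, strong), strong)
    return {"original": np.asarray(img, dtype=np.float64).copy(),
            "filtered": filtered,
            "sharpened": sharpened,
            "enhanced": enhanced}


# -- on-the-fly augmentation ----------------------------------------------

@dataclass
class AugmentConfig:
    """Augmentation switches and ranges; a fresh draw on every call.

    Geometric transforms (flips, rotation) are applied identically to
    image and mask; intensity transforms and dropout touch the image
    only. Ranges are package defaults — the study lists the transform
    families but not their magnitudes.
    """

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    p_rotate: float = 0.5
    max_rotate_deg: float = 30.0
    p_intensity: float = 0.8
    hue_shift: float = 0.03
    sat_range: tuple[float, float] = (0.8, 1.2)
    value_range: tuple[float, float] = (0.85, 1.15)
    brightness_shift: float = 0.08
    contrast_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.25)
    p_noise: float = 0.5
    noise_sd_range: tuple[float, float] = (0.005, 0.02)
    p_blur: float = 0.3
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    p_sharpen: float = 0.3
    sharpen_lam_range: tuple[float, float] = (0.5, 2.0)
    p_dropout: float = 0.5
    dropout_squares: tuple[int, int] = (1, 5)
    dropout_size: int = 8
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    @classmethod
    def disabled(cls, seed: int = 0) -> "AugmentConfig":
        """All transforms off; augment() becomes the identity."""
        return cls(p_flip_h=0, p_flip_v=0, p_rotate=0, p_intensity=0,
                   p_noise=0, p_blur=0, p_sharpen=0, p_dropout=0, seed=seed)


def rotate_pair(img: np.ndarray, mask: np.ndarray,
                angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image (bilinear) and mask (nearest) congruently.

    Multiples of 90 degrees are exact index permutations.
    """
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        return np.rot90(img, k, axes=(0, 1)).copy(), np.rot90(mask, k).copy()
    img_r = sktransform.rotate(img, angle_deg, order=1, mode="edge")
    mask_r = sktransform.rotate(mask.astype(np.float64), angle_deg,
                                order=0, mode="edge").astype(mask.dtype)
    return img_r, mask_r


def augment(img: np.ndarray, mask: np.ndarray,
            cfg: AugmentConfig) -> tuple[np.ndarray, np.ndarray]:
    """Randomly perturb an (image, mask) pair.

    Each call draws fresh parameters from the config's generator, so a
    training loop never sees the exact same image twice.
    """
    rng = cfg._rng
    img = np.asarray(img, dtype=np.float64).copy()
    mask = np.asarray(mask).copy()

    if rng.random() < cfg.p_flip_h:
        img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
    if rng.random() < cfg.p_flip_v:
        img, mask = img[::-1].copy(), mask[::-1].copy()
    if rng.random() < cfg.p_rotate:
        angle = rng.uniform(-cfg.max_rotate_deg, cfg.max_rotate_deg)
        img, mask = rotate_pair(img, mask, angle)

    if rng.random() < cfg.p_intensity:
        hsv = skcolor.rgb2hsv(np.clip(img, 0, 1))
        hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-cfg.hue_shift, cfg.hue_shift)) % 1.0
        hsv[:, :, 1] = np.clip(hsv[:, :, 1] * rng.uniform(*cfg.sat_range), 0, 1)
        hsv[:, :, 2] = np.clip(hsv[:, :, 2] * rng.uniform(*cfg.value_range), 0, 1)
        img = skcolor.hsv2rgb(hsv)
        img = img + rng.uniform(-cfg.brightness_shift, cfg.brightness_shift)
        m = img.mean()
        img = m + rng.uniform(*cfg.contrast_range) * (img - m)
        img = np.clip(img, 0, 1) ** rng.uniform(*cfg.gamma_range)
    if rng.random() < cfg.p_blur:
        sigma = rng.uniform(*cfg.blur_sigma_range)
        img = ndimage.gaussian_filter(img, (sigma, sigma, 0))
    if rng.random() < cfg.p_sharpen:
        lam = rng.uniform(*cfg.sharpen_lam_range)
        p = EnhanceParams(r=0.0, lam=lam)
        img = unsharp_mask(np.clip(img, 0, 1), usm_lowpass(np.clip(img, 0, 1), p), p)
    if rng.random() < cfg.p_noise:
        img = img + rng.normal(0, rng.uniform(*cfg.noise_sd_range), img.shape)
    if rng.random() < cfg.p_dropout:
        n_sq = rng.integers(cfg.dropout_squares[0], cfg.dropout_squares[1] + 1)
        s = cfg.dropout_size
        h, w = img.shape[:2]
        for _ in range(n_sq):
            r0 = rng.integers(0, max(h - s, 1))
            c0 = rng.integers(0, max(w - s, 1))
            img[r0:r0 + s, c0:c0 + s] = 0.0
    return np.clip(img, 0.0, 1.0), mask


# -- dataset plumbing ------------------------------------------------------

def split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_val = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for nonempty splits {fractions}")
    return n_train, n_val, n_test


def make_dataset(n: int, out_dir: str | Path,
                 split: tuple[float, float, float] = (0.9, 0.05, 0.05),
                 seed: int = 0, image_size: int = 160,
                 **scene_kwargs) -> dict:
    """Generate n scenes, save all four versions + masks, split by scene.

    All four pre-processed versions of a scene travel together into one
    split, so no near-duplicate leaks across the train/val/test
    boundary. Returns (and writes) a manifest listing every image with
    its scene id, version, split and file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_train, n_val, n_test = split_counts(n, split)
    if "lesion_area_range" not in scene_kwargs:
        # keep lesions at ~0.8-4.7 % of the frame at any size
        scene_kwargs["lesion_area_range"] = (
            max(8, round(0.008 * image_size ** 2)),
            max(16, round(0.047 * image_size ** 2)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split_of = {}
    for i, scene_id in enumerate(order):
        split_of[int(scene_id)] = ("train" if i < n_train
                                   else "val" if i < n_train + n_val
                                   else "test")
    records = []
    for scene_id in range(n):
        spec = SceneSpec(image_size=image_size,
                         seed=int(rng.integers(0, 2**31)), **scene_kwargs)
        img, mask = make_scene(spec)
        mask_path = out / f"scene_{scene_id:04d}_mask.png"
        imgio.save_mask(mask_path, mask)
        for version, vimg in four_versions(img).items():
            img_path = out / f"scene_{scene_id:04d}_{version}.png"
            imgio.save_image(img_path, vimg)
            records.append({"scene_id": scene_id, "version": version,
                            "split": split_of[scene_id],
                            "image": str(img_path), "mask": str(mask_path)})
    manifest = {"n_scenes": n, "split_fractions": list(split),
                "seed": seed, "records": records}
    imgio.save_json(out / "manifest.json", manifest)
    return manifest
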