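"""Procedural low-altitude farmland scenes with ground-truth masks.

A scene is a textured green crop canopy inside a darker background border,
with two families of bare-soil vacancies cut into the canopy: long narrow
strips (aspect ratio >= 4, the shapes strip pooling is designed to catch)
and compact elliptical blobs.  The generator iterates shape sizes until the
realized vacancy ratio V/(C+V) lands within a relative tolerance of the
requested target, so evaluation metrics have a known ground truth.

Also implements the training-time augmentation operators: salt-and-pepper
noise, Gaussian noise, histogram equalization, sharpening, Gaussian blur,
random rotation, and horizontal/vertical flips.  Photometric operators leave
the mask untouched; geometric operators transform image and mask identically
with nearest-neighbor mask resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

BACKGROUND, CROP, VACANCY = 0, 1, 2

#: mean RGB of the background border fill, also used when rotation exposes corners
_BG_TONE = (52, 50, 46)


class SceneGenerationError(RuntimeError):
    """The target vacancy fraction is unreachable under the shape ranges."""


@dataclass
class SceneParams:
    """Full parameterization (seed included) of one synthetic farmland scene.

    Pixel ranges are (min, max) inclusive and scale with the default 256x256
    canvas; use :meth:`for_size` to rescale them for other canvases.
    """

    seed: int = 0
    height: int = 256
    width: int = 256
    target_vacancy_fraction: float = 0.10
    n_strip_vacancies: int = 3
    n_blob_vacancies: int = 4
    strip_length_range: tuple[float, float] = (40.0, 110.0)
    strip_width_range: tuple[float, float] = (3.0, 10.0)
    blob_radius_range: tuple[float, float] = (5.0, 14.0)
    border_fraction: float = 0.06
    crop_texture_scale: float = 16.0
    noise_sd: float = 6.0
    vacancy_rel_tol: float = 0.25
    max_retries: int = 20

    def __post_init__(self):
        if not (0.0 <= self.target_vacancy_fraction < 1.0):
            raise ValueError("target_vacancy_fraction must be in [0, 1)")
        if not (0.0 <= self.border_fraction < 0.4):
            raise ValueError("border_fraction must be in [0, 0.4)")
        for name in ("strip_length_range", "strip_width_range", "blob_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")

    @classmethod
    def for_size(cls, height: int, width: int, seed: int = 0, **overrides) -> "SceneParams":
        """Scale the default shape ranges for a non-default canvas size."""
        s = min(height, width) / 256.0
        p = cls(seed=seed, height=height, width=width,
                strip_length_range=(max(4.0, 40 * s), max(8.0, 110 * s)),
                strip_width_range=(max(1.5, 3 * s), max(2.5, 10 * s)),
                blob_radius_range=(max(2.0, 5 * s), max(3.5, 14 * s)),
                crop_texture_scale=max(4.0, 16 * s))
        return replace(p, **overrides) if overrides else p


def _value_noise(rng: np.random.Generator, h: int, w: int, scale: float) -> np.ndarray:
    """Multi-octave smoothed noise in [0, 1]."""
    acc = np.zeros((h, w))
    amp_total = 0.0
    for octave, amp in enumerate((1.0, 0.5, 0.25)):
        sigma = max(scale / (2 ** octave), 0.75)
        acc += amp * ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        amp_total += amp
    acc /= amp_total
    lo, hi = acc.min(), acc.max()
    return (acc - lo) / (hi - lo) if hi > lo else np.full((h, w), 0.5)


def _paint_strip(canvas: np.ndarray, rng: np.random.Generator,
                 interior: tuple[int, int, int, int], length: float, width: float) -> None:
    """Rasterize a rotated rectangle of the given length/width into `canvas`."""
    r0, r1, c0, c1 = interior
    width = min(width, length / 4.0)             # enforce strip aspect ratio >= 4
    cy = rng.uniform(r0, r1)
    cx = rng.uniform(c0, c1)
    theta = rng.uniform(0.0, np.pi)
    half = length / 2.0 + width
    ylo, yhi = int(max(r0, cy - half)), int(min(r1, cy + half + 1))
    xlo, xhi = int(max(c0, cx - half)), int(min(c1, cx + half + 1))
    if ylo >= yhi or xlo >= xhi:
        return
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    canvas[ylo:yhi, xlo:xhi] |= (np.abs(u) <= length / 2.0) & (np.abs(v) <= width / 2.0)


def _paint_blob(canvas: np.ndarray, rng: np.random.Generator,
                interior: tuple[int, int, int, int], radius: float) -> None:
    """Rasterize a rotated ellipse of mean radius `radius` into `canvas`."""
    r0, r1, c0, c1 = interior
    cy = rng.uniform(r0, r1)
    cx = rng.uniform(c0, c1)
    ecc = rng.uniform(0.7, 1.3)
    ra, rb = radius * ecc, radius / ecc
    theta = rng.uniform(0.0, np.pi)
    half = max(ra, rb) + 1
    ylo, yhi = int(max(r0, cy - half)), int(min(r1, cy + half + 1))
    xlo, xhi = int(max(c0, cx - half)), int(min(c1, cx + half + 1))
    if ylo >= yhi or xlo >= xhi:
        return
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    canvas[ylo:yhi, xlo:xhi] |= (u / ra) ** 2 + (v / rb) ** 2 <= 1.0


def _place_vacancies(params: SceneParams, rng: np.random.Generator,
                     interior: tuple[int, int, int, int], interior_area: int) -> np.ndarray:
    """Place strip and blob vacancies, rescaling shape sizes until the realized
    vacancy fraction is within tolerance of the target."""
    h, w = params.height, params.width
    n_shapes = params.n_strip_vacancies + params.n_blob_vacancies
    target = params.target_vacancy_fraction
    if n_shapes == 0 or target == 0.0:
        if target > 0.0 and n_shapes == 0:
            raise SceneGenerationError(
                "target_vacancy_fraction > 0 but no vacancy shapes requested")
        return np.zeros((h, w), dtype=bool)

    scale = 1.0
    last = 0.0
    for _ in range(params.max_retries):
        canvas = np.zeros((h, w), dtype=bool)
        for _ in range(params.n_strip_vacancies):
            length = rng.uniform(*params.strip_length_range) * scale
            width = rng.uniform(*params.strip_width_range) * scale
            _paint_strip(canvas, rng, interior, length, width)
        for _ in range(params.n_blob_vacancies):
            radius = rng.uniform(*params.blob_radius_range) * scale
            _paint_blob(canvas, rng, interior, radius)
        realized = canvas.sum() / interior_area
        last = realized
        if realized > 0 and abs(realized - target) / target <= params.vacancy_rel_tol:
            return canvas
        # linear dimensions scale with the square root of the area deficit
        adj = np.sqrt(target / realized) if realized > 0 else 1.5
        scale *= float(np.clip(adj, 0.5, 2.0))
    raise SceneGenerationError(
        f"could not reach vacancy fraction {target:.3f} (last realized {last:.3f}) "
        f"within {params.max_retries} retries; adjust shape counts or ranges")


def generate_scene(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (RGB image, label mask) pair.  Deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    border = int(round(params.border_fraction * min(h, w)))
    r0, r1 = border, h - border
    c0, c1 = border, w - border
    if r1 <= r0 or c1 <= c0:
        raise SceneGenerationError("border_fraction leaves no crop interior")
    interior_area = (r1 - r0) * (c1 - c0)

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[r0:r1, c0:c1] = CROP
    vac = _place_vacancies(params, rng, (r0, r1, c0, c1), interior_area)
    mask[vac] = VACANCY

    # color the three classes with distinct, textured tones
    t_crop = _value_noise(rng, h, w, params.crop_texture_scale)
    t_soil = _value_noise(rng, h, w, params.crop_texture_scale / 2)
    t_bg = _value_noise(rng, h, w, params.crop_texture_scale)
    img = np.zeros((h, w, 3))
    crop_px = mask == CROP
    vac_px = mask == VACANCY
    bg_px = mask == BACKGROUND
    for ch, (base, span) in enumerate(((58, 44), (108, 72), (38, 30))):   # green canopy
        img[..., ch][crop_px] = (base + span * t_crop)[crop_px]
    for ch, (base, span) in enumerate(((122, 42), (94, 32), (66, 22))):   # bare soil
        img[..., ch][vac_px] = (base + span * t_soil)[vac_px]
    # darker soil at vacancy rims, as shadows would render them
    rim = vac_px & ~ndimage.binary_erosion(vac_px, iterations=1)
    img[rim] *= 0.8
    for ch, base in enumerate(_BG_TONE):                                  # border track
        img[..., ch][bg_px] = (base + 18 * t_bg)[bg_px]

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def vacancy_fraction(mask: np.ndarray) -> float:
    """Realized V/(C+V) of a label mask (background excluded)."""
    v = int((mask == VACANCY).sum())
    c = int((mask == CROP).sum())
    if c + v == 0:
        raise ValueError("mask has no crop or vacancy pixels")
    return v / (c + v)


# -- augmentation ----------------------------------------------------------

AUGMENT_OPS = ("salt_pepper", "gaussian_noise", "hist_equalize", "sharpen",
               "gaussian_blur", "rotate", "hflip", "vflip")


@dataclass(frozen=True)
class AugmentSpec:
    """One augmentation operator with its parameters and application probability."""

    op: str
    prob: float = 1.0
    amount: float = 0.02        # salt_pepper: fraction of pixels replaced
    sigma: float = 5.0          # gaussian_noise: intensity sd; gaussian_blur/sharpen: kernel sd
    strength: float = 1.0       # sharpen: unsharp-mask gain
    max_angle: float = 18.0     # rotate: degrees, drawn uniformly from +/- max_angle

    def __post_init__(self):
        if self.op not in AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {self.op!r}; choose from {AUGMENT_OPS}")
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError("prob must be in [0, 1]")
        if not (0.0 <= self.amount <= 1.0):
            raise ValueError("salt_pepper amount must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def default_augmentations() -> list[AugmentSpec]:
    """The train-time pipeline: random rotation (±18°, p=0.5), random
    horizontal and vertical flips, and Gaussian noise."""
    return [AugmentSpec("rotate", prob=0.5, max_angle=18.0),
            AugmentSpec("hflip", prob=0.5),
            AugmentSpec("vflip", prob=0.5),
            AugmentSpec("gaussian_noise", prob=0.5, sigma=5.0)]


def apply_augmentation(img: np.ndarray, mask: np.ndarray, spec: AugmentSpec,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply one augmentation operator.  Deterministic given `seed`."""
    rng = np.random.default_rng(seed)
    img = np.asarray(img)
    mask = np.asarray(mask)
    if rng.random() > spec.prob:
        return img.copy(), mask.copy()
    op = spec.op
    if op == "salt_pepper":
        out = img.copy()
        flip = rng.random(img.shape[:2]) < spec.amount
        salt = rng.random(img.shape[:2]) < 0.5
        out[flip & salt] = 255
        out[flip & ~salt] = 0
        return out, mask.copy()
    if op == "gaussian_noise":
        noisy = img.astype(np.float64) + rng.normal(0.0, spec.sigma, size=img.shape)
        return np.clip(noisy, 0, 255).astype(np.uint8), mask.copy()
    if op == "hist_equalize":
        from skimage import exposure
        out = np.stack([exposure.equalize_hist(img[..., c]) for c in range(3)], axis=-1)
        return np.clip(out * 255, 0, 255).astype(np.uint8), mask.copy()
    if op == "sharpen":
        f = img.astype(np.float64)
        blur = np.stack([ndimage.gaussian_filter(f[..., c], spec.sigma) for c in range(3)], -1)
        return np.clip(f + spec.strength * (f - blur), 0, 255).astype(np.uint8), mask.copy()
    if op == "gaussian_blur":
        f = img.astype(np.float64)
        out = np.stack([ndimage.gaussian_filter(f[..., c], spec.sigma) for c in range(3)], -1)
        return np.clip(out, 0, 255).astype(np.uint8), mask.copy()
    if op == "rotate":
        angle = rng.uniform(-spec.max_angle, spec.max_angle)
        out = np.stack([ndimage.rotate(img[..., c].astype(np.float64), angle,
                                       reshape=False, order=1, cval=_BG_TONE[c])
                        for c in range(3)], axis=-1)
        new_mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                                  cval=BACKGROUND, prefilter=False)
        return np.clip(out, 0, 255).astype(np.uint8), new_mask.astype(mask.dtype)
    if op == "hflip":
        return img[:, ::-1].copy(), mask[:, ::-1].copy()
    if op == "vflip":
        return img[::-1].copy(), mask[::-1].copy()
    raise AssertionError(op)


def apply_pipeline(img: np.ndarray, mask: np.ndarray, specs, seed: int):
    """Apply a sequence of augmentations with independent per-op random draws."""
    ss = np.random.SeedSequence(seed).spawn(len(list(specs)))
    for spec, child in zip(specs, ss):
        img, mask = apply_augmentation(img, mask, spec, int(child.generate_state(1)[0] % (2**31)))
    return img, mask
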