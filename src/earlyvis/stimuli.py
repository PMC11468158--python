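"""Synthetic stimulus generation: foregrounds, backgrounds, and composition.

The generator emulates the statistical structure of a face/non-face
psychophysics stimulus set without any photographic material:

* the *face* class is a shape-coherent family — an upright oval (superellipse)
  silhouette with a fixed internal feature layout (two dark eye blobs, a nose
  ridge, a horizontal mouth bar) plus per-seed texture and illumination;
* the *non-face* class is deliberately heterogeneous — compact blobs,
  elongated bars, and ring/oval confounders — so its shape statistics
  (notably elongation) are far more dispersed than the face class's.

Foregrounds live on a 256x256 canvas with a transparency mask and their
opaque bounding box has its longest side equal to 246 px. Composed stimuli
are 340x340 grayscale images: the foreground is randomly scaled, rotated and
jittered, then alpha-composited over one of eight background kinds.

Class-conditional calibration targets (means over many seeds): fraction of
canvas filled ~0.56 for faces vs ~0.4 for non-faces; bounding-box elongation
~1.66 (narrow) for faces vs ~2.5 (broad) for non-faces; opaque-pixel mean
luminance ~103 for faces and ~103/1.15 for non-faces before the +15%
luminance-matching step; opaque-pixel RMS contrast ~41.5 after matching.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .rng import substream

FG_SIZE = 256
CANVAS_SIZE = 340
FG_MAX_SIDE = 246
JITTER_MAX = 42

__all__ = [
    "AlphaImage",
    "GrayImage",
    "BackgroundKind",
    "TransformSpec",
    "TransformDraw",
    "ScenePool",
    "gen_foreground",
    "gen_scene",
    "degrade_scene",
    "gen_background",
    "transform_and_compose",
    "shape_stats",
    "match_luminance",
    "rms_contrast",
    "save_png",
    "load_foreground_png",
    "load_gray_png",
    "write_fixture_set",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AlphaImage:
    """256x256 grayscale foreground with a transparency mask.

    ``pixels`` holds real-valued luminance in [0, 255]; ``alpha`` holds
    opacity in [0, 1] (0 = fully transparent). A valid foreground has at
    least one opaque pixel and an opaque bounding box no larger than 246 px
    on its longest side.
    """

    pixels: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.pixels.shape != (FG_SIZE, FG_SIZE) or self.alpha.shape != (FG_SIZE, FG_SIZE):
            raise ValueError(f"foreground must be {FG_SIZE}x{FG_SIZE}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("luminance outside [0, 255]")

    @property
    def mask(self) -> np.ndarray:
        return self.alpha >= 0.5

    def opaque_values(self) -> np.ndarray:
        return self.pixels[self.mask]


@dataclass
class GrayImage:
    """340x340 real-valued grayscale stimulus, luminance in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (CANVAS_SIZE, CANVAS_SIZE):
            raise ValueError(f"stimulus must be {CANVAS_SIZE}x{CANVAS_SIZE}")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 255 + 1e-9:
            raise ValueError("luminance outside [0, 255]")


class BackgroundKind(enum.Enum):
    MID_GRAY = "mid_gray"
    MATCHED_GRAY = "matched_gray"
    PINK_NOISE = "pink_noise"
    WHITE_BLOCK_NOISE = "white_block_noise"
    BINARY_BLOCK_NOISE = "binary_block_noise"
    SAMPLED_BLOCK_NOISE = "sampled_block_noise"
    SCENE = "scene"
    BLURRED_SCENE = "blurred_scene"


@dataclass(frozen=True)
class TransformSpec:
    """Nuisance-transform ranges for one stimulus presentation.

    scale is drawn uniformly in [scale_min, 1] (isotropic; 1 = full size),
    rotation uniformly in [-rot_max, +rot_max] degrees (positive =
    clockwise), and the two jitter components are independent uniform
    integers in [-jitter_max, +jitter_max] px.
    """

    scale_min: float = 1.0
    rot_max: float = 0.0
    jitter_max: int = JITTER_MAX

    def __post_init__(self) -> None:
        if not (0.0 < self.scale_min <= 1.0):
            raise ValueError("scale_min must be in (0, 1]")
        if not (0.0 <= self.rot_max <= 180.0):
            raise ValueError("rot_max must be in [0, 180]")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")

    def draw(self, rng: np.random.Generator) -> "TransformDraw":
        scale = float(rng.uniform(self.scale_min, 1.0)) if self.scale_min < 1.0 else 1.0
        rot = float(rng.uniform(-self.rot_max, self.rot_max)) if self.rot_max > 0 else 0.0
        if self.jitter_max > 0:
            jx, jy = (int(v) for v in rng.integers(-self.jitter_max, self.jitter_max + 1, size=2))
        else:
            jx = jy = 0
        return TransformDraw(scale=scale, rotation=rot, jitter=(jx, jy))


@dataclass(frozen=True)
class TransformDraw:
    """The transform actually applied to one presentation."""

    scale: float
    rotation: float
    jitter: tuple[int, int]


# ---------------------------------------------------------------------------
# foreground synthesis


def _superellipse_mask(h: float, w: float, exponent: float) -> np.ndarray:
    """Boolean mask of a superellipse with bounding box h x w, centered."""
    yy, xx = np.mgrid[0:FG_SIZE, 0:FG_SIZE].astype(np.float64)
    cy = cx = (FG_SIZE - 1) / 2.0
    a, b = h / 2.0, w / 2.0
    return (np.abs((yy - cy) / a) ** exponent + np.abs((xx - cx) / b) ** exponent) <= 1.0


def _smooth_noise(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Zero-mean, unit-RMS low-pass Gaussian texture."""
    n = ndimage.gaussian_filter(rng.standard_normal((FG_SIZE, FG_SIZE)), sigma, mode="reflect")
    n -= n.mean()
    s = n.std()
    return n / s if s > 0 else n


def _set_mean_rms(pixels: np.ndarray, mask: np.ndarray, mean: float, rms: float,
                  n_iter: int = 3) -> np.ndarray:
    """Affinely rescale the masked pixels toward a target mean and RMS contrast.

    Clipping to [0, 255] perturbs the moments, so the affine map is iterated
    a few times; residual error after three passes is well under one gray
    level for the textures used here.
    """
    out = pixels.copy()
    for _ in range(n_iter):
        v = out[mask]
        m, s = v.mean(), v.std()
        if s < 1e-9:
            out[mask] = mean
            break
        out[mask] = np.clip((v - m) * (rms / s) + mean, 0.0, 255.0)
    return out


def _snap_longest_side(mask: np.ndarray) -> np.ndarray:
    """Rescale a mask so its opaque bounding box's longest side is FG_MAX_SIDE."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    h = rows[-1] - rows[0] + 1
    w = cols[-1] - cols[0] + 1
    longest = max(h, w)
    if longest == FG_MAX_SIDE:
        return mask
    zoom = FG_MAX_SIDE / longest
    z = ndimage.zoom(mask.astype(np.float64), zoom, order=1, grid_mode=False) >= 0.5
    out = np.zeros((FG_SIZE, FG_SIZE), dtype=bool)
    zr = np.flatnonzero(z.any(axis=1))
    zc = np.flatnonzero(z.any(axis=0))
    zh, zw = zr[-1] - zr[0] + 1, zc[-1] - zc[0] + 1
    r0 = (FG_SIZE - zh) // 2
    c0 = (FG_SIZE - zw) // 2
    out[r0:r0 + zh, c0:c0 + zw] = z[zr[0]:zr[-1] + 1, zc[0]:zc[-1] + 1]
    return out


def _face_mask(rng: np.random.Generator) -> tuple[np.ndarray, float]:
    elong = float(np.clip(rng.normal(1.66, 0.12), 1.35, 2.0))
    exponent = float(rng.uniform(5.0, 9.0))
    h = float(FG_MAX_SIDE)
    w = h / elong
    return _superellipse_mask(h, w, exponent), w


def _paint_face(rng: np.random.Generator, mask: np.ndarray, face_w: float) -> np.ndarray:
    """Fixed internal layout: two eye blobs, a nose ridge, a mouth bar."""
    yy, xx = np.mgrid[0:FG_SIZE, 0:FG_SIZE].astype(np.float64)
    cy = cx = (FG_SIZE - 1) / 2.0
    h = float(FG_MAX_SIDE)

    # base skin: gentle illumination gradient plus smooth texture
    gdir = rng.uniform(0, 2 * np.pi)
    grad = ((yy - cy) * np.sin(gdir) + (xx - cx) * np.cos(gdir)) / h
    img = 128.0 + rng.uniform(15, 35) * grad + 12.0 * _smooth_noise(rng, rng.uniform(6, 12))

    def blob(y0, x0, ry, rx, depth):
        return depth * np.exp(-(((yy - y0) / ry) ** 2 + ((xx - x0) / rx) ** 2))

    eye_dy = -0.18 * h + rng.normal(0, 3)
    eye_dx = 0.22 * face_w + rng.normal(0, 2)
    eye_r = 0.055 * h * rng.uniform(0.85, 1.15)
    depth = rng.uniform(60, 95)
    img -= blob(cy + eye_dy, cx - eye_dx, eye_r, eye_r * 1.4, depth)
    img -= blob(cy + eye_dy, cx + eye_dx, eye_r, eye_r * 1.4, depth)
    # nose: bright vertical ridge below eye line
    img += blob(cy + 0.05 * h, cx + rng.normal(0, 1.5), 0.16 * h, 0.035 * face_w,
                rng.uniform(20, 40))
    # mouth: dark horizontal bar
    img -= blob(cy + 0.27 * h + rng.normal(0, 3), cx, 0.035 * h, 0.18 * face_w,
                rng.uniform(40, 70))
    # slightly darker rim near the silhouette boundary
    dist = ndimage.distance_transform_edt(mask)
    img -= 20.0 * np.exp(-dist / (0.04 * h))
    return img


def _paint_generic(rng: np.random.Generator, mask: np.ndarray) -> np.ndarray:
    """Texture for non-face silhouettes: gradient + smooth noise, sometimes stripes."""
    yy, xx = np.mgrid[0:FG_SIZE, 0:FG_SIZE].astype(np.float64)
    cy = cx = (FG_SIZE - 1) / 2.0
    gdir = rng.uniform(0, 2 * np.pi)
    grad = ((yy - cy) * np.sin(gdir) + (xx - cx) * np.cos(gdir)) / FG_MAX_SIDE
    img = 128.0 + rng.uniform(10, 50) * grad
    img += rng.uniform(10, 30) * _smooth_noise(rng, rng.uniform(3, 10))
    if rng.random() < 0.35:  # occasional periodic texture
        wl = rng.uniform(20, 70)
        ph = rng.uniform(0, 2 * np.pi)
        sdir = rng.uniform(0, np.pi)
        img += rng.uniform(10, 30) * np.sin(
            2 * np.pi * ((yy * np.sin(sdir) + xx * np.cos(sdir)) / wl) + ph)
    return img


def _nonface_mask(rng: np.random.Generator) -> np.ndarray:
    kind = rng.choice(["blob", "bar", "ring"], p=[0.35, 0.47, 0.18])
    if kind == "blob":
        elong = rng.uniform(1.0, 1.6)
        exponent = rng.uniform(2.0, 4.0)
        mask = _superellipse_mask(FG_MAX_SIDE, FG_MAX_SIDE / elong, exponent)
    elif kind == "bar":
        elong = rng.uniform(2.6, 5.0)
        exponent = rng.uniform(2.0, 6.0)
        h, w = float(FG_MAX_SIDE), FG_MAX_SIDE / elong
        if rng.random() < 0.5:
            h, w = w, h
        mask = _superellipse_mask(h, w, exponent)
    else:  # ring
        elong = rng.uniform(1.0, 1.4)
        outer = _superellipse_mask(FG_MAX_SIDE, FG_MAX_SIDE / elong, 2.0)
        f = rng.uniform(0.45, 0.7)
        inner = _superellipse_mask(FG_MAX_SIDE * f, FG_MAX_SIDE / elong * f, 2.0)
        mask = outer & ~inner
    return mask


def gen_foreground(class_label: str, seed: int, params: dict | None = None) -> AlphaImage:
    """Generate one synthetic foreground of the requested class.

    Deterministic per ``(class_label, seed, params)``. ``params`` may override
    the opaque-pixel luminance calibration: ``mean_luminance``,
    ``mean_luminance_sd``, ``rms_contrast``, ``rms_contrast_sd``.
    """
    params = dict(params or {})
    if class_label == "face":
        lum_target = params.get("mean_luminance", 103.0)
    elif class_label == "nonface":
        # generated darker; the +15% luminance-matching step restores parity
        lum_target = params.get("mean_luminance", 103.0 / 1.15)
    else:
        raise ValueError(f"unknown class label: {class_label!r}")
    lum_sd = params.get("mean_luminance_sd", 6.0)
    rms_target = params.get("rms_contrast", 41.5 if class_label == "face" else 41.5 / 1.15)
    rms_sd = params.get("rms_contrast_sd", 4.0)

    rng = substream(seed, "foreground", class_label)
    if class_label == "face":
        mask, face_w = _face_mask(rng)
        mask = _snap_longest_side(mask)
        img = _paint_face(rng, mask, face_w)
    else:
        mask = _snap_longest_side(_nonface_mask(rng))
        img = _paint_generic(rng, mask)

    mean = float(np.clip(rng.normal(lum_target, lum_sd), 30, 225))
    rms = float(np.clip(rng.normal(rms_target, rms_sd), 10, 60))
    img = _set_mean_rms(np.clip(img, 0, 255), mask, mean, rms)
    pixels = np.where(mask, img, 0.0)
    return AlphaImage(pixels=pixels, alpha=mask.astype(np.float64))


# ---------------------------------------------------------------------------
# scenes and backgrounds


def _pink_field(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random-phase field with 1/f amplitude spectrum, zero mean, unit RMS."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    amp[f > 0] = 1.0 / f[f > 0]
    spec = amp * np.exp(2j * np.pi * rng.random(f.shape))
    field = np.fft.irfft2(spec, s=(size, size))
    field -= field.mean()
    return field / field.std()


def gen_scene(seed: int) -> GrayImage:
    """Procedural high-contrast scene: horizon gradient, 1/f texture,
    rectilinear edges; stretched to the full 0-255 range."""
    rng = substream(seed, "scene")
    size = CANVAS_SIZE
    yy = np.mgrid[0:size, 0:size][0].astype(np.float64)

    horizon = rng.uniform(0.35, 0.65) * size
    sky = 1.0 / (1.0 + np.exp((yy - horizon) / rng.uniform(4, 15)))
    img = 60.0 + 120.0 * sky  # bright sky over darker ground
    img += 45.0 * _pink_field(rng, size)

    # rectilinear structures (buildings / windows / fences)
    n_rect = rng.integers(5, 13)
    for _ in range(n_rect):
        h = int(rng.integers(15, 160))
        w = int(rng.integers(10, 120))
        r0 = int(rng.integers(0, size - h))
        c0 = int(rng.integers(0, size - w))
        level = rng.uniform(-90, 90)
        blend = rng.uniform(0.5, 1.0)
        img[r0:r0 + h, c0:c0 + w] = (1 - blend) * img[r0:r0 + h, c0:c0 + w] + blend * (128 + level)

    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) * 255.0
    return GrayImage(pixels=img)


def degrade_scene(scene: GrayImage) -> GrayImage:
    """Halve contrast about the mean, then blur with a sigma=3 px Gaussian."""
    m = scene.pixels.mean()
    out = m + 0.5 * (scene.pixels - m)
    out = ndimage.gaussian_filter(out, sigma=3.0, mode="reflect")
    return GrayImage(pixels=np.clip(out, 0, 255))


class ScenePool:
    """Lazily generated, cached pool of procedural scenes.

    Indexing is deterministic given the pool seed, so a pool is a
    reproducible stand-in for a directory of scene photographs.
    """

    def __init__(self, seed: int, n_scenes: int = 100):
        if n_scenes < 1:
            raise ValueError("n_scenes must be >= 1")
        self.seed = seed
        self.n_scenes = n_scenes
        self._cache: dict[tuple[int, bool], GrayImage] = {}

    def get(self, index: int, blurred: bool = False) -> GrayImage:
        index = int(index) % self.n_scenes
        key = (index, blurred)
        if key not in self._cache:
            if blurred:
                self._cache[key] = degrade_scene(self.get(index, blurred=False))
            else:
                self._cache[key] = gen_scene(self.seed * 100_003 + index)
        return self._cache[key]

    def sample(self, rng: np.random.Generator, blurred: bool = False) -> GrayImage:
        return self.get(int(rng.integers(self.n_scenes)), blurred=blurred)


PINK_NOISE_RMS = 41.5  # matches the stimulus sets' average RMS contrast


def gen_background(kind: BackgroundKind, fg: AlphaImage | None = None,
                   seed: int = 0, scene_pool: ScenePool | None = None) -> GrayImage:
    """Generate one 340x340 background of the requested kind.

    ``fg`` is required for MATCHED_GRAY and SAMPLED_BLOCK_NOISE (their
    luminance statistics are tied to the current foreground); ``scene_pool``
    is required for SCENE and BLURRED_SCENE.
    """
    size = CANVAS_SIZE
    rng = substream(seed, "background", kind.value)
    if kind is BackgroundKind.MID_GRAY:
        return GrayImage(pixels=np.full((size, size), 128.0))
    if kind is BackgroundKind.MATCHED_GRAY:
        if fg is None:
            raise ValueError("MATCHED_GRAY requires the foreground")
        return GrayImage(pixels=np.full((size, size), float(fg.opaque_values().mean())))
    if kind is BackgroundKind.PINK_NOISE:
        field = _pink_field(rng, size)
        img = np.clip(128.0 + PINK_NOISE_RMS * field, 0, 255)
        # one correction pass: clipping slightly deflates the RMS
        s = img.std()
        if s > 1e-9:
            img = np.clip((img - img.mean()) * (PINK_NOISE_RMS / s) + 128.0, 0, 255)
        return GrayImage(pixels=img)
    nb = size // 4  # 4x4 px blocks
    if kind is BackgroundKind.WHITE_BLOCK_NOISE:
        blocks = rng.integers(0, 256, size=(nb, nb)).astype(np.float64)
    elif kind is BackgroundKind.BINARY_BLOCK_NOISE:
        blocks = rng.integers(0, 2, size=(nb, nb)).astype(np.float64) * 255.0
    elif kind is BackgroundKind.SAMPLED_BLOCK_NOISE:
        if fg is None:
            raise ValueError("SAMPLED_BLOCK_NOISE requires the foreground")
        vals = fg.opaque_values()
        blocks = rng.choice(vals, size=(nb, nb), replace=True)
    elif kind in (BackgroundKind.SCENE, BackgroundKind.BLURRED_SCENE):
        if scene_pool is None:
            raise ValueError(f"{kind.name} requires a scene pool")
        return scene_pool.sample(rng, blurred=kind is BackgroundKind.BLURRED_SCENE)
    else:  # pragma: no cover
        raise ValueError(f"unknown background kind: {kind}")
    return GrayImage(pixels=np.repeat(np.repeat(blocks, 4, axis=0), 4, axis=1))


# ---------------------------------------------------------------------------
# composition


def _warp_foreground(fg: AlphaImage, draw: TransformDraw) -> tuple[np.ndarray, np.ndarray]:
    """Warp luminance and alpha into the 340x340 canvas frame.

    Forward map: p_out = R(theta) * s * (p_in - c_in) + c_out + jitter, with
    rotation about the foreground center and positive angles clockwise.
    Bilinear interpolation for both planes; alpha re-thresholded by the
    caller at 0.5.
    """
    th = np.deg2rad(draw.rotation)
    c, s = np.cos(th), np.sin(th)
    # inverse map for ndimage (output -> input), in (row, col) coordinates
    inv = np.array([[c, -s], [s, c]]) / draw.scale
    c_in = np.array([(FG_SIZE - 1) / 2.0] * 2)
    jy, jx = draw.jitter[1], draw.jitter[0]
    c_out = np.array([(CANVAS_SIZE - 1) / 2.0 + jy, (CANVAS_SIZE - 1) / 2.0 + jx])
    offset = c_in - inv @ c_out
    lum = ndimage.affine_transform(fg.pixels, inv, offset=offset,
                                   output_shape=(CANVAS_SIZE, CANVAS_SIZE),
                                   order=1, mode="constant", cval=0.0)
    alpha = ndimage.affine_transform(fg.alpha, inv, offset=offset,
                                     output_shape=(CANVAS_SIZE, CANVAS_SIZE),
                                     order=1, mode="constant", cval=0.0)
    return lum, alpha


def _clip_jitter(fg: AlphaImage, scale: float, rotation: float,
                 jitter: tuple[int, int]) -> tuple[int, int]:
    """Clamp jitter so the transformed opaque bounding box stays on canvas.

    Uses the transformed corners of the source bounding box, a conservative
    over-bound of the true opaque support.
    """
    mask = fg.mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cy = cx = (FG_SIZE - 1) / 2.0
    corners = np.array([[rows[0], cols[0]], [rows[0], cols[-1]],
                        [rows[-1], cols[0]], [rows[-1], cols[-1]]], dtype=np.float64)
    th = np.deg2rad(rotation)
    c, s = np.cos(th), np.sin(th)
    fwd = scale * np.array([[c, s], [-s, c]])  # inverse of the map in _warp_foreground
    warped = (corners - [cy, cx]) @ fwd.T + (CANVAS_SIZE - 1) / 2.0
    lo = warped.min(axis=0)  # (row, col) without jitter
    hi = warped.max(axis=0)
    pad = 1.0  # bilinear support
    jx, jy = jitter
    jy = int(np.clip(jy, -(lo[0] - pad), (CANVAS_SIZE - 1 - pad) - hi[0]))
    jx = int(np.clip(jx, -(lo[1] - pad), (CANVAS_SIZE - 1 - pad) - hi[1]))
    return jx, jy


def transform_and_compose(fg: AlphaImage, bg: GrayImage, spec: TransformSpec,
                          rng: np.random.Generator | None = None,
                          draw: TransformDraw | None = None,
                          ) -> tuple[GrayImage, TransformDraw]:
    """Scale, rotate, jitter and alpha-composite a foreground over a background.

    A transform is drawn from ``spec`` using ``rng`` unless an explicit
    ``draw`` is given. Jitter that would push any opaque pixel off the canvas
    is clipped to keep the foreground fully inside. Returns the composed
    stimulus together with the transform actually applied.
    """
    if draw is None:
        if rng is None:
            raise ValueError("either rng or an explicit draw is required")
        draw = spec.draw(rng)
    if not fg.mask.any():
        raise ValueError("foreground has no opaque pixel")
    jx, jy = _clip_jitter(fg, draw.scale, draw.rotation, draw.jitter)
    draw = TransformDraw(scale=draw.scale, rotation=draw.rotation, jitter=(jx, jy))
    lum, alpha = _warp_foreground(fg, draw)
    opaque = alpha >= 0.5
    out = np.where(opaque, lum, bg.pixels)
    return GrayImage(pixels=np.clip(out, 0, 255)), draw


# ---------------------------------------------------------------------------
# set-level statistics


def shape_stats(fg: AlphaImage) -> tuple[float, float]:
    """(fraction_filled, elongation) of the opaque support.

    fraction_filled is the opaque-pixel count over the 256^2 canvas;
    elongation is max(w, h) / min(w, h) of the opaque bounding box.
    """
    mask = fg.mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty alpha mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    h = rows[-1] - rows[0] + 1
    w = cols[-1] - cols[0] + 1
    return n / float(FG_SIZE * FG_SIZE), max(h, w) / float(min(h, w))


def rms_contrast(pixels: np.ndarray) -> float:
    """RMS contrast = standard deviation of luminance (0-255 scale)."""
    return float(np.asarray(pixels, dtype=np.float64).std())


def _set_summary(images: list[AlphaImage]) -> dict[str, float]:
    means = [float(im.opaque_values().mean()) for im in images]
    rmss = [rms_contrast(im.opaque_values()) for im in images]
    return {"mean_luminance": float(np.mean(means)), "rms_contrast": float(np.mean(rmss))}


def match_luminance(set_a: list[AlphaImage], set_b: list[AlphaImage],
                    ) -> tuple[list[AlphaImage], dict]:
    """Brighten every image of ``set_b`` by 15% (clipped at 255).

    Returns the adjusted set_b plus before/after mean-luminance and
    RMS-contrast summaries of both sets. Applied once at set-construction
    time, before any background or nuisance transform.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be nonempty")
    before = {"set_a": _set_summary(set_a), "set_b": _set_summary(set_b)}
    adjusted = [AlphaImage(pixels=np.clip(im.pixels * 1.15, 0, 255), alpha=im.alpha.copy())
                for im in set_b]
    after = {"set_a": before["set_a"], "set_b": _set_summary(adjusted)}
    return adjusted, {"before": before, "after": after}


# ---------------------------------------------------------------------------
# PNG I/O and fixtures


def save_png(img: AlphaImage | GrayImage, path: str | Path) -> None:
    """Write a foreground as 8-bit RGBA PNG or a stimulus as 8-bit grayscale."""
    path = Path(path)
    if isinstance(img, AlphaImage):
        g = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
        a = np.clip(np.rint(img.alpha * 255), 0, 255).astype(np.uint8)
        rgba = np.stack([g, g, g, a], axis=-1)
        Image.fromarray(rgba, mode="RGBA").save(path)
    else:
        g = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
        Image.fromarray(g, mode="L").save(path)


def load_foreground_png(path: str | Path) -> AlphaImage:
    arr = np.asarray(Image.open(path).convert("RGBA"), dtype=np.float64)
    return AlphaImage(pixels=arr[..., 0], alpha=arr[..., 3] / 255.0)


def load_gray_png(path: str | Path) -> GrayImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return GrayImage(pixels=arr)


def write_fixture_set(out_dir: str | Path, n_per_class: int, seed: int = 0,
                      fg_params: dict | None = None) -> dict[str, list[Path]]:
    """Materialize n face + n nonface foregrounds and n scenes as PNGs.

    Non-face foregrounds are written after the +15% luminance-matching step,
    mirroring how sets are constructed for experiments.
    """
    out_dir = Path(out_dir)
    written: dict[str, list[Path]] = {"face": [], "nonface": [], "scene": []}
    for cls in ("face", "nonface"):
        d = out_dir / cls
        d.mkdir(parents=True, exist_ok=True)
        imgs = [gen_foreground(cls, seed * 1_000_003 + i, fg_params) for i in range(n_per_class)]
        if cls == "nonface":
            faces = [gen_foreground("face", seed * 1_000_003 + i, fg_params)
                     for i in range(min(n_per_class, 8))]
            imgs, _ = match_luminance(faces, imgs)
        for i, im in enumerate(imgs):
            p = d / f"{cls}_{i:04d}.png"
            save_png(im, p)
            written[cls].append(p)
    d = out_dir / "scene"
    d.mkdir(parents=True, exist_ok=True)
    pool = ScenePool(seed=seed, n_scenes=n_per_class)
    for i in range(n_per_class):
        p = d / f"scene_{i:04d}.png"
        save_png(pool.get(i), p)
        written["scene"].append(p)
    return written
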