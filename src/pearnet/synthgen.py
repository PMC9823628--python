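"""Synthetic orchard scenes with exact ground truth.

The generator emulates the experimental axes of an in-field pear dataset:

* pears in three radius classes (small < 10 px, medium 10-25 px, large
  > 25 px; below 5 px omitted from ground truth), drawn as shaded ellipses
  in the yellow-green hue band over leaf/branch-textured background;
* dense occlusion by foliage, branches and other fruit, bounded by an
  occlusion fraction;
* four illumination regimes — weak, normal and strong daylight plus warm
  artificial night light — applied as brightness/gamma/colour-temperature
  transforms, ordered in mean brightness weak < normal < strong;
* ground (side) versus aerial (bird's-eye) viewpoints, the latter with a
  denser canopy and a smaller fruit-size distribution.

Scenes are deterministic functions of their spec (including its seed).
Ground-truth boxes are amodal (the full fruit extent) clipped to image
bounds.  The default radius mixture (25% small / 58% medium / 17% large)
follows the stratum proportions of the field dataset the generator stands
in for.

The module also implements the training-time augmentations: left-right
and up-down flips, HSV jitter, random blur and 4-image mosaic composition,
with consistent box remapping.
"""

from __future__ import annotations

import colorsys
import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import (BoundingBox, DatasetIndex, ImageRecord, size_class,
                      split_dataset, write_annotations)

__all__ = [
    "SceneSpec", "render_scene", "augment", "make_fixture_set",
    "lr_flip", "ud_flip", "hsv_jitter", "random_blur", "mosaic",
    "ILLUMINATIONS", "VIEWPOINTS",
]

ILLUMINATIONS = ("weak", "normal", "strong", "artificial")
VIEWPOINTS = ("side", "birdseye")

# default stratum mixture: small/medium/large proportions of the field data
DEFAULT_RADIUS_MIXTURE = ((5.0, 10.0, 0.25), (10.0, 25.0, 0.58),
                          (25.0, 60.0, 0.17))

# proportions of test images per illumination regime in the field data
ILLUMINATION_WEIGHTS = {"strong": 80 / 368, "normal": 124 / 368,
                        "weak": 96 / 368, "artificial": 68 / 368}
VIEWPOINT_WEIGHTS = {"side": 0.7, "birdseye": 0.3}


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic orchard image.

    ``radius_distribution`` is a tuple of (lo_px, hi_px, weight) bands;
    radii are drawn uniformly within a band chosen by weight.  Radii are
    capped at image_size / 4.  ``occlusion_fraction`` bounds the expected
    fraction of each pear covered by occluders.
    """

    image_size: int = 640
    n_pears: int = 12
    radius_distribution: tuple = DEFAULT_RADIUS_MIXTURE
    occlusion_fraction: float = 0.3
    illumination: str = "normal"
    viewpoint: str = "side"
    seed: int = 0

    def __post_init__(self):
        if self.illumination not in ILLUMINATIONS:
            raise ValueError(f"unknown illumination {self.illumination!r}")
        if self.viewpoint not in VIEWPOINTS:
            raise ValueError(f"unknown viewpoint {self.viewpoint!r}")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if self.n_pears < 0:
            raise ValueError("n_pears must be non-negative")
        for lo, hi, wgt in self.radius_distribution:
            if not (5.0 <= lo < hi) or wgt < 0:
                raise ValueError("radius bands must satisfy 5 <= lo < hi, w >= 0")


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------


def _hsv_rgb(h, s, v):
    return np.array(colorsys.hsv_to_rgb(h, s, v))


def _smooth_noise(rng, size, scale, lo, hi):
    coarse = rng.random((max(size // scale, 2),) * 2)
    up = np.kron(coarse, np.ones((scale, scale)))[:size, :size]
    up = ndimage.gaussian_filter(up, scale / 2)
    up = (up - up.min()) / max(np.ptp(up), 1e-9)
    return lo + (hi - lo) * up


def _draw_ellipse(img, cy, cx, ry, rx, color, shade=None, rng=None):
    """Paint a filled ellipse; ``shade`` adds a radial gradient in [0,1]
    distance units.  Returns the boolean mask painted."""
    size = img.shape[0]
    y0, y1 = max(int(cy - ry) - 1, 0), min(int(cy + ry) + 2, size)
    x0, x1 = max(int(cx - rx) - 1, 0), min(int(cx + rx) + 2, size)
    if y1 <= y0 or x1 <= x0:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    mask = d2 <= 1.0
    if not mask.any():
        return None
    patch = img[y0:y1, x0:x1]
    col = np.asarray(color, dtype=np.float32)
    if shade is not None:
        grad = (1.0 - shade * d2[mask])[:, None]
        patch[mask] = col * grad
    else:
        patch[mask] = col
    return (y0, y1, x0, x1, mask)


def _paint_background(img, rng, spec):
    size = spec.image_size
    # canopy base: green noise field with brownish undertone
    base_v = _smooth_noise(rng, size, max(size // 8, 2), 0.12, 0.45)
    base_h = _smooth_noise(rng, size, max(size // 4, 2), 0.20, 0.36)
    sat = 0.5 + 0.2 * _smooth_noise(rng, size, max(size // 8, 2), 0, 1)
    hsv = np.stack([base_h, sat, base_v], axis=-1)
    from skimage.color import hsv2rgb
    img[:] = hsv2rgb(hsv).astype(np.float32)
    # leaf blobs
    n_leaves = max(int((size / 64) ** 2 * (3 if spec.viewpoint == "side" else 5)), 3)
    for _ in range(n_leaves):
        cy, cx = rng.random(2) * size
        r = rng.uniform(size * 0.015, size * 0.06)
        hue = rng.uniform(0.22, 0.38)
        col = _hsv_rgb(hue, rng.uniform(0.5, 0.9), rng.uniform(0.15, 0.5))
        _draw_ellipse(img, cy, cx, r * rng.uniform(0.5, 1.0), r, col, shade=0.3)
    # branches: thin elongated dark strips
    for _ in range(max(size // 160, 1)):
        cy, cx = rng.random(2) * size
        ang = rng.uniform(0, np.pi)
        ln = rng.uniform(size * 0.3, size * 0.9)
        th = rng.uniform(1, max(size / 160, 1.5))
        _draw_strip(img, cy, cx, ang, ln, th,
                    _hsv_rgb(rng.uniform(0.06, 0.1), 0.6, rng.uniform(0.15, 0.3)))


def _draw_strip(img, cy, cx, angle, length, thickness, color):
    size = img.shape[0]
    t = np.linspace(-length / 2, length / 2, int(length) * 2)
    ys = (cy + t * np.sin(angle)).astype(int)
    xs = (cx + t * np.cos(angle)).astype(int)
    r = max(int(round(thickness)), 1)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            yy = np.clip(ys + dy, 0, size - 1)
            xx = np.clip(xs + dx, 0, size - 1)
            img[yy, xx] = color


def _sample_radius(rng, spec) -> float:
    cap = spec.image_size / 4
    bands = [b for b in spec.radius_distribution if b[0] < cap]
    if not bands:
        raise ValueError(
            f"no radius band fits below the {cap:.0f} px cap "
            f"(image_size / 4) for image_size={spec.image_size}")
    w = np.array([b[2] for b in bands], dtype=float)
    w /= w.sum()
    lo, hi, _ = bands[rng.choice(len(bands), p=w)]
    r = rng.uniform(lo, min(hi, cap))
    if spec.viewpoint == "birdseye":
        r = max(r * 0.8, 5.0)
    return min(r, cap)


def _apply_illumination(img, regime, rng):
    if regime == "weak":
        img = np.clip(img, 0, 1) ** 1.25 * 0.55
    elif regime == "strong":
        img = np.clip(img * 1.35 + 0.05, 0, 1) ** 0.85
    elif regime == "artificial":
        img = img * np.array([1.18, 0.95, 0.72])  # warm cast
        size = img.shape[0]
        yy, xx = np.mgrid[0:size, 0:size]
        d = np.sqrt(((yy - size / 2) ** 2 + (xx - size / 2) ** 2)) / (size / np.sqrt(2))
        img = img * (1.0 - 0.45 * d ** 2)[..., None] * 0.9
    return np.clip(img, 0.0, 1.0)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, list[BoundingBox]]:
    """Render one scene; returns (uint8 RGB image, ground-truth boxes).

    Deterministic in ``spec`` (including ``spec.seed``).  Boxes are the
    amodal extent of each pear clipped to image bounds; pears whose
    post-clip radius falls below 5 px are omitted.
    """
    size = spec.image_size
    min_r = min(b[0] for b in spec.radius_distribution)
    if spec.n_pears * (2 * min_r) ** 2 > 0.85 * size * size:
        raise ValueError(
            f"cannot pack {spec.n_pears} pears of radius >= {min_r} px "
            f"into a {size} px image")
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((size, size, 3), dtype=np.float32)
    _paint_background(img, rng, spec)

    pears = []  # (cy, cx, ry, rx)
    boxes: list[BoundingBox] = []
    for _ in range(spec.n_pears):
        r = _sample_radius(rng, spec)
        aspect = rng.uniform(0.8, 1.1)  # height / width
        rx, ry = r, r * aspect
        cy = rng.uniform(0, size)
        cx = rng.uniform(0, size)
        hue = rng.uniform(30 / 360, 75 / 360)
        col = _hsv_rgb(hue, rng.uniform(0.55, 0.85), rng.uniform(0.65, 0.95))
        _draw_ellipse(img, cy, cx, ry, rx, col, shade=0.5)
        if spec.illumination in ("strong", "artificial"):
            _draw_ellipse(img, cy - 0.35 * ry, cx - 0.35 * rx,
                          max(ry * 0.18, 1), max(rx * 0.18, 1),
                          np.minimum(col * 1.6 + 0.25, 1.0), shade=0.8)
        pears.append((cy, cx, ry, rx))

    # occluders: per-pear foliage covering up to the occlusion fraction
    for cy, cx, ry, rx in pears:
        cover = rng.uniform(0.0, spec.occlusion_fraction)
        if cover <= 0.02:
            continue
        occ_r = np.sqrt(cover) * max(ry, rx)
        ang = rng.uniform(0, 2 * np.pi)
        ocy = cy + np.sin(ang) * ry * 0.8
        ocx = cx + np.cos(ang) * rx * 0.8
        col = _hsv_rgb(rng.uniform(0.24, 0.36), rng.uniform(0.6, 0.9),
                       rng.uniform(0.2, 0.45))
        _draw_ellipse(img, ocy, ocx, occ_r * rng.uniform(0.7, 1.2), occ_r,
                      col, shade=0.3)
    # foreground branch strips
    for _ in range(max(size // 320, 1)):
        cy, cx = rng.random(2) * size
        _draw_strip(img, cy, cx, rng.uniform(0, np.pi),
                    rng.uniform(size * 0.2, size * 0.6),
                    max(size / 250, 1.0),
                    _hsv_rgb(rng.uniform(0.06, 0.1), 0.6, 0.2))

    img = _apply_illumination(img, spec.illumination, rng)

    tags = {"illumination": spec.illumination, "viewpoint": spec.viewpoint}
    for cy, cx, ry, rx in pears:
        b = BoundingBox(0, cx / size, cy / size, 2 * rx / size, 2 * ry / size,
                        tags=dict(tags)).clipped()
        if b.w <= 0 or b.h <= 0:
            continue
        if size_class(b, size) == "omitted":
            continue
        boxes.append(b)
    return (img * 255).round().astype(np.uint8), boxes


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------


def lr_flip(image, boxes):
    out = [dataclasses.replace(b, cx=1.0 - b.cx) for b in boxes]
    return np.ascontiguousarray(image[:, ::-1]), out


def ud_flip(image, boxes):
    out = [dataclasses.replace(b, cy=1.0 - b.cy) for b in boxes]
    return np.ascontiguousarray(image[::-1]), out


def hsv_jitter(image, rng, h_gain=0.015, s_gain=0.7, v_gain=0.7):
    """Random hue/saturation/value perturbation; boxes are unaffected."""
    from skimage.color import hsv2rgb, rgb2hsv
    hsv = rgb2hsv(image.astype(np.float32) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-h_gain, h_gain)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-s_gain, s_gain)), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-v_gain, v_gain)), 0, 1)
    return (hsv2rgb(hsv) * 255).round().astype(np.uint8)


def random_blur(image, rng, sigma_range=(0.5, 1.5)):
    sigma = rng.uniform(*sigma_range)
    out = ndimage.gaussian_filter(image.astype(np.float32),
                                  sigma=(sigma, sigma, 0))
    return np.clip(out, 0, 255).round().astype(np.uint8)


def mosaic(items: list[tuple[np.ndarray, list[BoundingBox]]], rng=None):
    """Compose four (image, boxes) pairs into one image of the same size:
    each source is scaled by 1/2 into its quadrant and its boxes remapped
    and clipped."""
    if len(items) != 4:
        raise ValueError("mosaic requires exactly 4 source images")
    size = items[0][0].shape[0]
    out = np.zeros_like(items[0][0])
    boxes_out: list[BoundingBox] = []
    half = size // 2
    offsets = [(0, 0), (0, half), (half, 0), (half, half)]
    for (img, boxes), (oy, ox) in zip(items, offsets):
        small = img[::2, ::2]
        out[oy:oy + half, ox:ox + half] = small[:half, :half]
        for b in boxes:
            nb = dataclasses.replace(
                b, cx=b.cx / 2 + ox / size, cy=b.cy / 2 + oy / size,
                w=b.w / 2, h=b.h / 2).clipped()
            if nb.w > 1e-4 and nb.h > 1e-4:
                boxes_out.append(nb)
    return out, boxes_out


_AUG_OPS = ("lr_flip", "ud_flip", "hsv", "blur", "mosaic")


def augment(image, boxes, ops=None, seed: int = 0, extra=None):
    """Apply augmentations with consistent box remapping.

    ``ops`` is a subset of {'lr_flip', 'ud_flip', 'hsv', 'blur', 'mosaic'};
    when None, the non-mosaic operations are each applied with probability
    0.5 (the random selection made at image-reading time during training).
    Mosaic needs three ``extra`` (image, boxes) sources.
    """
    rng = np.random.default_rng(seed)
    if ops is None:
        ops = [op for op in ("lr_flip", "ud_flip", "hsv", "blur")
               if rng.random() < 0.5]
    unknown = set(ops) - set(_AUG_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation(s): {sorted(unknown)}")
    if "mosaic" in ops:
        if not extra or len(extra) < 3:
            raise ValueError("mosaic requires 4 source images "
                             "(pass 3 more via extra=)")
        image, boxes = mosaic([(image, boxes)] + list(extra[:3]), rng)
    if "lr_flip" in ops:
        image, boxes = lr_flip(image, boxes)
    if "ud_flip" in ops:
        image, boxes = ud_flip(image, boxes)
    if "hsv" in ops:
        image = hsv_jitter(image, rng)
    if "blur" in ops:
        image = random_blur(image, rng)
    return image, boxes


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------


def make_fixture_set(n_images: int, spec_template: SceneSpec, seed: int,
                     out_dir, vary_conditions: bool = True) -> DatasetIndex:
    """Render ``n_images`` scenes to the ``images/`` + ``labels/`` layout
    with split manifests and a JSON manifest of per-stratum box counts.

    With ``vary_conditions`` the illumination regime and viewpoint of each
    scene are drawn with the field-data proportions; otherwise every scene
    uses the template's.
    """
    from PIL import Image

    if n_images < 0:
        raise ValueError("n_images must be non-negative")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    strata = {s: 0 for s in ("small", "medium", "large")}
    entries, records = [], []
    splits = split_dataset(n_images, seed=seed) if n_images >= 3 else \
        ["train"] * n_images
    for i in range(n_images):
        spec = dataclasses.replace(spec_template, seed=int(rng.integers(2**31)))
        if vary_conditions:
            ill = rng.choice(list(ILLUMINATION_WEIGHTS),
                             p=list(ILLUMINATION_WEIGHTS.values()))
            vp = rng.choice(list(VIEWPOINT_WEIGHTS),
                            p=list(VIEWPOINT_WEIGHTS.values()))
            spec = dataclasses.replace(spec, illumination=str(ill),
                                       viewpoint=str(vp))
        img, boxes = render_scene(spec)
        name = f"scene_{i:04d}"
        Image.fromarray(img).save(out_dir / "images" / f"{name}.png")
        (out_dir / "labels" / f"{name}.txt").write_text(
            write_annotations(boxes))
        counts = {s: 0 for s in strata}
        for b in boxes:
            sc = size_class(b, spec.image_size)
            if sc in counts:
                counts[sc] += 1
                strata[sc] += 1
        tags = {"illumination": spec.illumination, "viewpoint": spec.viewpoint}
        entries.append({"image": f"{name}.png", "seed": spec.seed,
                        "tags": tags, "n_boxes": len(boxes),
                        "stratum_counts": counts})
        records.append(ImageRecord(str(out_dir / "images" / f"{name}.png"),
                                   spec.image_size, spec.image_size, boxes,
                                   split=splits[i], tags=tags))
    index = DatasetIndex(records)
    index.write_manifests(out_dir)
    manifest = {"n_images": n_images, "seed": seed,
                "stratum_counts": strata, "images": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return index
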