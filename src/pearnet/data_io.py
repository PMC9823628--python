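"""Annotation I/O, dataset splitting, size stratification and
near-duplicate filtering.

Annotations use the YOLO plain-text convention: one ``.txt`` per image, one
object per line, ``class cx cy w h`` with coordinates normalised to the
image size (center format).  Directory layout is ``images/`` + ``labels/``
with parallel file stems and plain-text split manifests.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

__all__ = [
    "BoundingBox", "ImageRecord", "DatasetIndex",
    "read_annotations", "write_annotations", "read_corner_annotations",
    "split_dataset", "size_class", "dedup_filter", "load_dataset",
]

SIZE_CLASSES = ("small", "medium", "large", "omitted")


@dataclasses.dataclass
class BoundingBox:
    """One ground-truth or predicted object in normalised center format.

    ``cx, cy, w, h`` are fractions of the image size; ``confidence`` is set
    on predictions only; ``tags`` carries stratum labels (illumination,
    viewpoint, ...) when known.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None
    tags: dict | None = None

    def to_xyxy(self, size: float = 1.0) -> tuple[float, float, float, float]:
        return ((self.cx - self.w / 2) * size, (self.cy - self.h / 2) * size,
                (self.cx + self.w / 2) * size, (self.cy + self.h / 2) * size)

    @classmethod
    def from_xyxy(cls, class_id, x1, y1, x2, y2, size: float = 1.0, **kw):
        return cls(class_id, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                   (x2 - x1) / size, (y2 - y1) / size, **kw)

    def clipped(self) -> "BoundingBox":
        """Clip the box to the unit square, preserving center format."""
        x1, y1, x2, y2 = self.to_xyxy()
        x1, y1 = max(x1, 0.0), max(y1, 0.0)
        x2, y2 = min(x2, 1.0), min(y2, 1.0)
        if x2 <= x1 or y2 <= y1:
            return dataclasses.replace(self, w=0.0, h=0.0)
        return BoundingBox.from_xyxy(self.class_id, x1, y1, x2, y2,
                                     confidence=self.confidence, tags=self.tags)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclasses.dataclass
class ImageRecord:
    path: str
    width: int
    height: int
    boxes: list[BoundingBox]
    split: str | None = None
    tags: dict | None = None


@dataclasses.dataclass
class DatasetIndex:
    records: list[ImageRecord]

    def subset(self, split: str) -> list[ImageRecord]:
        return [r for r in self.records if r.split == split]

    def split_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.split] = out.get(r.split, 0) + 1
        return out

    def write_manifests(self, root: str | Path) -> None:
        root = Path(root)
        for split in ("train", "val", "test"):
            lines = [Path(r.path).name for r in self.subset(split)]
            (root / f"{split}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------


def read_annotations(text: str) -> list[BoundingBox]:
    """Parse YOLO-format annotation text.

    Values outside [0, 1] are clipped (one warning reporting the count);
    malformed lines raise ``ValueError`` naming the line number.
    """
    boxes: list[BoundingBox] = []
    clipped = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(
                f"line {lineno}: expected 5 fields 'class cx cy w h' "
                f"(optionally + confidence), got {len(parts)}")
        try:
            cid = int(parts[0])
            vals = [float(v) for v in parts[1:5]]
            conf = float(parts[5]) if len(parts) == 6 else None
        except ValueError as e:
            raise ValueError(f"line {lineno}: {e}") from None
        cl = [min(max(v, 0.0), 1.0) for v in vals]
        clipped += sum(a != b for a, b in zip(vals, cl))
        boxes.append(BoundingBox(cid, *cl, confidence=conf))
    if clipped:
        warnings.warn(f"{clipped} coordinate value(s) clipped to [0, 1]",
                      stacklevel=2)
    return boxes


def write_annotations(boxes: list[BoundingBox]) -> str:
    """Inverse of :func:`read_annotations`; 6-decimal round-trip."""
    lines = []
    for b in boxes:
        fields = f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
        if b.confidence is not None:
            fields += f" {b.confidence:.6f}"
        lines.append(fields)
    return "\n".join(lines) + ("\n" if lines else "")


def read_corner_annotations(text: str, image_size: tuple[int, int]
                            ) -> list[BoundingBox]:
    """Import shim for corner-format files: ``class x1 y1 x2 y2`` in pixels
    (upper-left and lower-right corners)."""
    W, H = image_size
    boxes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 'class x1 y1 x2 y2'")
        cid = int(parts[0])
        x1, y1, x2, y2 = (float(v) for v in parts[1:])
        b = BoundingBox(cid, (x1 + x2) / 2 / W, (y1 + y2) / 2 / H,
                        (x2 - x1) / W, (y2 - y1) / H)
        boxes.append(b.clipped())
    return boxes


# ---------------------------------------------------------------------------
# Splitting and stratification
# ---------------------------------------------------------------------------


def split_dataset(n_images: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> list[str]:
    """Random train/val/test partition labels for ``n_images`` items.

    Val and test counts are floor-based; the remainder goes to train
    (3680 -> 2944/368/368 at 80/10/10).  Deterministic under ``seed``.
    """
    if n_images < 3:
        raise ValueError("need at least 3 images to form three splits")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n_val = int(n_images * ratios[1])
    n_test = int(n_images * ratios[2])
    n_train = n_images - n_val - n_test
    labels = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_images)
    out = [""] * n_images
    for pos, lab in zip(perm, labels):
        out[pos] = lab
    return out


def size_class(box: BoundingBox, image_size: int) -> str:
    """Size stratum of a box by pear radius, taken as half the larger
    pixel side.  Radius < 5 px is omitted from evaluation; boundary radii
    fall in the lower class (exactly 10 -> small, exactly 25 -> medium)."""
    radius = max(box.w, box.h) * image_size / 2.0
    if radius < 5:
        return "omitted"
    if radius <= 10:
        return "small"
    if radius <= 25:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# Near-duplicate filtering
# ---------------------------------------------------------------------------


def dedup_filter(images: list[np.ndarray], similarity_threshold: float = 0.6,
                 n_keypoints: int = 500) -> list[int]:
    """Greedy near-duplicate scan using ORB keypoint descriptors.

    Returns indices of retained images.  An image is dropped when the
    fraction of its descriptors matching a retained image (mutual
    nearest-neighbour Hamming matches) exceeds ``similarity_threshold``.
    """
    from skimage.color import rgb2gray
    from skimage.feature import ORB, match_descriptors

    if not images:
        raise ValueError("dedup_filter requires at least one image")

    descs = []
    for img in images:
        g = rgb2gray(img) if img.ndim == 3 else img.astype(float)
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        try:
            orb.detect_and_extract(g)
            descs.append(orb.descriptors)
        except RuntimeError:  # no keypoints found
            descs.append(None)

    kept: list[int] = []
    for i, d in enumerate(descs):
        duplicate = False
        if d is not None:
            for j in kept:
                dj = descs[j]
                if dj is None:
                    continue
                matches = match_descriptors(d, dj, cross_check=True)
                ratio = len(matches) / max(min(len(d), len(dj)), 1)
                if ratio > similarity_threshold:
                    duplicate = True
                    break
        if not duplicate:
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------


def load_dataset(root: str | Path) -> DatasetIndex:
    """Load an ``images/`` + ``labels/`` layout with split manifests and an
    optional ``manifest.json`` carrying per-image stratum tags."""
    from PIL import Image

    root = Path(root)
    img_dir, lab_dir = root / "images", root / "labels"
    if not img_dir.is_dir() or not lab_dir.is_dir():
        raise FileNotFoundError(f"{root} lacks images/ and labels/ directories")
    split_of: dict[str, str] = {}
    for split in ("train", "val", "test"):
        mf = root / f"{split}.txt"
        if mf.exists():
            for name in mf.read_text().split():
                split_of[name] = split
    tags_of: dict[str, dict] = {}
    meta = root / "manifest.json"
    if meta.exists():
        manifest = json.loads(meta.read_text())
        tags_of = {e["image"]: e.get("tags", {})
                   for e in manifest.get("images", [])}
    records = []
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        with Image.open(p) as im:
            w, h = im.size
        lab = lab_dir / (p.stem + ".txt")
        boxes = read_annotations(lab.read_text()) if lab.exists() else []
        tags = tags_of.get(p.name)
        if tags:
            for b in boxes:
                b.tags = dict(tags)
        records.append(ImageRecord(str(p), w, h, boxes,
                                   split=split_of.get(p.name), tags=tags))
    return DatasetIndex(records)
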