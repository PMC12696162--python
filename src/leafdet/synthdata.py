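"""Deterministic synthetic foliar-disease scene generator with YOLO labels.

Renders a green Ginkgo-style fan-shaped leaf on a textured soil
background and paints class-conditioned lesions on it:

* class 0, chlorosis — diffuse yellow patches (fungal yellowing);
* class 1, insect pest — clusters of small dark holes/spots;
* class 2, physical damage — pale elongated tears.

The generator emulates the statistical structure of a field dataset of
leaf-disease annotations: a 1779 : 5260 : 2543 class mix, lesion
centroids uniform over the leaf surface, predominantly near-isometric
boxes with a configurable minority of elongated (anisotropic) ones, and
an 8:1:1 train/val/test split assigned by a stable hash of the image
index so that growing the dataset never reassigns existing images.
Every label box is the exact pixel bounding box of the painted lesion.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

CLASS_NAMES = ("chlorosis", "insect_pest", "physical_damage")
# instance counts of the emulated dataset, normalized to a class mix
_RAW_MIX = np.array([1779.0, 5260.0, 2543.0])
DEFAULT_CLASS_MIX = tuple(_RAW_MIX / _RAW_MIX.sum())

_LESION_COLORS = {
    0: np.array([198.0, 186.0, 64.0]),   # diffuse yellow
    1: np.array([48.0, 32.0, 18.0]),     # dark feeding holes
    2: np.array([226.0, 214.0, 186.0]),  # pale tear
}


@dataclass(frozen=True)
class SceneConfig:
    n_images: int = 100
    image_size: int = 640
    class_mix: tuple = DEFAULT_CLASS_MIX
    lesions_per_image: tuple = (1, 3)     # inclusive integer range
    anisotropy_fraction: float = 0.2      # share of elongated lesions
    lesion_scale: tuple = (0.06, 0.20)    # lesion extent relative to image
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        mix = np.asarray(self.class_mix, dtype=np.float64)
        if len(mix) != 3 or not np.isclose(mix.sum(), 1.0):
            raise ValueError("class_mix must be 3 proportions summing to 1")
        lo, hi = self.lesions_per_image
        if lo < 0 or hi < lo:
            raise ValueError("invalid lesions_per_image range")


@dataclass(frozen=True)
class LabelRecord:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not 0 <= self.class_id:
            raise ValueError("class_id must be non-negative")
        for v in (self.cx, self.cy, self.w, self.h):
            if not 0.0 <= v <= 1.0:
                raise ValueError("label fields must be normalized to [0, 1]")


# ---------------------------------------------------------------------------
# label file I/O
# ---------------------------------------------------------------------------


def read_yolo_labels(path, n_classes=3):
    """One ``class cx cy w h`` line per box; raises naming the bad line."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed number") from e
            if not 0 <= cid < n_classes:
                raise ValueError(
                    f"{path}:{ln}: class {cid} outside [0, {n_classes})")
            records.append(LabelRecord(cid, *vals))
    return records


def write_yolo_labels(path, records):
    """Space-separated, 6-decimal fixed format; round-trips at 1e-6."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.class_id} {r.cx:.6f} {r.cy:.6f} {r.w:.6f} {r.h:.6f}\n")


def split_of_index(index):
    """Stable 8:1:1 split by hash: adding images never reassigns old ones."""
    h = int(hashlib.sha1(f"img{index:06d}".encode()).hexdigest(), 16) % 10
    return "train" if h < 8 else ("val" if h == 8 else "test")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _smooth_noise(rng, size, sigma, lo, hi):
    n = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    n = (n - n.min()) / (np.ptp(n) + 1e-9)
    return lo + (hi - lo) * n


def _leaf_mask(rng, s):
    """Fan-shaped leaf silhouette with a wavy outer margin."""
    yy, xx = np.mgrid[0:s, 0:s]
    # stem point near the bottom center, fan opening upward
    px = s * (0.5 + rng.uniform(-0.05, 0.05))
    py = s * (0.92 + rng.uniform(-0.03, 0.0))
    dx, dy = xx - px, yy - py
    r = np.hypot(dx, dy)
    theta = np.arctan2(-dy, dx)  # 0..pi above the stem point
    t0 = np.pi / 2 + rng.uniform(-0.15, 0.15)
    spread = rng.uniform(0.95, 1.25)
    wav_k = rng.integers(7, 11)
    wav_ph = rng.uniform(0, 2 * np.pi)
    radius = s * rng.uniform(0.78, 0.9) * (
        1.0 + 0.035 * np.sin(wav_k * theta + wav_ph))
    inside = (np.abs(theta - t0) < spread) & (r < radius) & (r > s * 0.04)
    return inside


def _paint(img, mask, color, alpha):
    for c in range(3):
        img[..., c] = np.where(mask, (1 - alpha) * img[..., c] + alpha * color[c],
                               img[..., c])


def _ellipse_mask(s, cx, cy, rx, ry):
    yy, xx = np.mgrid[0:s, 0:s]
    return ((xx - cx) / max(rx, 1e-6)) ** 2 + ((yy - cy) / max(ry, 1e-6)) ** 2 <= 1.0


def _render_lesion(rng, img, leaf, cls, cx, cy, rx, ry):
    """Paint one lesion; returns its pixel footprint mask."""
    s = img.shape[0]
    if cls == 0:  # diffuse yellow patch with a soft edge
        core = _ellipse_mask(s, cx, cy, rx, ry)
        soft = ndimage.gaussian_filter(core.astype(float), sigma=max(rx, ry) * 0.08)
        # footprint = clearly visible pixels, so the label box hugs the
        # apparent patch rather than its faint halo
        mask = soft > 0.5
        alpha = np.clip(soft, 0, 1) * 0.95
        for c in range(3):
            img[..., c] = np.where(mask, (1 - alpha) * img[..., c]
                                   + alpha * _LESION_COLORS[0][c], img[..., c])
        return mask
    if cls == 1:  # compact cluster of dark feeding holes
        mask = np.zeros((s, s), dtype=bool)
        n_spots = rng.integers(2, 5)
        for _ in range(n_spots):
            ox = cx + rng.uniform(-0.35, 0.35) * rx
            oy = cy + rng.uniform(-0.35, 0.35) * ry
            rr = max(2.0, rng.uniform(0.35, 0.55) * min(rx, ry))
            mask |= _ellipse_mask(s, ox, oy, rr, rr)
        _paint(img, mask, _LESION_COLORS[1], 0.95)
        return mask
    # cls == 2: pale tear
    mask = _ellipse_mask(s, cx, cy, rx, ry)
    _paint(img, mask, _LESION_COLORS[2], 0.9)
    edge = mask & ~ndimage.binary_erosion(mask, iterations=max(1, int(s / 160)))
    _paint(img, edge, _LESION_COLORS[2] * 0.55, 0.8)
    return mask


def render_scene(cfg: SceneConfig, index):
    """Render image ``index``: returns (uint8 HxWx3 image, [LabelRecord])."""
    s = cfg.image_size
    rng = np.random.default_rng((cfg.seed * 1_000_003 + index) % (2 ** 31))
    img = np.empty((s, s, 3), dtype=np.float64)
    # soil/ground background
    base = np.array([112, 96, 72]) + rng.uniform(-12, 12, 3)
    tex = _smooth_noise(rng, s, sigma=max(s / 24, 2), lo=-18, hi=18)
    for c in range(3):
        img[..., c] = base[c] + tex
    leaf = _leaf_mask(rng, s)
    leaf_color = np.array([64, 128, 52]) + rng.uniform(-14, 14, 3)
    shade = _smooth_noise(rng, s, sigma=max(s / 10, 2), lo=-14, hi=14)
    for c in range(3):
        img[..., c] = np.where(leaf, leaf_color[c] + shade, img[..., c])

    n_lesions = int(rng.integers(cfg.lesions_per_image[0],
                                 cfg.lesions_per_image[1] + 1))
    interior = ndimage.binary_erosion(leaf, iterations=max(2, s // 64))
    ys, xs = np.nonzero(interior)
    records = []
    for _ in range(n_lesions):
        if len(xs) == 0:
            break
        cls = int(rng.choice(3, p=np.asarray(cfg.class_mix)))
        j = rng.integers(len(xs))
        cx, cy = float(xs[j]), float(ys[j])  # centroid uniform over the leaf
        extent = rng.uniform(*cfg.lesion_scale) * s / 2
        if rng.uniform() < cfg.anisotropy_fraction:
            ar = rng.uniform(2.5, 4.0)       # elongated (linear abrasion-like)
        else:
            ar = rng.uniform(1.0, 1.35)      # near-isometric
        if rng.uniform() < 0.5:
            rx, ry = extent * np.sqrt(ar), extent / np.sqrt(ar)
        else:
            rx, ry = extent / np.sqrt(ar), extent * np.sqrt(ar)
        footprint = _render_lesion(rng, img, leaf, cls, cx, cy, rx, ry)
        fy, fx = np.nonzero(footprint)
        if len(fx) < 4:
            continue
        x1, x2 = fx.min(), fx.max() + 1
        y1, y2 = fy.min(), fy.max() + 1
        rec = LabelRecord(cls,
                          cx=np.clip((x1 + x2) / 2 / s, 0, 1),
                          cy=np.clip((y1 + y2) / 2 / s, 0, 1),
                          w=min((x2 - x1) / s, 1.0),
                          h=min((y2 - y1) / s, 1.0))
        records.append(rec)
    return np.clip(img, 0, 255).astype(np.uint8), records


def generate_dataset(cfg: SceneConfig, out_dir):
    """Render the full dataset; returns the manifest dict (also written as
    ``manifest.yaml``).  Pure function of (cfg, seed): byte-identical across
    runs."""
    out_dir = str(out_dir)
    img_dir = os.path.join(out_dir, "images")
    lab_dir = os.path.join(out_dir, "labels")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(lab_dir, exist_ok=True)
    splits = {"train": [], "val": [], "test": []}
    wh = []
    for i in range(cfg.n_images):
        img, records = render_scene(cfg, i)
        stem = f"img{i:06d}"
        Image.fromarray(img).save(os.path.join(img_dir, stem + ".png"))
        write_yolo_labels(os.path.join(lab_dir, stem + ".txt"), records)
        splits[split_of_index(i)].append(stem)
        wh.extend((r.w, r.h) for r in records)
    manifest = {
        "names": list(CLASS_NAMES),
        "nc": 3,
        "image_size": cfg.image_size,
        "image_dir": "images",
        "label_dir": "labels",
        "splits": splits,
        "seed": cfg.seed,
        "n_instances": len(wh),
        "wh_stats": [[round(float(w), 6), round(float(h), 6)] for w, h in wh],
    }
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


# ---------------------------------------------------------------------------
# photometric / geometric augmentation
# ---------------------------------------------------------------------------


def _to_hsv(img):
    return np.array(Image.fromarray(img).convert("HSV"))


def _from_hsv(hsv):
    return np.array(Image.fromarray(hsv, mode="HSV").convert("RGB"))


def augment(image, labels, ops, brightness=0.0, hue_deg=0.0, contrast=0.0,
            rescale=1.0):
    """Apply a subset of {brightness, hue, contrast, rescale}.

    Photometric ops leave labels untouched; a uniform rescale keeps the
    normalized labels unchanged (resize only).  Magnitudes: brightness
    and contrast are fractional shifts (default range +-0.25), hue is in
    degrees (default range +-10).
    """
    allowed = {"brightness", "hue", "contrast", "rescale"}
    if not set(ops) <= allowed:
        raise ValueError(f"unknown ops: {set(ops) - allowed}")
    img = np.asarray(image)
    out = img.astype(np.float64)
    if "brightness" in ops:
        out = out * (1.0 + brightness)
    if "contrast" in ops:
        mean = out.mean()
        out = mean + (out - mean) * (1.0 + contrast)
    out = np.clip(out, 0, 255).astype(np.uint8)
    if "hue" in ops and hue_deg != 0.0:
        hsv = _to_hsv(out)
        shift = int(round(hue_deg / 360.0 * 255.0))
        hsv[..., 0] = (hsv[..., 0].astype(int) + shift) % 255
        out = _from_hsv(hsv)
    if "rescale" in ops and rescale != 1.0:
        h, w = out.shape[:2]
        nh, nw = max(int(round(h * rescale)), 1), max(int(round(w * rescale)), 1)
        out = np.array(Image.fromarray(out).resize((nw, nh), Image.BILINEAR))
    return out, list(labels)


def letterbox(image, new_size, color=114):
    """Aspect-preserving resize with constant padding to a square.

    Returns (image', scale, (pad_x, pad_y)) for label re-projection.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    scale = min(new_size / h, new_size / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = np.array(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
    out = np.full((new_size, new_size, 3), color, dtype=np.uint8)
    pad_y = (new_size - nh) // 2
    pad_x = (new_size - nw) // 2
    out[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized
    return out, scale, (pad_x, pad_y)


def labels_to_letterbox(labels, orig_shape, new_size, scale, pad):
    """Re-project normalized labels into the letterboxed frame."""
    h, w = orig_shape[:2]
    pad_x, pad_y = pad
    out = []
    for r in labels:
        cx = (r.cx * w * scale + pad_x) / new_size
        cy = (r.cy * h * scale + pad_y) / new_size
        out.append(LabelRecord(r.class_id, cx, cy,
                               r.w * w * scale / new_size,
                               r.h * h * scale / new_size))
    return out


def labels_from_letterbox(labels, orig_shape, new_size, scale, pad):
    """Inverse of :func:`labels_to_letterbox` (round-trips to ~1e-6)."""
    h, w = orig_shape[:2]
    pad_x, pad_y = pad
    out = []
    for r in labels:
        cx = (r.cx * new_size - pad_x) / (w * scale)
        cy = (r.cy * new_size - pad_y) / (h * scale)
        out.append(LabelRecord(r.class_id, cx, cy,
                               r.w * new_size / (w * scale),
                               r.h * new_size / (h * scale)))
    return out
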