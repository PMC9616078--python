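"""Slide preprocessing: tissue masking, stain normalization, tiling, augmentation.

Tissue is separated from the near-white slide background by Otsu
thresholding of the HSV saturation channel.  Stain normalization maps each
color channel of a slide linearly so that its tissue-pixel mean and
standard deviation match target statistics derived from a training cohort:

    Z_c = (X_c - mu_c) / sigma_c * sigma_c^target + mu_c^target

Statistics are computed over tissue pixels only, but the transform is
applied to every pixel of the image; the three normalized channels are then
merged and clipped to [0, 255].

Tiling cuts the slide into a non-overlapping grid of P x P patches
(right/bottom remainders padded with background white), dropping patches
whose tissue fraction falls below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .core import SlideImage

__all__ = [
    "TissueMask",
    "ChannelStats",
    "Patch",
    "AugmentConfig",
    "extract_tissue_mask",
    "compute_channel_stats",
    "normalize_stain",
    "tile_slide",
    "reassemble_patches",
    "augment",
]

#: Pad value for out-of-slide patch area (background white).
_PAD_VALUE = 255


@dataclass
class TissueMask:
    """Boolean tissue raster aligned with its slide."""

    mask: np.ndarray
    degenerate: bool = False

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel (R, G, B) mean and standard deviation over tissue pixels."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]
    role: str = "source"  # "source" (one slide) or "target" (cohort average)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.mean, dtype=np.float64), np.asarray(self.std, dtype=np.float64)


@dataclass
class Patch:
    """One tile of the non-overlapping slide grid.

    Origins are 0-based, top-left, half-open: the patch covers
    ``[y0, y0+P) x [x0, x0+P)`` on the padded canvas.
    """

    slide_id: str
    row: int
    col: int
    x0: int
    y0: int
    image: np.ndarray
    tissue_fraction: float
    mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return self.image.shape[0]


def extract_tissue_mask(slide: SlideImage | np.ndarray, *, min_object_px: int = 64) -> TissueMask:
    """Segment tissue from background by Otsu thresholding of saturation.

    Near-white background has close to zero saturation while stained tissue
    is strongly chromatic, so the higher-saturation side of the Otsu split is
    tissue.  Connected components smaller than `min_object_px` are removed.
    A constant (single-valued) image yields an empty mask with a warning.
    """
    image = slide.image if isinstance(slide, SlideImage) else slide
    # HSV saturation, computed directly: S = 1 - min/max (0 for black pixels)
    img = image.astype(np.float32)
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-6), 0.0)
    if np.ptp(sat) < 1e-6:
        warnings.warn("degenerate single-valued image; returning empty tissue mask",
                      stacklevel=2)
        return TissueMask(np.zeros(sat.shape, dtype=bool), degenerate=True)
    thresh = threshold_otsu(sat)
    # background must be BOTH unsaturated and near-white (every channel
    # bright, i.e. the min channel is high); otherwise Otsu would split the
    # tissue's own saturation spread on slides with no background
    mask = ~((sat <= thresh) & (mn >= 230))
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return TissueMask(mask)


def _slide_stats(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    px = image[mask].astype(np.float64)
    if px.size == 0:
        raise ValueError("no tissue pixels under the mask")
    return px.mean(axis=0), px.std(axis=0)


def compute_channel_stats(slides, masks=None, role: str = "target") -> ChannelStats:
    """Per-channel tissue statistics.

    With ``role="source"`` exactly one slide is expected and its per-slide
    tissue mean/std are returned.  With ``role="target"`` the result is the
    arithmetic mean over slides of the per-slide means and stds — the
    normalization target a training cohort defines.
    """
    if isinstance(slides, (SlideImage, np.ndarray)):
        slides = [slides]
    if masks is None:
        masks = [extract_tissue_mask(s).mask for s in slides]
    elif isinstance(masks, (TissueMask, np.ndarray)):
        masks = [masks]
    masks = [m.mask if isinstance(m, TissueMask) else m for m in masks]
    if len(slides) != len(masks):
        raise ValueError("slides and masks must pair up")
    if role == "source" and len(slides) != 1:
        raise ValueError("source stats are per-slide; pass exactly one slide")
    means, stds = [], []
    for s, m in zip(slides, masks):
        image = s.image if isinstance(s, SlideImage) else s
        mu, sd = _slide_stats(image, m)
        means.append(mu)
        stds.append(sd)
    mean = np.mean(means, axis=0)
    std = np.mean(stds, axis=0)
    return ChannelStats(tuple(mean), tuple(std), role=role)


def normalize_stain(slide: SlideImage | np.ndarray,
                    mask: TissueMask | np.ndarray | None,
                    target: ChannelStats,
                    source: ChannelStats | None = None) -> np.ndarray:
    """Linearly map each channel to the target tissue mean/std.

    `source` statistics are computed from the slide's tissue pixels when not
    supplied.  The transform is applied to the whole image (all pixels) and
    the result is clipped to [0, 255] uint8.  A zero source standard
    deviation in any channel is a degenerate source and raises.
    """
    image = slide.image if isinstance(slide, SlideImage) else slide
    if source is None:
        if mask is None:
            mask = extract_tissue_mask(image)
        m = mask.mask if isinstance(mask, TissueMask) else mask
        mu, sd = _slide_stats(image, m)
        source = ChannelStats(tuple(mu), tuple(sd), role="source")
    mu, sd = source.as_arrays()
    if np.any(sd <= 0):
        raise ValueError("degenerate source: zero standard deviation in some channel")
    mu_t, sd_t = target.as_arrays()
    z = (image.astype(np.float64) - mu) / sd * sd_t + mu_t
    return np.clip(np.rint(z), 0, 255).astype(np.uint8)


def tile_slide(slide: SlideImage | np.ndarray,
               mask: TissueMask | np.ndarray | None = None,
               patch_size: int = 128,
               min_tissue_fraction: float = 0.05,
               label_mask: np.ndarray | None = None) -> list[Patch]:
    """Cut the slide into a non-overlapping P x P grid, row-major.

    The canvas is padded on the right/bottom with background white so its
    dimensions are multiples of P.  Patches whose tissue fraction is below
    `min_tissue_fraction` are dropped.  When `label_mask` is given, each
    patch carries its aligned label-mask crop (padded with 0).
    """
    if patch_size < 16:
        raise ValueError("patch_size must be >= 16")
    image = slide.image if isinstance(slide, SlideImage) else slide
    slide_id = slide.slide_id if isinstance(slide, SlideImage) else ""
    if label_mask is None and isinstance(slide, SlideImage):
        label_mask = slide.mask
    if mask is None:
        mask = extract_tissue_mask(image)
    tmask = mask.mask if isinstance(mask, TissueMask) else mask

    h, w = image.shape[:2]
    p = patch_size
    nrows, ncols = -(-h // p), -(-w // p)
    ph, pw = nrows * p, ncols * p
    canvas = np.full((ph, pw, 3), _PAD_VALUE, dtype=image.dtype)
    canvas[:h, :w] = image
    tcanvas = np.zeros((ph, pw), dtype=bool)
    tcanvas[:h, :w] = tmask
    lcanvas = None
    if label_mask is not None:
        lcanvas = np.zeros((ph, pw), dtype=label_mask.dtype)
        lcanvas[:h, :w] = label_mask

    patches = []
    for r in range(nrows):
        for c in range(ncols):
            y0, x0 = r * p, c * p
            tf = float(tcanvas[y0:y0 + p, x0:x0 + p].mean())
            if tf < min_tissue_fraction:
                continue
            patches.append(Patch(
                slide_id, r, c, x0, y0,
                image=canvas[y0:y0 + p, x0:x0 + p].copy(),
                tissue_fraction=tf,
                mask=None if lcanvas is None else lcanvas[y0:y0 + p, x0:x0 + p].copy(),
            ))
    return patches


def reassemble_patches(patches: list[Patch], canvas_shape: tuple[int, int],
                       fill: int = _PAD_VALUE) -> np.ndarray:
    """Inverse of :func:`tile_slide` on the padded canvas (pixel-exact where
    patches survived; `fill` elsewhere)."""
    h, w = canvas_shape
    out = np.full((h, w, 3), fill, dtype=np.uint8)
    for pt in patches:
        out[pt.y0:pt.y0 + pt.size, pt.x0:pt.x0 + pt.size] = pt.image
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Seeded augmentation recipe applied to training patches.

    Spatial transforms (flips, 90-degree rotations, random erasing) are
    applied identically to the patch's label-mask crop so training pairs
    stay aligned; color jitter touches the image only.
    """

    hflip_prob: float = 0.0
    vflip_prob: float = 0.0
    rot90: bool = False
    erase_prob: float = 0.0
    erase_area: tuple[float, float] = (0.1, 0.2)
    brightness: float = 0.0   # multiplicative jitter half-range, e.g. 0.1 -> [0.9, 1.1]
    saturation: float = 0.0
    contrast: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.hflip_prob, self.vflip_prob, self.erase_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.erase_area
        if not 0 <= lo <= hi <= 1:
            raise ValueError("erase_area must be an ordered sub-range of [0, 1]")
        for j in (self.brightness, self.saturation, self.contrast):
            if not np.isfinite(j) or j < 0:
                raise ValueError("jitter ranges must be finite and >= 0")


def augment(patch: Patch, cfg: AugmentConfig,
            rng: np.random.Generator | None = None) -> Patch:
    """Apply the configured augmentations; deterministic for a fixed seed."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img = patch.image.astype(np.float64)
    msk = None if patch.mask is None else patch.mask.copy()

    if cfg.hflip_prob and rng.random() < cfg.hflip_prob:
        img = img[:, ::-1]
        msk = None if msk is None else msk[:, ::-1]
    if cfg.vflip_prob and rng.random() < cfg.vflip_prob:
        img = img[::-1]
        msk = None if msk is None else msk[::-1]
    if cfg.rot90:
        k = int(rng.integers(0, 4))
        img = np.rot90(img, k)
        msk = None if msk is None else np.rot90(msk, k)
    if cfg.erase_prob and rng.random() < cfg.erase_prob:
        p = img.shape[0]
        area = rng.uniform(*cfg.erase_area) * p * p
        aspect = rng.uniform(0.5, 2.0)
        eh = min(p, max(1, int(round(np.sqrt(area * aspect)))))
        ew = min(p, max(1, int(round(area / eh))))
        y = int(rng.integers(0, p - eh + 1))
        x = int(rng.integers(0, p - ew + 1))
        img[y:y + eh, x:x + ew] = rng.uniform(0, 255, size=(eh, ew, 3))
        if msk is not None:
            msk[y:y + eh, x:x + ew] = 0
    if cfg.brightness:
        img = img * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    if cfg.saturation:
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (img - gray) * rng.uniform(1 - cfg.saturation, 1 + cfg.saturation)
    if cfg.contrast:
        mean = img.mean()
        img = mean + (img - mean) * rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return replace(patch, image=np.ascontiguousarray(out),
                   mask=None if msk is None else np.ascontiguousarray(msk))
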