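"""Patch segmenter: a small V-Net-style encoder-decoder trained with dice loss.

The network locates abnormal tissue (LGD, HGD or IIN — a single "abnormal"
foreground) in P x P RGB patches and doubles as the feature extractor for
the slide graph: the global-average-pooled bottleneck activation is the
patch's feature vector.

Desk-scale default: 3 resolution levels, base width 8, feature dimension
d = 32, patch size 128.  Everything runs in float32 NumPy on one CPU and is
deterministic for a fixed training seed.

Layer plan (width w, P divisible by 4).  Skip connections are additive
through 1x1 channel projections, which keeps the decoder cheap enough for
single-CPU training::

    enc1  conv3x3(3 -> w)     ReLU            P
    pool  2x2 max                             P/2
    enc2  conv3x3(w -> 2w)    ReLU            P/2
    pool  2x2 max                             P/4
    bott  conv3x3(2w -> 4w)   ReLU            P/4   -- GAP -> feature (d = 4w)
    up    nearest x2; proj2 conv1x1(4w -> 2w) + enc2
    dec2  conv3x3(2w -> 2w)   ReLU            P/2
    up    nearest x2; proj1 conv1x1(2w -> w) + enc1
    dec1  conv3x3(w -> w)     ReLU            P
    head  conv1x1(w -> 1)     sigmoid         P
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import Patch

__all__ = [
    "SegTrainConfig",
    "SegModelState",
    "dice_loss",
    "binarize_abnormal",
    "train_segmenter",
    "infer_patch",
    "infer_patches",
    "stitch_probability_map",
]

_EPS = 1e-6  # soft-dice stabilizer


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = _EPS) -> float:
    """Soft dice loss ``1 - 2*sum(p*g) / (sum(p^2) + sum(g^2) + eps)``.

    `pred` holds probabilities in [0, 1]; `target` is binary.  Returns a
    value in [0, 1]: 0 for perfect binary overlap, 1 for disjoint rasters.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.size == 0:
        raise ValueError("empty rasters")
    inter = float((pred * target).sum())
    denom = float((pred * pred).sum() + (target * target).sum()) + eps
    return 1.0 - 2.0 * inter / denom


def binarize_abnormal(label_mask: np.ndarray) -> np.ndarray:
    """Collapse a 0-4 label mask to the binary abnormal target (labels 2-4)."""
    return (np.asarray(label_mask) >= 2).astype(np.float32)


@dataclass(frozen=True)
class SegTrainConfig:
    """Adam / soft-dice training recipe for the patch segmenter."""

    learning_rate: float = 1e-3
    epochs: int = 8
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class SegModelState:
    """Trained segmenter: architecture descriptor + parameter blob."""

    patch_size: int
    width: int
    params: dict[str, np.ndarray]
    seed: int = 0
    version: str = "1"
    loss_trace: list[float] = field(default_factory=list)

    @property
    def feature_dim(self) -> int:
        return 4 * self.width

    def save(self, path: str | Path) -> None:
        """Write the parameter blob (.npz) plus a JSON sidecar."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, **self.params)
        sidecar = {"patch_size": self.patch_size, "width": self.width,
                   "seed": self.seed, "version": self.version,
                   "loss_trace": self.loss_trace}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "SegModelState":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path) as blob:
            params = {k: blob[k] for k in blob.files}
        return cls(meta["patch_size"], meta["width"], params, meta["seed"],
                   meta["version"], meta["loss_trace"])


def _init_params(width: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    w = width
    shapes = {
        "enc1": (3, 3, 3, w),
        "enc2": (3, 3, w, 2 * w),
        "bott": (3, 3, 2 * w, 4 * w),
        "proj2": (1, 1, 4 * w, 2 * w),
        "dec2": (3, 3, 2 * w, 2 * w),
        "proj1": (1, 1, 2 * w, w),
        "dec1": (3, 3, w, w),
        "head": (1, 1, w, 1),
    }
    params: dict[str, np.ndarray] = {}
    for name, shp in shapes.items():
        fan_in = shp[0] * shp[1] * shp[2]
        fan_out = shp[0] * shp[1] * shp[3]
        params[f"{name}_w"] = nn.glorot(rng, shp, fan_in, fan_out)
        params[f"{name}_b"] = np.zeros(shp[3], dtype=np.float32)
    params["head_b"] += np.float32(-1.0)  # background prior at initialisation
    return params


def _prep(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32) / 255.0 - 0.5
    if x.ndim == 3:
        x = x[None]
    return x


def _forward(params: dict[str, np.ndarray], x: np.ndarray, *, want_cache: bool):
    """Full forward pass; returns (probs, features, cache-or-None)."""
    a1, c1 = nn.conv2d_forward(x, params["enc1_w"], params["enc1_b"])
    a1 = nn.relu(a1)
    p1, m1 = nn.maxpool2_forward(a1)
    a2, c2 = nn.conv2d_forward(p1, params["enc2_w"], params["enc2_b"])
    a2 = nn.relu(a2)
    p2, m2 = nn.maxpool2_forward(a2)
    a3, c3 = nn.conv2d_forward(p2, params["bott_w"], params["bott_b"])
    a3 = nn.relu(a3)
    feats = a3.mean(axis=(1, 2))  # global average pool -> (N, 4w)

    s2, cp2 = nn.conv2d_forward(nn.upsample2_forward(a3), params["proj2_w"], params["proj2_b"])
    u2 = s2 + a2
    a4, c4 = nn.conv2d_forward(u2, params["dec2_w"], params["dec2_b"])
    a4 = nn.relu(a4)
    s1, cp1 = nn.conv2d_forward(nn.upsample2_forward(a4), params["proj1_w"], params["proj1_b"])
    u1 = s1 + a1
    a5, c5 = nn.conv2d_forward(u1, params["dec1_w"], params["dec1_b"])
    a5 = nn.relu(a5)
    z, c6 = nn.conv2d_forward(a5, params["head_w"], params["head_b"])
    probs = nn.sigmoid(z[..., 0])

    cache = (a1, m1, a2, m2, a3, a4, a5,
             c1, c2, c3, cp2, c4, cp1, c5, c6) if want_cache else None
    return probs, feats, cache


def _backward(params, cache, dprobs, probs) -> dict[str, np.ndarray]:
    a1, m1, a2, m2, a3, a4, a5, c1, c2, c3, cp2, c4, cp1, c5, c6 = cache
    grads: dict[str, np.ndarray] = {}
    dz = (dprobs * probs * (1.0 - probs))[..., None].astype(np.float32)
    da5, grads["head_w"], grads["head_b"] = nn.conv2d_backward(dz, params["head_w"], c6)
    da5 = nn.relu_backward(da5, a5)
    du1, grads["dec1_w"], grads["dec1_b"] = nn.conv2d_backward(da5, params["dec1_w"], c5)
    da1 = du1  # additive skip: gradient flows to both enc1 and the projection
    ds1, grads["proj1_w"], grads["proj1_b"] = nn.conv2d_backward(du1, params["proj1_w"], cp1)
    da4 = nn.upsample2_backward(ds1)
    da4 = nn.relu_backward(da4, a4)
    du2, grads["dec2_w"], grads["dec2_b"] = nn.conv2d_backward(da4, params["dec2_w"], c4)
    da2 = du2
    ds2, grads["proj2_w"], grads["proj2_b"] = nn.conv2d_backward(du2, params["proj2_w"], cp2)
    da3 = nn.upsample2_backward(ds2)
    da3 = nn.relu_backward(da3, a3)
    dp2, grads["bott_w"], grads["bott_b"] = nn.conv2d_backward(da3, params["bott_w"], c3)
    da2 = da2 + nn.maxpool2_backward(dp2, m2)
    da2 = nn.relu_backward(da2, a2)
    dp1, grads["enc2_w"], grads["enc2_b"] = nn.conv2d_backward(da2, params["enc2_w"], c2)
    da1 = da1 + nn.maxpool2_backward(dp1, m1)
    da1 = nn.relu_backward(da1, a1)
    _, grads["enc1_w"], grads["enc1_b"] = nn.conv2d_backward(da1, params["enc1_w"], c1)
    return grads


def _soft_dice_grad(p: np.ndarray, g: np.ndarray):
    inter = (p * g).sum()
    denom = (p * p).sum() + (g * g).sum() + _EPS
    loss = 1.0 - 2.0 * inter / denom
    dp = -(2.0 * g * denom - 4.0 * inter * p) / (denom * denom)
    return loss, dp


def _batch_dice_grad(probs: np.ndarray, targets: np.ndarray):
    """Two-class (abnormal + background) batch soft dice and its gradient.

    Averaging the foreground and background dice terms keeps gradients
    informative on batches without any abnormal pixel, where the foreground
    term alone is flat at 1.
    """
    p = probs.astype(np.float64)
    g = targets.astype(np.float64)
    l_fg, d_fg = _soft_dice_grad(p, g)
    l_bg, d_bg = _soft_dice_grad(1.0 - p, 1.0 - g)
    return 0.5 * float(l_fg + l_bg), 0.5 * (d_fg - d_bg)


def train_segmenter(pairs, cfg: SegTrainConfig = SegTrainConfig(), *,
                    width: int = 8) -> SegModelState:
    """Train the segmenter on (image, binary-abnormal-mask) pairs.

    `pairs` is a sequence of ``(uint8 P x P x 3 image, binary P x P mask)``
    tuples or :class:`~gastrograph.preprocess.Patch` objects carrying label
    masks (binarized here).  Soft dice is computed per batch; two runs with
    the same seed produce identical parameter blobs.
    """
    images, targets = [], []
    for item in pairs:
        if isinstance(item, Patch):
            if item.mask is None:
                raise ValueError(f"patch {item.slide_id}({item.row},{item.col}) "
                                 "has no label mask")
            images.append(item.image)
            targets.append(binarize_abnormal(item.mask))
        else:
            img, msk = item
            images.append(np.asarray(img))
            targets.append(np.asarray(msk, dtype=np.float32))
    if not images:
        raise ValueError("empty training set")
    x_all = _prep(np.stack(images))
    g_all = np.stack(targets)
    p = x_all.shape[1]
    if p % 4 != 0:
        raise ValueError("patch size must be divisible by 4")

    params = _init_params(width, cfg.seed)
    opt = nn.Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(images)
    trace = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs, _, cache = _forward(params, x_all[idx], want_cache=True)
            loss, dprobs = _batch_dice_grad(probs, g_all[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; aborting")
            grads = _backward(params, cache, dprobs, probs)
            opt.step(grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return SegModelState(p, width, params, seed=cfg.seed, loss_trace=trace)


def infer_patches(model: SegModelState, images, *, batch_size: int = 8):
    """Probability maps and bottleneck features for a stack of patches.

    Returns ``(probs (N, P, P) float32, features (N, d) float32)``.  A pure
    function of (model state, pixels): identical inputs give identical
    outputs.
    """
    arr = np.stack([im.image if isinstance(im, Patch) else np.asarray(im)
                    for im in images])
    if arr.shape[1] != model.patch_size or arr.shape[2] != model.patch_size:
        raise ValueError(f"patch size {arr.shape[1:3]} does not match model "
                         f"({model.patch_size})")
    probs_out = np.empty(arr.shape[:3], dtype=np.float32)
    feats_out = np.empty((arr.shape[0], model.feature_dim), dtype=np.float32)
    for start in range(0, arr.shape[0], batch_size):
        x = _prep(arr[start:start + batch_size])
        probs, feats, _ = _forward(model.params, x, want_cache=False)
        probs_out[start:start + batch_size] = probs
        feats_out[start:start + batch_size] = feats
    return probs_out, feats_out


def infer_patch(model: SegModelState, patch) -> tuple[np.ndarray, np.ndarray]:
    """Single-patch convenience wrapper around :func:`infer_patches`."""
    probs, feats = infer_patches(model, [patch])
    return probs[0], feats[0]


def save_probability_map_png(prob_map: np.ndarray, path) -> None:
    """Export a probability map as 16-bit grayscale PNG (pixel/65535 = p)."""
    from PIL import Image
    arr = np.clip(np.asarray(prob_map, dtype=np.float64), 0, 1)
    Image.fromarray(np.rint(arr * 65535).astype(np.uint16)).save(path)


def load_probability_map_png(path) -> np.ndarray:
    from PIL import Image
    return np.asarray(Image.open(path), dtype=np.float64) / 65535.0


def stitch_probability_map(maps, patches: list[Patch],
                           canvas_shape: tuple[int, int]) -> np.ndarray:
    """Place per-patch probability maps back onto the padded slide canvas.

    Grid cells whose patches were dropped during tiling stay 0 (negligible
    tissue contributes no abnormality).  Values are copied exactly — no
    blending.  Overlapping or out-of-canvas patches raise.
    """
    h, w = canvas_shape
    out = np.zeros((h, w), dtype=np.float32)
    seen = np.zeros((h, w), dtype=bool)
    for pm, pt in zip(maps, patches):
        pm = np.asarray(pm)
        p = pm.shape[0]
        if pm.shape != (p, p) or pt.y0 % p or pt.x0 % p:
            raise ValueError("patches must sit on the non-overlapping grid")
        if pt.y0 + p > h or pt.x0 + p > w:
            raise ValueError("patch extends outside the canvas")
        if seen[pt.y0:pt.y0 + p, pt.x0:pt.x0 + p].any():
            raise ValueError("overlapping patches")
        out[pt.y0:pt.y0 + p, pt.x0:pt.x0 + p] = pm
        seen[pt.y0:pt.y0 + p, pt.x0:pt.x0 + p] = True
    return out
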