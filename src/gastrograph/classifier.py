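"""Slide-level GCN classifier and the two clinical output modes.

A two-layer graph convolutional network aggregates the node features of a
slide graph (bottleneck feature vector plus abnormality grade per node)
through the stored adjacency, mean-pools over nodes, and emits four-tier
probabilities (p_NED, p_LGD, p_HGD, p_IIN) that sum to 1.  Training uses
focal loss, Adam, and per-class balance weights.

Two output modes mirror clinical use:

* **Four-tier classification** — argmax of the simplex, exact ties resolved
  toward the more severe category so malignancy is never under-called.
* **NED screening** — slides with p_NED strictly greater than a threshold t
  are screened out as benign.  t is calibrated as the maximum p_NED over
  the positive (LGD/HGD/IIN) slides of a calibration set, which makes the
  100% sensitivity / 100% NPV guarantee on that set structural: no
  positive slide can exceed t, and among thresholds with the guarantee this
  t screens out the most benign slides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .core import CATEGORIES, POSITIVE_CATEGORIES, category_index
from .graphs import SlideGraph

__all__ = [
    "FourTierProbs",
    "GcnTrainConfig",
    "GcnModelState",
    "ScreeningConfig",
    "focal_loss",
    "train_gcn",
    "predict_four_tier",
    "classify_four_tier",
    "calibrate_screening_threshold",
    "screen_slide",
]

_PT_FLOOR = 1e-12  # floor under the focal-loss logarithm


@dataclass(frozen=True)
class FourTierProbs:
    """Per-slide category probabilities; a simplex over (NED, LGD, HGD, IIN)."""

    p_ned: float
    p_lgd: float
    p_hgd: float
    p_iin: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(arr.sum()) - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1 (got {arr.sum():.8f})")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_ned, self.p_lgd, self.p_hgd, self.p_iin], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FourTierProbs":
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class GcnTrainConfig:
    """Adam / focal-loss training recipe for the GCN."""

    learning_rate: float = 1e-3
    epochs: int = 60
    seed: int = 0
    focal_gamma: float = 2.0
    class_weights: tuple[float, float, float, float] | None = None  # None -> 1/freq
    hidden_dim: int = 32

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.class_weights is not None and any(a <= 0 for a in self.class_weights):
            raise ValueError("class weights must be > 0")


@dataclass
class GcnModelState:
    """Trained GCN: parameters plus the input standardisation constants."""

    in_dim: int
    hidden_dim: int
    params: dict[str, np.ndarray]
    feat_mean: np.ndarray
    feat_std: np.ndarray
    seed: int = 0
    version: str = "1"
    loss_trace: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, feat_mean=self.feat_mean, feat_std=self.feat_std, **self.params)
        meta = {"in_dim": self.in_dim, "hidden_dim": self.hidden_dim,
                "seed": self.seed, "version": self.version, "loss_trace": self.loss_trace}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "GcnModelState":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path) as blob:
            arrays = {k: blob[k] for k in blob.files}
        feat_mean = arrays.pop("feat_mean")
        feat_std = arrays.pop("feat_std")
        return cls(meta["in_dim"], meta["hidden_dim"], arrays, feat_mean, feat_std,
                   meta["seed"], meta["version"], meta["loss_trace"])


def focal_loss(probs: FourTierProbs | np.ndarray, true_class: str | int,
               gamma: float = 2.0, alpha: float = 1.0) -> float:
    """Focal loss ``-alpha * (1 - p_t)**gamma * ln(p_t)`` for one slide.

    ``p_t`` is the predicted probability of the true class, floored at
    1e-12 before the logarithm.  gamma = 0, alpha = 1 reduces to plain
    cross-entropy.
    """
    arr = probs.as_array() if isinstance(probs, FourTierProbs) else np.asarray(probs, dtype=np.float64)
    idx = category_index(true_class) if isinstance(true_class, str) else int(true_class)
    if not 0 <= idx < len(CATEGORIES):
        raise ValueError(f"invalid class index {idx}")
    pt = float(arr[idx])
    return float(-alpha * (1.0 - pt) ** gamma * np.log(max(pt, _PT_FLOOR)))


# ---------------------------------------------------------------------------
# GCN forward / backward
# ---------------------------------------------------------------------------

def _norm_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2} (zero-degree safe)."""
    a = adj.astype(np.float64)
    deg = a.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
    return a * dinv[:, None] * dinv[None, :]


def _graph_inputs(graph: SlideGraph, feat_mean: np.ndarray, feat_std: np.ndarray) -> np.ndarray:
    """Node matrix: standardized bottleneck features ++ abnormality grade."""
    x = graph.features.astype(np.float64)
    x = (x - feat_mean) / feat_std
    return np.concatenate([x, graph.grades[:, None]], axis=1)


def _gcn_forward(params, x: np.ndarray, ahat: np.ndarray):
    m1 = ahat @ x
    h1 = nn.relu(m1 @ params["w1"] + params["b1"])
    m2 = ahat @ h1
    h2 = nn.relu(m2 @ params["w2"] + params["b2"])
    pooled = h2.mean(axis=0)
    logits = pooled @ params["w3"] + params["b3"]
    probs = nn.softmax(logits[None, :])[0]
    return probs, (x, m1, h1, m2, h2, pooled)


def _focal_dlogits(probs: np.ndarray, idx: int, gamma: float, alpha: float) -> np.ndarray:
    pt = max(float(probs[idx]), _PT_FLOOR)
    one_m = 1.0 - pt
    dl_dpt = -alpha * (-gamma * one_m ** max(gamma - 1.0, 0.0) * np.log(pt)
                       + one_m ** gamma / pt) if gamma > 0 else -alpha / pt
    onehot = np.zeros_like(probs)
    onehot[idx] = 1.0
    return dl_dpt * pt * (onehot - probs)


def train_gcn(graphs: list[SlideGraph], labels: list[str] | None = None,
              cfg: GcnTrainConfig = GcnTrainConfig()) -> GcnModelState:
    """Train the GCN on slide graphs with four-tier labels.

    Labels default to each graph's own ``label`` attribute.  Class-balance
    weights default to inverse class frequency (normalized to mean 1).
    Deterministic for a fixed seed.
    """
    if labels is None:
        labels = [g.label for g in graphs]
    if not graphs or len(labels) != len(graphs):
        raise ValueError("need one label per graph")
    idxs = [category_index(lb) for lb in labels]

    all_feats = np.concatenate([g.features for g in graphs]).astype(np.float64)
    feat_mean = all_feats.mean(axis=0)
    feat_std = np.maximum(all_feats.std(axis=0), 1e-6)

    if cfg.class_weights is not None:
        alpha = np.asarray(cfg.class_weights, dtype=np.float64)
    else:
        counts = np.bincount(idxs, minlength=4).astype(np.float64)
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        alpha = np.where(counts > 0, inv / inv[counts > 0].mean(), 1.0)

    in_dim = all_feats.shape[1] + 1
    hid = cfg.hidden_dim
    rng = np.random.default_rng(cfg.seed)
    params = {
        "w1": nn.glorot(rng, (in_dim, hid), in_dim, hid).astype(np.float64),
        "b1": np.zeros(hid),
        "w2": nn.glorot(rng, (hid, hid), hid, hid).astype(np.float64),
        "b2": np.zeros(hid),
        "w3": nn.glorot(rng, (hid, 4), hid, 4).astype(np.float64),
        "b3": np.zeros(4),
    }
    opt = nn.Adam(params, lr=cfg.learning_rate)

    inputs = [_graph_inputs(g, feat_mean, feat_std) for g in graphs]
    ahats = [_norm_adjacency(g.adjacency) for g in graphs]

    trace = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(graphs))
        losses = []
        for gi in order:
            x, ahat, idx = inputs[gi], ahats[gi], idxs[gi]
            probs, cache = _gcn_forward(params, x, ahat)
            loss = focal_loss(probs, idx, cfg.focal_gamma, float(alpha[idx]))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite GCN training loss; aborting")
            dlogits = _focal_dlogits(probs, idx, cfg.focal_gamma, float(alpha[idx]))

            xg, m1, h1, m2, h2, pooled = cache
            n = x.shape[0]
            grads = {"w3": np.outer(pooled, dlogits), "b3": dlogits}
            dh2 = np.tile((params["w3"] @ dlogits) / n, (n, 1))
            dpre2 = dh2 * (h2 > 0)
            grads["w2"] = m2.T @ dpre2
            grads["b2"] = dpre2.sum(axis=0)
            dh1 = ahat @ (dpre2 @ params["w2"].T)   # ahat is symmetric
            dpre1 = dh1 * (h1 > 0)
            grads["w1"] = m1.T @ dpre1
            grads["b1"] = dpre1.sum(axis=0)
            opt.step(grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return GcnModelState(in_dim, hid, params, feat_mean, feat_std,
                         seed=cfg.seed, loss_trace=trace)


def predict_four_tier(model: GcnModelState, graph: SlideGraph) -> FourTierProbs:
    """Four-tier probability simplex for one slide graph."""
    x = _graph_inputs(graph, model.feat_mean, model.feat_std)
    if x.shape[1] != model.in_dim:
        raise ValueError(f"feature dimension {x.shape[1]} does not match model "
                         f"({model.in_dim})")
    probs, _ = _gcn_forward(model.params, x, _norm_adjacency(graph.adjacency))
    probs = probs / probs.sum()  # renormalize away float round-off
    return FourTierProbs.from_array(probs)


def classify_four_tier(probs: FourTierProbs) -> str:
    """Argmax category; exact ties resolve toward the more severe category."""
    arr = probs.as_array()
    best = len(arr) - 1 - int(np.argmax(arr[::-1]))  # first max scanning IIN -> NED
    return CATEGORIES[best]


# ---------------------------------------------------------------------------
# NED-screening mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningConfig:
    """Calibrated screening threshold t plus calibration metadata."""

    threshold: float
    calibration_set: str = ""
    n_positives: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"t": self.threshold,
                                          "calibration_set": self.calibration_set,
                                          "n_positives": self.n_positives}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreeningConfig":
        d = json.loads(Path(path).read_text())
        return cls(d["t"], d.get("calibration_set", ""), d.get("n_positives", 0))


def calibrate_screening_threshold(p_ned: np.ndarray, is_positive: np.ndarray,
                                  *, calibration_set: str = "") -> ScreeningConfig:
    """Set t to the maximum p_NED over positive slides.

    Under the rule "benign iff p_NED > t" no positive slide can then be
    screened out, so sensitivity and NPV on the calibration set are exactly
    100% whatever the model quality; among thresholds with that guarantee
    this is the smallest, hence it screens out the most benign slides.
    Refuses to calibrate without at least one positive slide.
    """
    p_ned = np.asarray(p_ned, dtype=np.float64)
    is_positive = np.asarray(is_positive, dtype=bool)
    if p_ned.shape != is_positive.shape:
        raise ValueError("p_ned and is_positive must align")
    if not is_positive.any():
        raise ValueError("calibration requires at least one positive slide; "
                         "t is undefined otherwise")
    if np.any(p_ned < 0) or np.any(p_ned > 1):
        raise ValueError("p_NED values must lie in [0, 1]")
    t = float(p_ned[is_positive].max())
    return ScreeningConfig(t, calibration_set=calibration_set,
                           n_positives=int(is_positive.sum()))


def screen_slide(probs: FourTierProbs | float, cfg: ScreeningConfig) -> str:
    """Screening decision: ``"benign-screened-out"`` iff p_NED > t (strict),
    else ``"retained-for-review"``."""
    p = probs.p_ned if isinstance(probs, FourTierProbs) else float(probs)
    return "benign-screened-out" if p > cfg.threshold else "retained-for-review"


def is_positive_category(category: str) -> bool:
    return category in POSITIVE_CATEGORIES
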