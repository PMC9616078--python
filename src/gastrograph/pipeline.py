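"""End-to-end slide pipeline: preprocess -> segment -> graph -> classify.

Wires the stages together the way the system is used clinically:

1. tissue masking and stain normalization to cohort target statistics,
2. tiling into patches and binary abnormality segmentation per patch,
3. per-slide graph over the top-n discriminative patches,
4. GCN four-tier probabilities, plus the calibrated NED-screening mode.

`train_pipeline` fits the whole stack on labelled slides; `predict_slides`
emits the per-slide prediction table the evaluation battery consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (FourTierProbs, GcnModelState, GcnTrainConfig, ScreeningConfig,
                         calibrate_screening_threshold, classify_four_tier,
                         predict_four_tier, screen_slide, train_gcn)
from .core import POSITIVE_CATEGORIES, SlideImage
from .graphs import GraphConfig, SlideGraph, graph_from_patch_outputs
from .preprocess import (ChannelStats, compute_channel_stats, extract_tissue_mask,
                         normalize_stain, tile_slide)
from .segmentation import (SegModelState, SegTrainConfig, binarize_abnormal,
                           infer_patches, stitch_probability_map, train_segmenter)

__all__ = ["PipelineConfig", "PipelineModel", "train_pipeline", "build_slide_graph",
           "predict_slides", "calibrate_pipeline", "slide_probability_map"]


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale defaults for the full stack."""

    patch_size: int = 128
    min_tissue_fraction: float = 0.05
    normalize: bool = True
    seg_width: int = 8
    seg: SegTrainConfig = field(default_factory=SegTrainConfig)
    max_seg_patches: int = 256
    graph: GraphConfig = field(default_factory=GraphConfig)
    gcn: GcnTrainConfig = field(default_factory=GcnTrainConfig)
    seed: int = 0


@dataclass
class PipelineModel:
    """Everything needed to classify a new slide."""

    seg_state: SegModelState
    gcn_state: GcnModelState
    target_stats: ChannelStats | None
    config: PipelineConfig
    screening: ScreeningConfig | None = None

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.seg_state.save(out / "segmenter.npz")
        self.gcn_state.save(out / "gcn.npz")
        meta = {
            "patch_size": self.config.patch_size,
            "min_tissue_fraction": self.config.min_tissue_fraction,
            "normalize": self.config.normalize,
            "graph": {"n_nodes": self.config.graph.n_nodes,
                      "gamma": self.config.graph.gamma,
                      "auto_percentile": self.config.graph.auto_percentile,
                      "add_self_loops": self.config.graph.add_self_loops},
            "target_stats": None if self.target_stats is None else
                {"mean": list(self.target_stats.mean), "std": list(self.target_stats.std)},
        }
        (out / "pipeline.json").write_text(json.dumps(meta))
        if self.screening is not None:
            self.screening.to_json(out / "screening.json")

    @classmethod
    def load(cls, out_dir: str | Path) -> "PipelineModel":
        out = Path(out_dir)
        meta = json.loads((out / "pipeline.json").read_text())
        gamma = meta["graph"]["gamma"]
        cfg = PipelineConfig(
            patch_size=meta["patch_size"],
            min_tissue_fraction=meta["min_tissue_fraction"],
            normalize=meta["normalize"],
            graph=GraphConfig(meta["graph"]["n_nodes"], gamma,
                              meta["graph"]["auto_percentile"],
                              meta["graph"]["add_self_loops"]),
        )
        ts = meta["target_stats"]
        target = None if ts is None else ChannelStats(tuple(ts["mean"]), tuple(ts["std"]), "target")
        screening = None
        if (out / "screening.json").exists():
            screening = ScreeningConfig.from_json(out / "screening.json")
        return cls(SegModelState.load(out / "segmenter.npz"),
                   GcnModelState.load(out / "gcn.npz"), target, cfg, screening)


def _prepared_patches(slide: SlideImage, target: ChannelStats | None, cfg: PipelineConfig,
                      tissue=None):
    """Tissue-mask, normalize, and tile one slide (label crops included when
    the slide carries a mask).  Falls back to threshold 0 if no patch
    clears the tissue cut, so every slide yields at least one patch."""
    if tissue is None:
        tissue = extract_tissue_mask(slide.image)
    image = slide.image
    if cfg.normalize and target is not None and not tissue.degenerate:
        image = normalize_stain(image, tissue, target)
    patches = tile_slide(image, tissue, cfg.patch_size, cfg.min_tissue_fraction,
                         label_mask=slide.mask)
    if not patches:
        patches = tile_slide(image, tissue, cfg.patch_size, 0.0, label_mask=slide.mask)
    for pt in patches:
        pt.slide_id = slide.slide_id
    return patches


def _sample_training_patches(patches_per_slide, cfg: PipelineConfig):
    """Balanced patch sample for segmenter training: lesion-bearing patches
    and plain-tissue patches in roughly equal numbers, capped at
    `max_seg_patches`."""
    rng = np.random.default_rng(cfg.seed)
    lesion, plain = [], []
    for patches in patches_per_slide:
        for pt in patches:
            if pt.mask is None:
                raise ValueError(f"slide {pt.slide_id} has no label mask; cannot "
                                 "train the segmenter")
            (lesion if (pt.mask >= 2).any() else plain).append(pt)
    half = cfg.max_seg_patches // 2
    take_l = min(len(lesion), half)
    take_p = min(len(plain), cfg.max_seg_patches - take_l)
    chosen = ([lesion[i] for i in rng.choice(len(lesion), take_l, replace=False)] if lesion else []) \
        + ([plain[i] for i in rng.choice(len(plain), take_p, replace=False)] if plain else [])
    rng.shuffle(chosen)
    return [(pt.image, binarize_abnormal(pt.mask)) for pt in chosen]


def build_slide_graph(seg_state: SegModelState, slide: SlideImage,
                      target: ChannelStats | None, cfg: PipelineConfig) -> SlideGraph:
    """Run preprocessing + segmentation on one slide and build its graph."""
    patches = _prepared_patches(slide, target, cfg)
    probs, feats = infer_patches(seg_state, patches)
    return graph_from_patch_outputs(probs, feats, patches, cfg.graph,
                                    slide_id=slide.slide_id, label=slide.category)


def slide_probability_map(seg_state: SegModelState, slide: SlideImage,
                          target: ChannelStats | None, cfg: PipelineConfig) -> np.ndarray:
    """Stitched slide-level abnormality probability map (padded canvas)."""
    patches = _prepared_patches(slide, target, cfg)
    probs, _ = infer_patches(seg_state, patches)
    p = cfg.patch_size
    h, w = slide.shape
    canvas = (-(-h // p) * p, -(-w // p) * p)
    return stitch_probability_map(list(probs), patches, canvas)


def train_pipeline(train_slides: list[SlideImage],
                   cfg: PipelineConfig = PipelineConfig()) -> PipelineModel:
    """Fit normalization target, segmenter and GCN on labelled slides."""
    if not train_slides:
        raise ValueError("no training slides")
    tissue_masks = [extract_tissue_mask(s.image) for s in train_slides]
    target = None
    if cfg.normalize:
        target = compute_channel_stats([s.image for s in train_slides],
                                       [m.mask for m in tissue_masks], role="target")

    # one prepared-patch pass per slide, reused for segmenter sampling and graphs
    patches_per_slide = [_prepared_patches(s, target, cfg, tissue=m)
                         for s, m in zip(train_slides, tissue_masks)]
    pairs = _sample_training_patches(patches_per_slide, cfg)
    seg_state = train_segmenter(pairs, cfg.seg, width=cfg.seg_width)

    graphs = []
    for slide, patches in zip(train_slides, patches_per_slide):
        probs, feats = infer_patches(seg_state, patches)
        graphs.append(graph_from_patch_outputs(probs, feats, patches, cfg.graph,
                                               slide_id=slide.slide_id,
                                               label=slide.category))
    gcn_state = train_gcn(graphs, cfg=cfg.gcn)
    return PipelineModel(seg_state, gcn_state, target, cfg)


def predict_slides(model: PipelineModel, slides: list[SlideImage],
                   graphs: list[SlideGraph] | None = None) -> pd.DataFrame:
    """Per-slide prediction table.

    Columns: ``slide_id, center, truth, p_NED, p_LGD, p_HGD, p_IIN, call,
    screened_out`` (the last is pd.NA until a screening threshold is
    calibrated).  Precomputed `graphs` may be passed to skip re-running the
    segmenter.
    """
    if graphs is None:
        graphs = [build_slide_graph(model.seg_state, s, model.target_stats, model.config)
                  for s in slides]
    rows = []
    for slide, graph in zip(slides, graphs):
        probs = predict_four_tier(model.gcn_state, graph)
        row = {
            "slide_id": slide.slide_id, "center": slide.center,
            "truth": slide.category,
            "p_NED": probs.p_ned, "p_LGD": probs.p_lgd,
            "p_HGD": probs.p_hgd, "p_IIN": probs.p_iin,
            "call": classify_four_tier(probs),
            "screened_out": pd.NA,
        }
        if model.screening is not None:
            row["screened_out"] = (screen_slide(probs, model.screening)
                                   == "benign-screened-out")
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_pipeline(model: PipelineModel, calibration_slides: list[SlideImage],
                       *, set_id: str = "validation") -> ScreeningConfig:
    """Calibrate the screening threshold on labelled slides and attach it to
    the model.  Ground-truth categories are required."""
    if any(s.category is None for s in calibration_slides):
        raise ValueError("calibration slides need ground-truth categories")
    preds = predict_slides(model, calibration_slides)
    is_pos = preds["truth"].isin(POSITIVE_CATEGORIES).to_numpy()
    screening = calibrate_screening_threshold(preds["p_NED"].to_numpy(), is_pos,
                                              calibration_set=set_id)
    model.screening = screening
    return screening
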