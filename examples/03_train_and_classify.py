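"""Train the two-step model and classify held-out slides.

Step 1: a small V-Net-style patch segmenter locates abnormal tissue and
doubles as a feature extractor.  Step 2: the top-n most abnormal patches
form a graph (Chebyshev edge rule on patch features) and a GCN emits
four-tier probabilities per slide.
"""

from gastrograph.classifier import GcnTrainConfig
from gastrograph.pipeline import PipelineConfig, predict_slides, train_pipeline
from gastrograph.segmentation import SegTrainConfig
from gastrograph.synthetic import generate_cohort

counts = lambda n: {"C0": {c: n for c in ("NED", "LGD", "HGD", "IIN")}}
train = generate_cohort(counts(4), seed=11, width=256, height=256)
test = generate_cohort(counts(2), seed=99, width=256, height=256)

cfg = PipelineConfig(patch_size=64,
                     seg=SegTrainConfig(epochs=3, seed=5), max_seg_patches=48,
                     gcn=GcnTrainConfig(epochs=30, seed=5), seed=5)
model = train_pipeline(train, cfg)
print(f"segmenter dice-loss trace: "
      f"{[round(x, 3) for x in model.seg_state.loss_trace]}")

preds = predict_slides(model, test)
print(preds[["slide_id", "truth", "call", "p_NED", "p_IIN"]].round(3).to_string(index=False))
acc = (preds.truth == preds.call).mean()
print(f"held-out four-tier accuracy: {acc:.2f}")

# Each row is one slide: the four probabilities sum to 1 and `call` is the
# argmax (ties resolve toward the more severe category).
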