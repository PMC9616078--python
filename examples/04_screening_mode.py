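"""NED-screening mode: triage benign slides with a zero-miss guarantee.

The threshold t is calibrated as the maximum p_NED over the positive
(LGD/HGD/IIN) slides of a calibration set.  Under the rule
"benign iff p_NED > t" no positive slide of that set can be screened out,
so sensitivity and NPV there are 100% by construction — the screening only
reduces the pathologist's benign workload.
"""

from gastrograph.classifier import GcnTrainConfig
from gastrograph.core import POSITIVE_CATEGORIES
from gastrograph.pipeline import (PipelineConfig, calibrate_pipeline, predict_slides,
                                  train_pipeline)
from gastrograph.segmentation import SegTrainConfig
from gastrograph.synthetic import generate_cohort

counts = lambda n: {"C0": {c: n for c in ("NED", "LGD", "HGD", "IIN")}}
train = generate_cohort(counts(4), seed=11, width=256, height=256)
calib = generate_cohort(counts(3), seed=77, width=256, height=256)

cfg = PipelineConfig(patch_size=64,
                     seg=SegTrainConfig(epochs=3, seed=5), max_seg_patches=48,
                     gcn=GcnTrainConfig(epochs=30, seed=5), seed=5)
model = train_pipeline(train, cfg)

screening = calibrate_pipeline(model, calib, set_id="demo-calibration")
print(f"calibrated t = {screening.threshold:.4f} "
      f"({screening.n_positives} positive slides)")

preds = predict_slides(model, calib)
screened = preds["screened_out"].astype(bool)
pos = preds["truth"].isin(POSITIVE_CATEGORIES)
print(f"screened out {int(screened.sum())}/{len(preds)} slides "
      f"({int((screened & ~pos).sum())} benign, {int((screened & pos).sum())} positive)")
print(f"sensitivity for positives: {int((pos & ~screened).sum())}/{int(pos.sum())}")

# The positive count inside the screened-out group is structurally zero on
# the calibration set: t was chosen so that no positive slide exceeds it.
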