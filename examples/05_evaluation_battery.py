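"""Run the evaluation battery on a prediction table.

Shows the four-tier confusion matrix, per-group rates, ROC/AUC for the
screening grouping, and Cohen's kappa (unweighted and quadratically
weighted) with its descriptive band.
"""

import numpy as np
import pandas as pd

from gastrograph.core import CATEGORIES
from gastrograph.evaluation import evaluate_predictions

# a synthetic rater: 85% correct, errors drawn uniformly
rng = np.random.default_rng(0)
truth = rng.choice(CATEGORIES, 300)
call = np.where(rng.random(300) < 0.85, truth, rng.choice(CATEGORIES, 300))
p_ned = np.clip(np.where(truth == "NED", rng.normal(0.8, 0.15, 300),
                         rng.normal(0.2, 0.15, 300)), 0, 1)
preds = pd.DataFrame({"truth": truth, "call": call, "p_NED": p_ned})

four = evaluate_predictions(preds, "four-tier")
print("four-tier confusion matrix (rows = truth):")
print(four.matrix)
print(f"overall accuracy {four.overall_accuracy:.3f}")
for name, kr in (("unweighted", four.kappa_unweighted),
                 ("quadratic ", four.kappa_quadratic)):
    print(f"kappa ({name}) = {kr.kappa:.3f}  band: {kr.band}")

screen = evaluate_predictions(preds, "ned-vs-rest", score_column="p_NED",
                              positive_group="POS")
m = screen.per_group["POS"]
print(f"\nNED-vs-rest: sensitivity {m['sensitivity']:.3f}, "
      f"specificity {m['specificity']:.3f}, NPV {m['npv']:.3f}, AUC {screen.auc:.3f}")

# The kappa bands follow the conventional cut-points (0.2/0.4/0.6/0.8); the
# AUC is the probability a positive slide scores above a benign one.
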