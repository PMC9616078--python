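"""Evaluation battery: confusion matrices, rate metrics, ROC/AUC, Cohen's kappa.

Supports the four-tier classification and the two clinically motivated
two-tier groupings (NED vs LGD/HGD/IIN for screening; NED/LGD vs HGD/IIN
for intervention), per-center breakdowns via simple pooling, and
chance-corrected agreement with the conventional descriptive bands:

    poor < 0.20 <= fair < 0.40 <= moderate < 0.60 <= good < 0.80 <= very good

Quadratic kappa weights use the standard squared-distance scheme on the
severity ordering NED < LGD < HGD < IIN.  Standard estimators (confusion
matrix, trapezoidal AUC, kappa) are delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix as _sk_confusion, roc_curve

from .core import CATEGORIES

__all__ = [
    "Grouping",
    "GROUPINGS",
    "KappaResult",
    "EvalReport",
    "confusion_matrix",
    "binary_metrics",
    "roc_auc",
    "cohens_kappa",
    "kappa_band",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class Grouping:
    """A total mapping from the four categories onto evaluation groups."""

    name: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.mapping)
        if missing:
            raise ValueError(f"grouping {self.name!r} does not map {sorted(missing)}")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for cat in CATEGORIES:
            g = self.mapping[cat]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def apply(self, labels) -> list[str]:
        """Map four-tier labels onto groups; group labels pass through."""
        groups = set(self.mapping.values())
        out = []
        for lb in labels:
            if lb in self.mapping:
                out.append(self.mapping[lb])
            elif lb in groups:
                out.append(lb)
            else:
                raise KeyError(f"label {lb!r} not in grouping {self.name!r}")
        return out


GROUPINGS: dict[str, Grouping] = {
    "four-tier": Grouping("four-tier", {c: c for c in CATEGORIES}),
    "ned-vs-rest": Grouping("ned-vs-rest",
                            {"NED": "NED", "LGD": "POS", "HGD": "POS", "IIN": "POS"}),
    "nedlgd-vs-hgdiin": Grouping("nedlgd-vs-hgdiin",
                                 {"NED": "LOW", "LGD": "LOW", "HGD": "HIGH", "IIN": "HIGH"}),
}


def confusion_matrix(truths, predictions, grouping: Grouping | str = "four-tier") -> pd.DataFrame:
    """K x K counts, rows = truth, columns = prediction, in severity order."""
    grouping = GROUPINGS[grouping] if isinstance(grouping, str) else grouping
    t = grouping.apply(truths)
    p = grouping.apply(predictions)
    if len(t) != len(p):
        raise ValueError("truths and predictions must have equal length")
    groups = list(grouping.groups)
    mat = _sk_confusion(t, p, labels=groups)
    return pd.DataFrame(mat, index=groups, columns=groups)


def binary_metrics(matrix: pd.DataFrame, positive_group: str) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and NPV from a confusion matrix.

    The matrix is collapsed to 2x2 against `positive_group`.  A metric whose
    denominator is empty is reported as NaN, never as 0.
    """
    if positive_group not in matrix.index:
        raise ValueError(f"{positive_group!r} is not a group of this matrix")
    pos = matrix.index == positive_group
    m = matrix.to_numpy(dtype=np.float64)
    tp = m[pos][:, pos].sum()
    fn = m[pos][:, ~pos].sum()
    fp = m[~pos][:, pos].sum()
    tn = m[~pos][:, ~pos].sum()

    def rate(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "accuracy": rate(tp + tn, m.sum()),
        "npv": rate(tn, tn + fn),
    }


def roc_auc(scores, truths) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoidal AUC for binary truths.

    Ties follow the Mann-Whitney convention (tied pairs count 1/2), which
    the threshold-sweep/trapezoid construction reproduces exactly.  Returns
    ``(points, auc)`` where `points` is an (n, 2) array of (fpr, tpr).
    """
    y = np.asarray(truths).astype(bool)
    s = np.asarray(scores, dtype=np.float64)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


_BANDS = [(0.20, "poor"), (0.40, "fair"), (0.60, "moderate"), (0.80, "good"),
          (np.inf, "very good")]


def kappa_band(kappa: float) -> str:
    """Descriptive band; each cut-point belongs to the upper band
    (0.80 -> "very good")."""
    for upper, name in _BANDS:
        if kappa < upper:
            return name
    return "very good"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weighting: str  # "none" | "quadratic"
    band: str


def cohens_kappa(ratings_a, ratings_b, categories: tuple[str, ...] = CATEGORIES,
                 weighting: str = "none") -> KappaResult:
    """Cohen's kappa between two raters over ordered categories.

    ``weighting="quadratic"`` applies weights ``w_ij = 1 - ((i-j)/(K-1))^2``
    on the category ordering.  Constant identical ratings (chance agreement
    p_e = 1) leave kappa undefined and raise.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    bad = (set(a) | set(b)) - set(categories)
    if bad:
        raise ValueError(f"labels outside the category set: {sorted(bad)}")
    if weighting not in ("none", "quadratic"):
        raise ValueError("weighting must be 'none' or 'quadratic'")
    if len(set(a)) == 1 and set(a) == set(b):
        raise ValueError("degenerate constant ratings: chance agreement is 1, "
                         "kappa undefined")
    weights = None if weighting == "none" else "quadratic"
    k = float(cohen_kappa_score(a, b, labels=list(categories), weights=weights))
    return KappaResult(k, weighting, kappa_band(k))


@dataclass
class EvalReport:
    """Complete metric battery for one set of slide predictions."""

    grouping: str
    matrix: pd.DataFrame
    per_group: dict[str, dict[str, float]]
    overall_accuracy: float
    auc: float | None
    roc_points: np.ndarray | None = field(default=None, repr=False)
    kappa_unweighted: KappaResult | None = None
    kappa_quadratic: KappaResult | None = None
    per_center: dict[str, "EvalReport"] | None = None

    def to_dict(self) -> dict:
        d = {
            "grouping": self.grouping,
            "confusion_matrix": {"groups": list(self.matrix.index),
                                 "counts": self.matrix.to_numpy().tolist()},
            "per_group": self.per_group,
            "overall_accuracy": self.overall_accuracy,
            "auc": self.auc,
        }
        if self.roc_points is not None:
            d["roc_points"] = self.roc_points.tolist()
        for name, kr in (("kappa_unweighted", self.kappa_unweighted),
                         ("kappa_quadratic", self.kappa_quadratic)):
            if kr is not None:
                d[name] = {"kappa": kr.kappa, "weighting": kr.weighting, "band": kr.band}
        if self.per_center:
            d["per_center"] = {c: r.to_dict() for c, r in self.per_center.items()}
        return d


def evaluate_predictions(predictions: pd.DataFrame, grouping: Grouping | str = "four-tier",
                         *, score_column: str | None = None, positive_group: str | None = None,
                         by_center: bool = False) -> EvalReport:
    """Run the metric battery on a predictions table.

    `predictions` needs columns ``truth`` and ``call`` (four-tier labels),
    optionally ``center`` and a score column for ROC analysis.  For a
    two-group grouping the AUC is computed from `score_column` against the
    non-`positive_group` side being benign (higher score = more benign when
    the score is p_NED; the orientation is resolved automatically so AUC is
    always >= 0.5 under label flip, never silently inverted).
    """
    grouping = GROUPINGS[grouping] if isinstance(grouping, str) else grouping
    truths = list(predictions["truth"])
    calls = list(predictions["call"])
    mat = confusion_matrix(truths, calls, grouping)
    per_group = {g: binary_metrics(mat, g) for g in grouping.groups}
    overall = float(np.trace(mat.to_numpy())) / max(1, len(truths))

    auc = None
    points = None
    if score_column is not None and positive_group is not None and len(grouping.groups) == 2:
        y = np.array(grouping.apply(truths)) == positive_group
        if y.any() and not y.all():
            s = predictions[score_column].to_numpy(dtype=np.float64)
            # orient the score toward the positive group if needed
            if np.nanmean(s[y]) < np.nanmean(s[~y]):
                s = -s
            points, auc = roc_auc(s, y)

    kap_u = kap_q = None
    try:
        kap_u = cohens_kappa(truths, calls, grouping.groups, "none")
        kap_q = cohens_kappa(truths, calls, grouping.groups, "quadratic")
    except ValueError:
        pass  # degenerate ratings: leave kappa unset rather than fabricate 0

    per_center = None
    if by_center and "center" in predictions.columns:
        per_center = {}
        for center, sub in predictions.groupby("center"):
            per_center[center] = evaluate_predictions(
                sub, grouping, score_column=score_column,
                positive_group=positive_group, by_center=False)

    return EvalReport(grouping.name, mat, per_group, overall, auc, points,
                      kap_u, kap_q, per_center)
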