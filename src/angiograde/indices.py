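"""Ischemic and leakage indices, and the two-threshold discriminant grader.

The ischemic index is the nonperfusion area divided by the biological
standard d² (the visible-retina area); the leakage index is the leakage area
divided by the same d². Both are dimensionless fractions.

Grading from the index pair uses a one-dimensional canonical (Fisher)
discriminant: the two indices are projected onto the canonical axis and two
thresholds t1 < t2 split the score line into normal / NPDR / PDR. The
thresholds are chosen by exhaustive search over midpoints of adjacent sorted
training scores, maximizing training accuracy. A plain least-squares
regression of coded grades (0, 1, 2) on the index pair is available as an
alternative scoring direction (``method="lstsq"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .frames import GRADES, Grade, IndexPair, LesionMasks, RetinaGeometry

__all__ = [
    "compute_indices",
    "DiscriminantModel",
    "fit_discriminant",
    "predict_grade_from_indices",
    "index_summary",
]


def compute_indices(masks: LesionMasks, geometry: RetinaGeometry) -> IndexPair:
    """Lesion-area fractions: |nonperfusion| / d² and |leakage| / d²."""
    d2 = float(geometry.d2)
    if d2 <= 0:
        raise ValueError("d2 must be positive")
    return IndexPair(
        ischemic_index=float(masks.nonperfusion.sum()) / d2,
        leakage_index=float(masks.leakage.sum()) / d2,
    )


@dataclass
class DiscriminantModel:
    """Linear score over (ischemic, leakage) with two grade thresholds.

    score = weights . (II, LI) + bias; grade = normal if score <= t1,
    NPDR if t1 < score <= t2, PDR otherwise (boundary scores fall into the
    lower class). Orientation is fixed so the PDR training mean is largest.
    """

    weights: np.ndarray
    bias: float
    thresholds: Tuple[float, float]
    class_order: Tuple[Grade, Grade, Grade] = GRADES
    training_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(2)
        t1, t2 = self.thresholds
        if not t1 < t2:
            raise ValueError(f"thresholds must satisfy t1 < t2, got ({t1}, {t2})")

    def score(self, pair: IndexPair) -> float:
        return float(self.weights @ pair.as_array() + self.bias)

    def to_dict(self) -> Dict:
        return {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "thresholds": list(self.thresholds),
            "class_order": [g.value for g in self.class_order],
            "training_accuracy": self.training_accuracy,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "DiscriminantModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            thresholds=(float(d["thresholds"][0]), float(d["thresholds"][1])),
            class_order=tuple(Grade(g) for g in d["class_order"]),  # type: ignore[arg-type]
            training_accuracy=float(d.get("training_accuracy", float("nan"))),
        )


def _fisher_direction(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leading canonical direction of Sw^-1 Sb for the 2-D index pairs.

    Falls back to the PDR-minus-normal mean difference with diagonal
    regularization when the within-class scatter is singular.
    """
    classes = np.unique(y)
    overall = x.mean(axis=0)
    sw = np.zeros((2, 2))
    sb = np.zeros((2, 2))
    for c in classes:
        xc = x[y == c]
        mu = xc.mean(axis=0)
        d = xc - mu
        sw += d.T @ d
        dm = (mu - overall)[:, None]
        sb += len(xc) * (dm @ dm.T)
    try:
        evals, evecs = np.linalg.eig(np.linalg.solve(sw, sb))
        w = np.real(evecs[:, np.argmax(np.real(evals))])
    except np.linalg.LinAlgError:
        mu_hi = x[y == classes.max()].mean(axis=0)
        mu_lo = x[y == classes.min()].mean(axis=0)
        reg = np.diag(np.diag(sw) + 1e-6)
        w = np.linalg.solve(reg, mu_hi - mu_lo)
    nrm = np.linalg.norm(w)
    return w / nrm if nrm > 0 else np.array([1.0, 0.0])


def _best_two_thresholds(scores: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Exhaustive two-threshold search over midpoints of adjacent scores.

    Returns (t1, t2, training_accuracy); among ties the lowest (t1, t2) pair
    wins. Candidate cuts bracket the score range so degenerate splits
    (everything one class) are searchable too.
    """
    order = np.argsort(scores, kind="stable")
    s, yy = scores[order], y[order]
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = max(float(uniq[-1] - uniq[0]), 1.0)
    cand = np.concatenate(([uniq[0] - 0.5 * span], mids, [uniq[-1] + 0.5 * span]))
    best = (-1.0, 0.0, 1.0)
    n = len(s)
    for i, t1 in enumerate(cand):
        n0 = np.searchsorted(s, t1, side="right")
        c0 = int(np.sum(yy[:n0] == 0))
        for t2 in cand[i + 1 :]:
            n1 = np.searchsorted(s, t2, side="right")
            c1 = int(np.sum(yy[n0:n1] == 1))
            c2 = int(np.sum(yy[n1:] == 2))
            acc = (c0 + c1 + c2) / n
            if acc > best[0] + 1e-12:
                best = (acc, float(t1), float(t2))
    return best[1], best[2], best[0]


def fit_discriminant(
    pairs: Sequence[IndexPair],
    grades: Sequence[Grade],
    method: str = "fisher",
) -> DiscriminantModel:
    """Fit the canonical discriminant and its two grade thresholds.

    Requires at least two samples of each grade. ``method="fisher"`` (the
    default) projects on the leading canonical axis; ``method="lstsq"``
    regresses coded grades 0/1/2 on the index pair and uses the fitted
    linear predictor as the score. Both then run the same exhaustive
    two-threshold search.
    """
    x = np.array([p.as_array() for p in pairs], dtype=float)
    y = np.array([Grade(g).ordinal for g in grades], dtype=int)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be (ischemic, leakage) index pairs")
    for g in GRADES:
        if int(np.sum(y == g.ordinal)) < 2:
            raise ValueError(f"need at least 2 samples of grade {g.value}")

    if method == "fisher":
        w = _fisher_direction(x, y)
        bias = 0.0
    elif method == "lstsq":
        design = np.column_stack([x, np.ones(len(x))])
        coef, *_ = np.linalg.lstsq(design, y.astype(float), rcond=None)
        w, bias = coef[:2], float(coef[2])
    else:
        raise ValueError(f"unknown method {method!r}")

    scores = x @ w + bias
    # orientation fix: PDR mean score must be the largest
    if scores[y == 2].mean() < scores[y == 0].mean():
        w, bias, scores = -w, -bias, -scores
    t1, t2, acc = _best_two_thresholds(scores, y)
    return DiscriminantModel(
        weights=w, bias=bias, thresholds=(t1, t2), training_accuracy=acc
    )


def predict_grade_from_indices(model: DiscriminantModel, pair: IndexPair) -> Grade:
    """Grade an index pair with the fitted two-threshold rule."""
    s = model.score(pair)
    t1, t2 = model.thresholds
    if s <= t1:
        return model.class_order[0]
    if s <= t2:
        return model.class_order[1]
    return model.class_order[2]


def index_summary(
    pairs: Sequence[IndexPair], grades: Sequence[Grade]
) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Five-number summaries (min, q1, median, q3, max) per grade per index."""
    grades = [Grade(g) for g in grades]
    out: Dict[str, Dict[str, Dict[str, float]]] = {}
    for g in GRADES:
        vals = [p for p, gi in zip(pairs, grades) if gi == g]
        if not vals:
            raise ValueError(f"no samples for grade {g.value}")
        out[g.value] = {}
        for name, arr in (
            ("ischemic_index", np.array([p.ischemic_index for p in vals])),
            ("leakage_index", np.array([p.leakage_index for p in vals])),
        ):
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            out[g.value][name] = {
                "min": float(arr.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(arr.max()),
            }
    return out
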