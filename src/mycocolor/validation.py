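"""Interrater agreement machinery: confusion matrices, accuracy, kappa.

The tool's hue calls are validated against expert color descriptions by
treating the two as raters: rater 1 is the published (expected) hue,
rater 2 the predicted hue. Agreement over a multiclass confusion matrix
of hue categories (yellow, green, red, blue, purple by default) is
summarised by per-category one-vs-rest accuracy

    (TP + TN) / (TP + TN + FP + FN)

and by Cohen's kappa, kappa = (p_o - p_e) / (1 - p_e), with p_o the
observed agreement and p_e the chance agreement from the margins.
Replicate runs are summarised as mean +/- sample (n-1) standard
deviation.

Compound hue groups ("purple-blue", "yellow-red", ...) collapse to
their first component for the 5-category analysis; the mapping is
overridable. A full result table collapses to one predicted hue per
image via the dominant (highest-Pct) bin by default, or a Pct-weighted
vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matching import ResultTable

DEFAULT_HUE_CATEGORIES = ("yellow", "green", "red", "blue", "purple")

# Landis & Koch interpretation bands; upper edges inclusive.
KAPPA_BANDS = (
    (0.0, "none/slight"),
    (0.20, "none/slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this matrix (e.g. no observations)."""


@dataclass
class ConfusionMatrix:
    """Square multiclass count matrix: rows = expected, columns = predicted."""

    categories: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the category list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, category: str) -> int:
        try:
            return self.categories.index(category)
        except ValueError:
            raise KeyError(f"unknown category {category!r}") from None


@dataclass
class AgreementSummary:
    """Per-category accuracies plus kappa and its banded interpretation."""

    confusion: ConfusionMatrix
    per_category_accuracy: dict[str, float]
    kappa: float
    interpretation: str


def collapse_hue(label: str) -> str:
    """Map a compound hue group to its first component.

    "purple-blue" -> "purple", "blue-green" -> "blue", "yellow-red" ->
    "yellow"; simple labels pass through unchanged (whitespace trimmed,
    lowercased).
    """
    return str(label).strip().lower().split("-")[0]


def build_confusion(
    expected,
    predicted,
    categories=DEFAULT_HUE_CATEGORIES,
) -> ConfusionMatrix:
    """Tally expected-vs-predicted label pairs into a confusion matrix."""
    expected = list(expected)
    predicted = list(predicted)
    if len(expected) != len(predicted):
        raise ValueError(
            f"label sequences differ in length: {len(expected)} vs {len(predicted)}"
        )
    categories = tuple(categories)
    idx = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for e, p in zip(expected, predicted):
        if e not in idx:
            raise ValueError(f"unknown expected label {e!r}")
        if p not in idx:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[idx[e], idx[p]] += 1
    return ConfusionMatrix(categories=categories, counts=counts)


def category_accuracy(cm: ConfusionMatrix, category: str) -> float:
    """One-vs-rest accuracy (TP+TN)/(TP+TN+FP+FN) for one category."""
    n = cm.total
    if n == 0:
        raise UndefinedStatisticError("accuracy undefined for an empty matrix")
    c = cm.index(category)
    tp = cm.counts[c, c]
    fn = cm.counts[c, :].sum() - tp
    fp = cm.counts[:, c].sum() - tp
    tn = n - tp - fn - fp
    return float((tp + tn) / n)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between the two raters."""
    n = cm.total
    if n == 0:
        raise UndefinedStatisticError("kappa undefined for an empty matrix")
    po = float(np.trace(cm.counts)) / n
    pe = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / n**2
    if pe == 1.0:
        if po == 1.0:
            return 1.0
        raise UndefinedStatisticError("kappa undefined: chance agreement is 1")
    return (po - pe) / (1.0 - pe)


def replicate_summary(values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation across replicate runs."""
    values = np.asarray(list(values), dtype=np.float64)
    if values.size < 2:
        raise ValueError("replicate summary needs at least 2 values")
    return float(values.mean()), float(values.std(ddof=1))


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value in [-1, 1]."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0:
        return "poor"
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


def predicted_hue(result: ResultTable, method: str = "dominant") -> str:
    """Collapse an 8-row hue result table to one hue label per image.

    ``dominant``: the (collapsed) hue of the highest-Pct bin, earliest
    bin winning ties. ``weighted``: the collapsed hue with the largest
    total Pct across bins.
    """
    if result.label_kind != "hue":
        raise ValueError("predicted_hue expects a hue result table")
    if method == "dominant":
        best = max(result.rows, key=lambda r: (r.pct, -r.index))
        return collapse_hue(best.label)
    if method == "weighted":
        votes: dict[str, float] = {}
        order: dict[str, int] = {}
        for r in result.rows:
            h = collapse_hue(r.label)
            votes[h] = votes.get(h, 0.0) + r.pct
            order.setdefault(h, r.index)
        return max(votes, key=lambda h: (votes[h], -order[h]))
    raise ValueError(f"unknown collapse method {method!r}")


def summarize_agreement(
    expected,
    predicted,
    categories=DEFAULT_HUE_CATEGORIES,
) -> AgreementSummary:
    """Confusion matrix, per-category accuracies, kappa, interpretation."""
    cm = build_confusion(expected, predicted, categories)
    acc = {c: category_accuracy(cm, c) for c in cm.categories}
    k = cohens_kappa(cm)
    return AgreementSummary(
        confusion=cm,
        per_category_accuracy=acc,
        kappa=k,
        interpretation=interpret_kappa(max(-1.0, min(1.0, k))),
    )
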