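"""Accuracy accounting for prediction sets.

Implements the bookkeeping used to report predictor performance: exact
accuracy (a dual call is credited when either of its two classes matches
the experimental label), within-one-C5 accuracy, per-kingdom /
per-phylum / per-best-template breakdowns, a predicted-by-labeled confusion
matrix, and the distribution of predicted classes across a screen.

A >=C30 prediction counts as an exact match for any >=C30 label (products
longer than C30 are binned together).  NA-labeled records (no detectable
activity) count as incorrect unless explicitly excluded, since the
predictor has no inactive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .formats_io import LabeledRecord, PredictionReportRow, ProductClass
from .scoring import CASCADE_CLASSES, Prediction

__all__ = [
    "EvaluationReport",
    "EvaluationError",
    "score_predictions",
    "class_distribution",
    "percent",
]

LABEL_ORDER = (
    ProductClass.C10,
    ProductClass.C15,
    ProductClass.C20,
    ProductClass.C25,
    ProductClass.GE_C30,
    ProductClass.NA,
)


class EvaluationError(ValueError):
    """Raised for inconsistent prediction/label inputs."""


def percent(fraction: float) -> int:
    """Round a fraction to an integer percentage, half-up (0.858 -> 86)."""
    return int(
        (Decimal(str(fraction)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class _Call:
    """Normalized view of a prediction (from either a Prediction object or
    a report row)."""

    classes: tuple[ProductClass, ...]
    primary: ProductClass
    template_id: str
    identity: float


def _normalize(pred) -> _Call:
    if isinstance(pred, Prediction):
        return _Call(pred.classes, pred.primary, pred.template_id, pred.identity)
    if isinstance(pred, PredictionReportRow):
        # report rows serialize dual calls shorter-chain-first; the first
        # entry is taken as primary for the confusion matrix
        return _Call(pred.predicted, pred.predicted[0], pred.best_template, pred.identity)
    raise EvaluationError(f"cannot interpret prediction object {type(pred).__name__}")


@dataclass(frozen=True)
class EvaluationReport:
    """Full accuracy accounting for one prediction/label set."""

    n: int
    n_correct: int
    n_within_one: int
    n_excluded_na: int
    per_kingdom: dict[str, tuple[int, int]]  # group -> (n, n_correct)
    per_phylum: dict[str, tuple[int, int]]
    per_template: dict[str, tuple[int, int]]
    confusion: dict[str, dict[str, int]]  # predicted -> labeled -> count
    class_distribution: dict[str, float]
    mean_identity: float

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n if self.n else float("nan")

    @property
    def within_one_accuracy(self) -> float:
        return self.n_within_one / self.n if self.n else float("nan")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "n_within_one": self.n_within_one,
            "within_one_accuracy": self.within_one_accuracy,
            "n_excluded_na": self.n_excluded_na,
            "per_kingdom": {k: list(v) for k, v in self.per_kingdom.items()},
            "per_phylum": {k: list(v) for k, v in self.per_phylum.items()},
            "per_template": {k: list(v) for k, v in self.per_template.items()},
            "confusion": self.confusion,
            "class_distribution": self.class_distribution,
            "mean_identity": self.mean_identity,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def summary(self) -> str:
        """Human-readable summary with integer percentages (half-up)."""
        lines = [
            f"overall accuracy: {percent(self.accuracy)}% "
            f"({self.n_correct}/{self.n})",
            f"within one C5 unit: {percent(self.within_one_accuracy)}% "
            f"({self.n_within_one}/{self.n})",
            f"mean best-template identity: {100 * self.mean_identity:.1f}%",
        ]
        if self.n_excluded_na:
            lines.append(f"excluded NA-labeled records: {self.n_excluded_na}")
        for title, groups in (
            ("kingdom", self.per_kingdom),
            ("phylum", self.per_phylum),
            ("best template", self.per_template),
        ):
            if groups:
                lines.append(f"by {title}:")
                for key in sorted(groups):
                    gn, gc = groups[key]
                    lines.append(
                        f"  {key}: {percent(gc / gn)}% ({gc}/{gn})"
                    )
        lines.append("predicted class distribution:")
        for cls in CASCADE_CLASSES:
            frac = self.class_distribution.get(str(cls), 0.0)
            lines.append(f"  {cls}: {percent(frac)}%")
        return "\n".join(lines)


def score_predictions(
    predictions: Mapping[str, Prediction | PredictionReportRow],
    labels: Iterable[LabeledRecord],
    exclude_na: bool = False,
) -> EvaluationReport:
    """Score predictions against experimentally determined labels.

    A prediction is correct iff its primary *or* secondary class equals the
    label; within-one-C5 credits any emitted class whose carbon count is
    within 5 of the label's.  Prediction and label ids must match exactly;
    orphans on either side raise :class:`EvaluationError` listing them.
    """
    label_by_id = {rec.sequence.id: rec for rec in labels}
    pred_ids = set(predictions)
    label_ids = set(label_by_id)
    orphans = sorted(pred_ids ^ label_ids)
    if orphans:
        raise EvaluationError(
            f"prediction/label id mismatch; orphan id(s): {', '.join(orphans)}"
        )

    n = n_correct = n_within = n_na_excluded = 0
    per_kingdom: dict[str, list[int]] = {}
    per_phylum: dict[str, list[int]] = {}
    per_template: dict[str, list[int]] = {}
    confusion: dict[str, dict[str, int]] = {
        str(p): {str(l): 0 for l in LABEL_ORDER} for p in CASCADE_CLASSES
    }
    identities: list[float] = []

    for rid in sorted(pred_ids):
        call = _normalize(predictions[rid])
        rec = label_by_id[rid]
        if rec.label is ProductClass.NA and exclude_na:
            n_na_excluded += 1
            continue
        n += 1
        identities.append(call.identity)
        confusion[str(call.primary)][str(rec.label)] += 1

        truth = {rec.label}
        if rec.label_secondary is not None:
            truth.add(rec.label_secondary)
        correct = any(c in truth for c in call.classes)
        within = False
        if rec.label.carbons is not None:
            within = any(
                abs(c.carbons - t.carbons) <= 5
                for c in call.classes
                for t in truth
                if t.carbons is not None
            )
        n_correct += int(correct)
        n_within += int(within)

        seq = rec.sequence
        for groups, key in (
            (per_kingdom, seq.kingdom),
            (per_phylum, seq.phylum),
            (per_template, call.template_id),
        ):
            if key:
                cell = groups.setdefault(key, [0, 0])
                cell[0] += 1
                cell[1] += int(correct)

    if n == 0:
        raise EvaluationError("no records to evaluate")

    dist = class_distribution(
        {rid: predictions[rid] for rid in pred_ids}
    )
    return EvaluationReport(
        n=n,
        n_correct=n_correct,
        n_within_one=n_within,
        n_excluded_na=n_na_excluded,
        per_kingdom={k: tuple(v) for k, v in per_kingdom.items()},
        per_phylum={k: tuple(v) for k, v in per_phylum.items()},
        per_template={k: tuple(v) for k, v in per_template.items()},
        confusion=confusion,
        class_distribution=dist,
        mean_identity=sum(identities) / len(identities),
    )


def class_distribution(
    predictions: Mapping[str, Prediction | PredictionReportRow] | Iterable,
) -> dict[str, float]:
    """Fractions of primary predicted classes, over all four emittable
    classes (zeros included); fractions sum to 1."""
    if isinstance(predictions, Mapping):
        items = list(predictions.values())
    else:
        items = list(predictions)
    if not items:
        raise EvaluationError("no predictions given")
    counts = {cls: 0 for cls in CASCADE_CLASSES}
    for pred in items:
        counts[_normalize(pred).primary] += 1
    total = len(items)
    return {str(cls): counts[cls] / total for cls in CASCADE_CLASSES}
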