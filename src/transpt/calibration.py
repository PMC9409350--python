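"""Calibration of site weights and floor thresholds from labeled data.

The loss surface is a step function of the thresholds and piecewise
constant in the weights, so gradient methods are useless; instead each
floor's weight triple is searched exhaustively on a simplex grid (default
step 0.01, matching the three-decimal precision at which trained site
contributions are conventionally reported) with a 1-D threshold sweep over
the midpoints of the observed floor scores.  Floors are updated by
coordinate descent in fixed order 1 -> 2 -> 3, repeated to convergence.
Ties are broken toward more uniform weights, then lexicographically, then
toward lower thresholds, making the fit bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import select_best_template
from .floors import TemplateRegistry, map_floor_residues
from .formats_io import LabeledRecord, ProductClass
from .scoring import (
    CASCADE_CLASSES,
    PredictorModel,
    Thresholds,
    WeightVector,
    default_model,
    floor_blocking_score,
    predict_from_assignment,
)

__all__ = [
    "TrainingConfig",
    "TrainingResult",
    "CalibrationError",
    "fit_model",
    "cross_validate",
]

logger = logging.getLogger(__name__)

_LOSSES = ("misclassification", "within-one-C5-weighted")


class CalibrationError(ValueError):
    """Raised for unusable training inputs or configuration."""


@dataclass(frozen=True)
class TrainingConfig:
    """Search configuration.

    ``grid_step`` must divide 1 evenly.  The within-one-C5-weighted loss
    charges 0.5 for an error of one C5 unit and 1.0 beyond.
    """

    grid_step: float = 0.01
    seed: int = 0
    loss: str = "misclassification"
    max_rounds: int = 20
    train_weights: bool = True
    train_thresholds: bool = True

    def __post_init__(self) -> None:
        k = 1.0 / self.grid_step
        if abs(k - round(k)) > 1e-9:
            raise CalibrationError("grid_step must divide 1 evenly")
        if self.loss not in _LOSSES:
            raise CalibrationError(f"loss must be one of {_LOSSES}")

    @property
    def grid_divisions(self) -> int:
        return round(1.0 / self.grid_step)


@dataclass(frozen=True)
class TrainingResult:
    model: PredictorModel
    training_accuracy: float
    confusion: dict[str, dict[str, int]]  # label -> predicted primary -> count
    loss_trajectory: tuple[float, ...]
    n_used: int
    n_excluded: int
    excluded_ids: tuple[str, ...]
    config: TrainingConfig


_LEVEL_OF_CLASS = {cls: i + 1 for i, cls in enumerate(CASCADE_CLASSES)}


def _prepare(
    dataset: list[LabeledRecord],
    registry: TemplateRegistry,
    base: PredictorModel,
):
    """Map every sequence onto floor sites and tabulate blocking scores.

    Returns (ids, B, labels, assignments, excluded_ids) where B[i, f, s] is
    the blocking score of record i at floor f+1 site s+1 (0 at gaps) and
    labels[i] is the cascade decision level 1..4.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    assignments = []
    excluded: list[str] = []
    for rec in dataset:
        if rec.label not in _LEVEL_OF_CLASS:
            excluded.append(rec.sequence.id)
            logger.warning(
                "excluding %s: label %s is outside the predictable classes",
                rec.sequence.id, rec.label,
            )
            continue
        try:
            match = select_best_template(rec.sequence, registry, base.alignment_params)
            assignment = map_floor_residues(match, registry[match.template_id])
        except Exception as exc:  # unmappable sequence
            excluded.append(rec.sequence.id)
            logger.warning("excluding %s: %s", rec.sequence.id, exc)
            continue
        b = np.zeros((3, 3))
        for f in range(3):
            for s in range(3):
                site = assignment.sites[f][s]
                if not site.is_gap:
                    b[f, s] = base.table[site.residue]
        ids.append(rec.sequence.id)
        rows.append(b)
        labels.append(_LEVEL_OF_CLASS[rec.label])
        assignments.append(assignment)
    if not ids:
        raise CalibrationError("no trainable records in dataset")
    return ids, np.stack(rows), np.array(labels), assignments, excluded


def _simplex_grid(divisions: int) -> np.ndarray:
    """All weight triples (i, j, k)/divisions with i + j + k = divisions."""
    pts = []
    for i in range(divisions + 1):
        for j in range(divisions + 1 - i):
            pts.append((i, j, divisions - i - j))
    return np.array(pts, dtype=float) / divisions


def _loss_matrix(levels: np.ndarray, labels: np.ndarray, loss: str) -> np.ndarray:
    """Per-record losses for predicted decision levels vs true levels."""
    if loss == "misclassification":
        return (levels != labels).astype(float)
    diff = np.abs(levels - labels)
    return np.where(diff == 0, 0.0, np.where(diff == 1, 0.5, 1.0))


def _sweep_floor(
    B: np.ndarray,
    labels: np.ndarray,
    floor: int,
    grid: np.ndarray,
    fixed_blocked: dict[int, np.ndarray],
    loss_kind: str,
) -> tuple[np.ndarray, float, float]:
    """Exhaustive (weights, threshold) search for one floor, holding the
    other floors' blocked/pass patterns fixed.  Returns (w, theta, loss)."""
    n = B.shape[0]
    scores = B[:, floor - 1, :] @ grid.T  # (n, G)
    scores = scores.T  # (G, n)

    ssorted = np.sort(scores, axis=1)
    mids = (ssorted[:, 1:] + ssorted[:, :-1]) / 2.0
    lo = ssorted[:, :1] - 1.0
    hi = ssorted[:, -1:] + 1.0
    cand = np.concatenate([lo, mids, hi], axis=1)  # (G, K)

    blocked_here = scores[:, None, :] > cand[:, :, None]  # (G, K, n)

    # cascade levels with this floor varying and the others fixed; int8
    # keeps the (G, K, n) intermediates small
    one, two, three, four = (np.int8(v) for v in (1, 2, 3, 4))
    b = {f: fixed_blocked[f][None, None, :] for f in (1, 2, 3) if f != floor}
    if floor == 1:
        levels = np.where(blocked_here, one, np.where(b[2], two, np.where(b[3], three, four)))
    elif floor == 2:
        levels = np.where(b[1], one, np.where(blocked_here, two, np.where(b[3], three, four)))
    else:
        levels = np.where(b[1], one, np.where(b[2], two, np.where(blocked_here, three, four)))

    losses = _loss_matrix(levels, labels[None, None, :].astype(np.int8), loss_kind).mean(axis=2)
    losses = np.round(losses, 12)

    best_loss = losses.min()
    gi, ki = np.nonzero(losses == best_loss)
    # tie-break: most uniform weights, then lexicographic weights, then
    # lowest threshold
    nonuni = np.round(((grid[gi] - 1.0 / 3.0) ** 2).sum(axis=1), 12)
    thetas = cand[gi, ki]
    order = np.lexsort(
        (thetas, -grid[gi, 2], -grid[gi, 1], -grid[gi, 0], nonuni)
    )
    # lexsort sorts by last key first: nonuniformity, then w descending
    # (prefer larger leading weights only as a stable arbitrary order),
    # then threshold ascending
    pick = order[0]
    return grid[gi[pick]], float(thetas[pick]), float(best_loss)


def _fit_matrices(
    B: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    base: PredictorModel,
) -> tuple[WeightVector, Thresholds, list[float]]:
    grid = _simplex_grid(config.grid_divisions)
    weights = [np.array(base.weights[f]) for f in (1, 2, 3)]
    if not config.train_weights:
        grid_by_floor = {f: weights[f - 1][None, :] for f in (1, 2, 3)}
    else:
        grid_by_floor = {f: grid for f in (1, 2, 3)}
    # start with everything passing: thresholds above any achievable score
    theta = [float(B.max()) + 1.0] * 3
    trajectory: list[float] = []

    for _round in range(config.max_rounds):
        prev = ([w.copy() for w in weights], list(theta))
        for f in (1, 2, 3):
            fixed = {
                g: (B[:, g - 1, :] @ weights[g - 1]) > theta[g - 1]
                for g in (1, 2, 3)
                if g != f
            }
            w, t, loss = _sweep_floor(
                B, labels, f, grid_by_floor[f], fixed, config.loss
            )
            weights[f - 1] = w
            if config.train_thresholds:
                theta[f - 1] = t
            trajectory.append(loss)
        unchanged = all(
            np.array_equal(pw, w) for pw, w in zip(prev[0], weights)
        ) and prev[1] == theta
        if unchanged:
            break

    wv = WeightVector(weights=tuple(tuple(float(x) for x in w) for w in weights))
    th = Thresholds(
        theta=tuple(float(t) for t in theta), ambiguity=base.thresholds.ambiguity
    )
    return wv, th, trajectory


def fit_model(
    dataset: list[LabeledRecord],
    registry: TemplateRegistry,
    config: TrainingConfig = TrainingConfig(),
    base: PredictorModel | None = None,
) -> TrainingResult:
    """Fit per-floor site weights and thresholds to a labeled dataset.

    The blocking table and alignment parameters are taken from ``base``
    (default: the shipped model) and are not refitted.  NA-labeled and
    unmappable records are excluded with a warning and counted in the
    result.  Deterministic for a fixed config.
    """
    base = base or default_model()
    usable = [r for r in dataset if r.label is not ProductClass.NA]
    n_na = len(dataset) - len(usable)
    if n_na:
        logger.warning("excluding %d NA-labeled record(s) from training", n_na)
    ids, B, labels, assignments, excluded = _prepare(usable, registry, base)
    if len(set(labels.tolist())) < 2:
        raise CalibrationError("training requires at least two distinct classes")

    wv, th, trajectory = _fit_matrices(B, labels, config, base)
    fitted = dataclasses.replace(base, weights=wv, thresholds=th)

    # warn when the ambiguity band swamps the observed score spreads
    min_spread = np.inf
    for f in (1, 2, 3):
        s = np.unique(np.round(B[:, f - 1, :] @ np.array(wv[f]), 12))
        if len(s) > 1:
            min_spread = min(min_spread, float(np.diff(s).min()))
    for f in (1, 2, 3):
        if np.isfinite(min_spread) and th.band(f) >= min_spread:
            warnings.warn(
                "ambiguity band exceeds the minimum spread of training floor "
                "scores; dual calls may be overabundant",
                stacklevel=2,
            )
            break

    # training accuracy recomputed through the real cascade
    confusion: dict[str, dict[str, int]] = {}
    n_correct = 0
    for rec_id, assignment, level in zip(ids, assignments, labels):
        pred = predict_from_assignment(assignment, fitted)
        true_cls = CASCADE_CLASSES[level - 1]
        confusion.setdefault(str(true_cls), {}).setdefault(str(pred.primary), 0)
        confusion[str(true_cls)][str(pred.primary)] += 1
        if pred.primary is true_cls:
            n_correct += 1

    return TrainingResult(
        model=fitted,
        training_accuracy=n_correct / len(ids),
        confusion=confusion,
        loss_trajectory=tuple(trajectory),
        n_used=len(ids),
        n_excluded=n_na + len(excluded),
        excluded_ids=tuple(excluded),
        config=config,
    )


def cross_validate(
    dataset: list[LabeledRecord],
    registry: TemplateRegistry,
    config: TrainingConfig = TrainingConfig(),
    folds: int = 5,
    base: PredictorModel | None = None,
) -> list[float]:
    """Stratified k-fold cross-validation; returns per-fold accuracies.

    Folds are stratified by class with a seed-deterministic shuffle; a
    class with fewer members than folds triggers a merged-stratum warning
    (its members are still spread round-robin).
    """
    if not 2 <= folds <= len(dataset):
        raise CalibrationError("folds must be in [2, len(dataset)]")
    base = base or default_model()
    usable = [r for r in dataset if r.label is not ProductClass.NA]
    ids, B, labels, assignments, _ = _prepare(usable, registry, base)

    rng = np.random.default_rng(config.seed)
    fold_of = np.zeros(len(ids), dtype=int)
    for level in np.unique(labels):
        members = np.nonzero(labels == level)[0]
        if len(members) < folds:
            warnings.warn(
                f"class {CASCADE_CLASSES[level - 1]} has fewer members "
                f"({len(members)}) than folds ({folds}); stratum merged",
                stacklevel=2,
            )
        members = members[rng.permutation(len(members))]
        fold_of[members] = np.arange(len(members)) % folds

    accuracies: list[float] = []
    for k in range(folds):
        train = fold_of != k
        test = ~train
        if not test.any():
            accuracies.append(float("nan"))
            continue
        if len(set(labels[train].tolist())) < 2:
            raise CalibrationError(f"fold {k}: training split has a single class")
        wv, th, _ = _fit_matrices(B[train], labels[train], config, base)
        fitted = dataclasses.replace(base, weights=wv, thresholds=th)
        correct = 0
        for i in np.nonzero(test)[0]:
            pred = predict_from_assignment(assignments[i], fitted)
            if pred.primary is CASCADE_CLASSES[labels[i] - 1]:
                correct += 1
        accuracies.append(correct / int(test.sum()))
    return accuracies
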