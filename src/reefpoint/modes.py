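"""Deployment modes for the automated annotator.

Three ways of putting per-point classifier scores to work:

* **Alleviate** — semi-automated deferral.  A point keeps the automated
  label when the maximum score strictly exceeds a threshold ``epsilon``;
  otherwise the decision is deferred to the human annotator.  The fraction
  of points labelled automatically is the *level of alleviation*
  ``lambda(epsilon)``, a step function of the threshold, so any target
  level maps onto a quantile of the max-score distribution.
* **Abundance** — fully automated cover estimation.  Per image, the raw
  automated cover vector is corrected through the inverse transpose of a
  row-stochastic confusion matrix estimated by grouped cross-validation on
  the training pool: ``c_corrected = (Q'^T)^{-1} c_automated``.  The
  correction is unbiased by construction but inflates variance, and single
  corrected entries may fall outside [0, 1].
* **Refine** — the top-k highest-scoring labels per point, as suggestions
  for a human annotator (k = 5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotator import (
    FeatureSet,
    ScoreMatrix,
    automated_annotations,
    score_points,
    train_classifier,
)
from .confusion import ConfusionMatrix
from .core import AnnotationSet, Key
from . import evaluation

__all__ = [
    "AlleviateResult",
    "alleviate",
    "epsilon_for_level",
    "alleviation_curve",
    "estimate_confusion_cv",
    "abundance_correct",
    "abundance_mode",
    "refine_suggestions",
]


@dataclass
class AlleviateResult:
    """Outcome of one Alleviate pass.

    ``level`` is the achieved fraction of automated decisions;
    ``deferred_keys`` the points handed to the human annotator.
    """

    annotations: AnnotationSet
    epsilon: float
    level: float
    deferred_keys: set[Key]


def _check_shared_keys(scores: ScoreMatrix, human: AnnotationSet) -> list[Key]:
    skeys, hkeys = set(scores.keys()), set(human.keys())
    if skeys != hkeys:
        missing = sorted(skeys ^ hkeys)[:10]
        raise ValueError(
            f"scores and human annotations do not share keys; "
            f"first mismatches: {missing}"
        )
    return sorted(skeys)


def alleviate(
    scores: ScoreMatrix,
    human: AnnotationSet,
    epsilon: float,
    annotator_id: str = "Alleviate",
) -> AlleviateResult:
    """Automated label where ``max score > epsilon`` (strict), else human."""
    keys = _check_shared_keys(scores, human)
    new_labels: dict[Key, str] = {}
    deferred: set[Key] = set()
    for key in keys:
        if scores.max_score(key) > epsilon:
            new_labels[key] = scores.argmax_label(key)
        else:
            deferred.add(key)
    out = human.replace_labels(new_labels, annotator_id=annotator_id)
    level = (len(keys) - len(deferred)) / len(keys) if keys else 0.0
    return AlleviateResult(out, float(epsilon), level, deferred)


def epsilon_for_level(scores: ScoreMatrix, level_target: float) -> float:
    """Threshold whose achieved alleviation level is closest to the target.

    The level is a right-continuous step function of ``epsilon`` taking
    values ``#{max-score > v}/n`` at candidate thresholds ``v``; candidates
    are the distinct max scores plus one value below the minimum (level 1).
    Ties in closeness resolve toward the lower achievable level.
    """
    if not 0.0 <= level_target <= 1.0:
        raise ValueError(f"level_target must lie in [0, 1], got {level_target}")
    mx = np.array(sorted(scores.max_scores().values()))
    if mx.size == 0:
        raise ValueError("empty score matrix")
    n = mx.size
    candidates = [(float(v), float(np.sum(mx > v)) / n) for v in np.unique(mx)]
    candidates.append((float(mx.min()) - 1.0, 1.0))
    # closest level; ties toward the lower level (more human decisions)
    best = min(candidates, key=lambda c: (abs(c[1] - level_target), c[1]))
    return best[0]


def alleviation_curve(
    scores: ScoreMatrix,
    human: AnnotationSet,
    reference: AnnotationSet,
    group=None,
    grid=(0.0, 0.25, 0.5, 0.75, 1.0),
) -> list[tuple[float, float]]:
    """Agreement with the reference along the human/automated trade-off.

    For each target level the matching threshold is derived, the alleviated
    set built, and Cohen's kappa against the reference computed — over the
    full vocabulary, or collapsed to the binary in/out task when ``group``
    (a group name or label collection) is given.  The endpoints reproduce
    the human-only and automated-only kappas exactly.
    """
    out = []
    for level in grid:
        res = alleviate(scores, human, epsilon_for_level(scores, level))
        if group is None:
            kap = evaluation.cohens_kappa(reference, res.annotations)
        else:
            kap = evaluation.kappa_group(reference, res.annotations, group)
        out.append((float(level), float(kap)))
    return out


def estimate_confusion_cv(
    features: FeatureSet,
    labels: AnnotationSet,
    folds: int = 20,
    rng_seed: int = 0,
    reg_strength: float | None = 1.0,
) -> ConfusionMatrix:
    """Out-of-fold confusion matrix of the classifier on its training pool.

    Folds are stratified by image — every point of an image lands in the
    same fold — so that co-located patches never straddle the train/test
    split.  ``folds`` equal to the number of images gives leave-one-image-out.
    Counts accumulate (true label, out-of-fold prediction) pairs over every
    point; rates are the row-normalised view of the result.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    keys = features.keys()
    if set(keys) != set(labels.keys()):
        raise ValueError("features and labels do not share keys")
    images = sorted({k[0] for k in keys})
    if folds > len(images):
        raise ValueError(
            f"folds={folds} exceeds the {len(images)} distinct images"
        )
    label_order = tuple(labels.label_set.labels)
    counts_by_label = pd.Series(labels.labels()).value_counts()
    rare = [
        lab
        for lab in counts_by_label.index
        if len({k[0] for k in keys if labels.label(k) == lab}) < folds
    ]
    if rare:
        warnings.warn(
            f"labels present in fewer images than folds: {rare}; "
            "their rows may be sparse or zero",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(images))
    fold_of_image = {
        images[idx]: fold
        for fold, chunk in enumerate(np.array_split(order, folds))
        for idx in chunk
    }
    counts = np.zeros((len(label_order), len(label_order)), dtype=np.int64)
    col = {lab: i for i, lab in enumerate(label_order)}
    for fold in range(folds):
        test_keys = [k for k in keys if fold_of_image[k[0]] == fold]
        train_keys = [k for k in keys if fold_of_image[k[0]] != fold]
        if not test_keys:
            continue
        clf = train_classifier(
            features.matrix(train_keys),
            labels.labels(train_keys),
            reg_strength=reg_strength,
            rng_seed=rng_seed,
            label_order=label_order,
            encoder_id=features.encoder_id,
        )
        pred = score_points(clf, features.subset(test_keys))
        for k in test_keys:
            counts[col[labels.label(k)], col[pred.argmax_label(k)]] += 1
    return ConfusionMatrix(label_order, counts)


def abundance_correct(
    Q_prime: ConfusionMatrix,
    cover_auto: np.ndarray,
    clip_negative: bool = False,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Invert the classifier's mixing to de-bias an automated cover vector.

    Solves ``R^T c = cover_auto`` for ``c`` with ``R`` the row-stochastic
    rate matrix (zero-count rows replaced by identity rows) plus a small
    ridge on the diagonal for numerical robustness.  Because the rows of
    ``R`` sum to one, the corrected vector conserves total mass; individual
    entries may be negative, which preserves unbiasedness in aggregate.
    ``clip_negative`` clips at zero and renormalises, for display only.
    """
    cover_auto = np.asarray(cover_auto, dtype=np.float64)
    m = len(Q_prime.labels)
    if cover_auto.shape != (m,):
        raise ValueError(f"cover vector shape {cover_auto.shape} != ({m},)")
    if abs(cover_auto.sum() - 1.0) > 1e-9:
        raise ValueError(f"cover vector sums to {cover_auto.sum()}, not 1")
    R0 = Q_prime.rates_filled()
    R = R0 + ridge * np.eye(m)
    try:
        # conditioning judged on the unridged rates: the ridge is a numerical
        # nicety, not a licence to invert a structurally singular matrix
        if np.linalg.cond(R0.T) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        corrected = np.linalg.solve(R.T, cover_auto)
    except np.linalg.LinAlgError:
        warnings.warn(
            "confusion rate matrix is singular beyond regularization; "
            "falling back to the pseudo-inverse",
            stacklevel=2,
        )
        corrected = np.linalg.pinv(R0.T) @ cover_auto
    if clip_negative:
        corrected = np.clip(corrected, 0.0, None)
        total = corrected.sum()
        if total > 0:
            corrected = corrected / total
    return corrected


def abundance_mode(
    Q_prime: ConfusionMatrix,
    automated: AnnotationSet,
    clip_negative: bool = False,
) -> "evaluation.CoverTable":
    """Per-image confusion-corrected covers from automated annotations."""
    raw = evaluation.cover(automated, labels=Q_prime.labels)
    corrected = raw.frame.copy()
    for image_id, row in raw.frame.iterrows():
        corrected.loc[image_id] = abundance_correct(
            Q_prime, row.to_numpy(), clip_negative=clip_negative
        )
    return evaluation.CoverTable("Abundance", corrected)


def refine_suggestions(scores: ScoreMatrix, k: int = 5) -> dict[Key, list[str]]:
    """Top-``k`` labels per point by descending score, ties by label order."""
    if k > len(scores.labels):
        raise ValueError(
            f"k={k} exceeds the {len(scores.labels)}-label vocabulary"
        )
    return {key: scores.top_labels(key, k) for key in scores.keys()}
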