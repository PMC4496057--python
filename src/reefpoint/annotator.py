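"""Automated point annotation: sampling, patch encoding, linear scoring.

The automated annotator labels a point by encoding the texture and colour
of the image patch centred on it as a fixed-length feature vector, then
scoring the vector with a one-versus-rest linear maximum-margin classifier.
The per-label scores are kept (:class:`ScoreMatrix`): their maximum drives
the confidence-based deferral of the Alleviate mode, and their ranking the
top-k suggestions of Refine.

The default :class:`PatchEncoder` concatenates per-channel colour
statistics (mean, spread, histogram) with oriented gradient-energy
histograms at two smoothing scales.  It is deliberately simple — a pure,
translation-invariant function of the patch — and pluggable: any callable
with the same signature and a distinct ``encoder_id`` can stand in, e.g. a
Fisher-vector encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.svm import LinearSVC

from .core import AnnotationSet, Key, PointAnnotation
from .labelset import LabelSet

__all__ = [
    "sample_points",
    "PatchEncoder",
    "extract_features",
    "FeatureSet",
    "encode_points",
    "TrainedClassifier",
    "train_classifier",
    "score_points",
    "ScoreMatrix",
    "automated_annotations",
    "SENTINEL_SCORE",
]

#: Finite stand-in for "never predict": labels absent from training keep this
#: score, far below any attainable decision value.
SENTINEL_SCORE: float = -1.0e12


def sample_points(
    image_width: int, image_height: int, n: int, rng_seed: int = 0
) -> list[tuple[int, int]]:
    """Draw ``n`` distinct uniformly random in-bounds ``(row, col)`` points."""
    if image_width <= 0 or image_height <= 0:
        raise ValueError("image dimensions must be positive")
    n_pixels = image_width * image_height
    if n < 1 or n > n_pixels:
        raise ValueError(f"n must be in [1, {n_pixels}], got {n}")
    rng = np.random.default_rng(rng_seed)
    if n > n_pixels // 2:
        flat = rng.permutation(n_pixels)[:n]
    else:
        seen: set[int] = set()
        while len(seen) < n:
            draw = rng.integers(0, n_pixels, size=n - len(seen))
            seen.update(int(v) for v in draw)
        flat = np.fromiter(seen, dtype=np.int64)
        # set iteration order is insertion order here, but sort+shuffle makes
        # the output depend only on the sampled values and the seed
        flat.sort()
        rng.shuffle(flat)
    return [(int(f // image_width), int(f % image_width)) for f in flat]


# -------------------------------------------------------------- encoding


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a non-empty HxWx3 RGB image")
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return image.astype(np.float64)


def _reflect_patch(image: np.ndarray, row: int, col: int, size: int) -> np.ndarray:
    """Square patch centred on (row, col); out-of-bounds filled by reflection."""
    h, w = image.shape[:2]
    half = size // 2
    r0, r1 = row - half, row - half + size
    c0, c1 = col - half, col - half + size
    pad_top, pad_left = max(0, -r0), max(0, -c0)
    pad_bot, pad_right = max(0, r1 - h), max(0, c1 - w)
    crop = image[max(0, r0) : min(h, r1), max(0, c0) : min(w, c1)]
    if pad_top or pad_bot or pad_left or pad_right:
        crop = np.pad(
            crop,
            ((pad_top, pad_bot), (pad_left, pad_right), (0, 0)),
            mode="reflect",
        )
    return crop


@dataclass(frozen=True)
class PatchEncoder:
    """Colour-statistics + oriented gradient-energy patch encoder.

    Parameters
    ----------
    patch_size:
        Side length in pixels of the square patch around the point.
    hist_bins:
        Per-channel intensity histogram bins.
    n_orientations:
        Orientation bins over [0, pi) for gradient energy.
    scales:
        Gaussian smoothing sigmas; one orientation histogram (plus a total
        gradient-energy component) per scale.
    """

    patch_size: int = 224
    hist_bins: int = 8
    n_orientations: int = 8
    scales: tuple[float, ...] = (1.0, 2.0)

    @property
    def encoder_id(self) -> str:
        s = "-".join(f"{x:g}" for x in self.scales)
        return (
            f"colortex-p{self.patch_size}-b{self.hist_bins}"
            f"-o{self.n_orientations}-s{s}"
        )

    @property
    def dim(self) -> int:
        return 3 * (2 + self.hist_bins) + len(self.scales) * (
            self.n_orientations + 1
        )

    def __call__(self, image: np.ndarray, point: tuple[int, int]) -> np.ndarray:
        img = _as_float_rgb(image)
        row, col = point
        h, w = img.shape[:2]
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"point {point} out of bounds for {h}x{w} image")
        patch = _reflect_patch(img, row, col, self.patch_size)
        parts: list[np.ndarray] = []
        for ch in range(3):
            band = patch[:, :, ch]
            hist, _ = np.histogram(band, bins=self.hist_bins, range=(0.0, 1.0))
            parts.append(np.array([band.mean(), band.std()]))
            parts.append(hist / band.size)
        gray = patch.mean(axis=2)
        area = gray.size
        for sigma in self.scales:
            smooth = ndimage.gaussian_filter(gray, sigma, mode="reflect")
            gy, gx = np.gradient(smooth)
            mag = np.hypot(gx, gy)
            theta = np.mod(np.arctan2(gy, gx), np.pi)
            ohist, _ = np.histogram(
                theta, bins=self.n_orientations, range=(0.0, np.pi), weights=mag
            )
            parts.append(ohist / area)
            parts.append(np.array([mag.mean()]))
        vec = np.concatenate(parts)
        if not np.all(np.isfinite(vec)):
            raise ValueError("non-finite feature component")
        return vec


def extract_features(
    image: np.ndarray, point: tuple[int, int], encoder: PatchEncoder
) -> np.ndarray:
    """Encode the patch around ``point``; deterministic in its inputs."""
    return encoder(image, point)


@dataclass
class FeatureSet:
    """Keyed feature vectors from one encoder."""

    encoder_id: str
    dim: int
    vectors: dict[Key, np.ndarray] = field(default_factory=dict)

    def add(self, key: Key, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (self.dim,):
            raise ValueError(f"feature dim {vec.shape} != ({self.dim},)")
        self.vectors[key] = vec

    def keys(self) -> list[Key]:
        return sorted(self.vectors)

    def matrix(self, keys: Sequence[Key] | None = None) -> np.ndarray:
        if keys is None:
            keys = self.keys()
        return np.stack([self.vectors[k] for k in keys])

    def subset(self, keys: Sequence[Key]) -> "FeatureSet":
        return FeatureSet(
            self.encoder_id, self.dim, {k: self.vectors[k] for k in keys}
        )

    def __len__(self) -> int:
        return len(self.vectors)


def encode_points(
    images: Mapping[str, np.ndarray],
    points: Mapping[Key, tuple[int, int]],
    encoder: PatchEncoder,
) -> FeatureSet:
    """Encode every keyed point from its image; points grouped per image."""
    fs = FeatureSet(encoder.encoder_id, encoder.dim)
    for key in sorted(points):
        image_id, _ = key
        fs.add(key, encoder(images[image_id], points[key]))
    return fs


# ------------------------------------------------------------- classifier


@dataclass
class TrainedClassifier:
    """One-versus-rest linear scorer: score(x, m) = w_m . x + b_m.

    ``label_order`` fixes the full score-vector layout; labels in it that
    were absent from training keep :data:`SENTINEL_SCORE` and are therefore
    never predicted.
    """

    label_order: tuple[str, ...]
    trained_labels: tuple[str, ...]
    coef: np.ndarray  # (n_trained, dim)
    intercept: np.ndarray  # (n_trained,)
    encoder_id: str = ""
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Scores over ``label_order`` for feature rows ``X``."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef.shape[1]:
            raise ValueError(
                f"feature dim {X.shape[1]} != trained dim {self.coef.shape[1]}"
            )
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        raw = X @ self.coef.T + self.intercept
        out = np.full((X.shape[0], len(self.label_order)), SENTINEL_SCORE)
        cols = [self.label_order.index(lab) for lab in self.trained_labels]
        out[:, cols] = raw
        return out


def train_classifier(
    features,
    labels: Sequence[str],
    reg_strength: float | None = 1.0,
    rng_seed: int = 0,
    label_order: Sequence[str] | None = None,
    encoder_id: str = "",
) -> TrainedClassifier:
    """Fit a one-versus-rest linear maximum-margin classifier.

    ``features`` is an array-like of shape (n, dim) or a list of vectors.
    When ``reg_strength`` is ``None`` the inverse regularisation constant is
    chosen from a small grid on a seeded 80/20 validation split.  Features
    are standardised (mean/scale folded into the stored affine map), so
    scores remain affine in the raw features.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        X = np.stack(list(features))
    y = np.asarray(labels, dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ValueError("one feature vector per label is required")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(
            "training requires >= 2 distinct labels; with a single class, "
            "use a trivial constant predictor instead"
        )
    if label_order is None:
        label_order = tuple(classes)
    else:
        missing = [c for c in classes if c not in label_order]
        if missing:
            raise ValueError(f"training labels outside label_order: {missing}")
        label_order = tuple(label_order)

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    def fit(C: float, Xf: np.ndarray, yf: np.ndarray) -> LinearSVC:
        clf = LinearSVC(C=C, random_state=rng_seed, dual=False, max_iter=5000)
        clf.fit(Xf, yf)
        return clf

    if reg_strength is None:
        rng = np.random.default_rng(rng_seed)
        idx = rng.permutation(len(y))
        n_val = max(1, len(y) // 5)
        val, tr = idx[:n_val], idx[n_val:]
        best_C, best_acc = 1.0, -1.0
        if len(set(y[tr])) < 2:  # tiny inputs: fall back to default C
            tr, val = idx, idx
        for C in (0.01, 0.1, 1.0, 10.0):
            clf = fit(C, Xs[tr], y[tr])
            acc = float(np.mean(clf.predict(Xs[val]) == y[val]))
            if acc > best_acc:
                best_C, best_acc = C, acc
        reg_strength = best_C
    svc = fit(float(reg_strength), Xs, y)

    coef, intercept = svc.coef_, svc.intercept_
    if len(classes) == 2:
        # scikit-learn stores the single separating direction; expand to a
        # symmetric two-row one-vs-rest form so argmax semantics hold
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
    return TrainedClassifier(
        label_order=label_order,
        trained_labels=tuple(svc.classes_),
        coef=coef,
        intercept=intercept,
        encoder_id=encoder_id,
        feature_mean=mean,
        feature_scale=scale,
    )


# ----------------------------------------------------------- score matrix


class ScoreMatrix:
    """Per-point score vectors over an ordered label vocabulary."""

    def __init__(
        self, labels: Sequence[str], scores: Mapping[Key, np.ndarray] | None = None
    ) -> None:
        self.labels = tuple(labels)
        self._scores: dict[Key, np.ndarray] = {}
        if scores:
            for k, v in scores.items():
                self.add(k, v)

    def add(self, key: Key, vec) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (len(self.labels),):
            raise ValueError(
                f"score vector length {vec.shape} != {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError("score vectors must be finite")
        self._scores[key] = vec

    def keys(self) -> list[Key]:
        return sorted(self._scores)

    def __len__(self) -> int:
        return len(self._scores)

    def __getitem__(self, key: Key) -> np.ndarray:
        return self._scores[key]

    def max_score(self, key: Key) -> float:
        return float(self._scores[key].max())

    def max_scores(self) -> dict[Key, float]:
        return {k: float(v.max()) for k, v in self._scores.items()}

    def argmax_label(self, key: Key) -> str:
        # ties break toward the earlier label in the vocabulary order
        return self.labels[int(np.argmax(self._scores[key]))]

    def top_labels(self, key: Key, k: int) -> list[str]:
        vec = self._scores[key]
        order = np.argsort(-vec, kind="stable")
        return [self.labels[i] for i in order[:k]]

    # --------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        keys = self.keys()
        df = pd.DataFrame(
            [self._scores[k] for k in keys],
            columns=[f"score_{lab}" for lab in self.labels],
        )
        df.insert(0, "point_index", [k[1] for k in keys])
        df.insert(0, "image_id", [k[0] for k in keys])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreMatrix":
        df = pd.read_csv(path, dtype={"image_id": str})
        score_cols = [c for c in df.columns if c.startswith("score_")]
        labels = [c[len("score_") :] for c in score_cols]
        sm = cls(labels)
        for rec in df.itertuples(index=False):
            key = (rec.image_id, int(rec.point_index))
            sm.add(key, np.array([getattr(rec, c) for c in score_cols]))
        return sm


def score_points(clf: TrainedClassifier, features: FeatureSet) -> ScoreMatrix:
    """Score every keyed feature vector; argmax defines the automated label."""
    if clf.encoder_id and features.encoder_id and clf.encoder_id != features.encoder_id:
        raise ValueError(
            f"encoder mismatch: classifier {clf.encoder_id!r} "
            f"vs features {features.encoder_id!r}"
        )
    sm = ScoreMatrix(clf.label_order)
    keys = features.keys()
    if keys:
        raw = clf.decision_scores(features.matrix(keys))
        for key, row in zip(keys, raw):
            sm.add(key, row)
    return sm


def automated_annotations(
    scores: ScoreMatrix,
    label_set: LabelSet | None = None,
    annotator_id: str = "Automated",
    points: Mapping[Key, tuple[int, int]] | None = None,
) -> AnnotationSet:
    """Argmax labels of a score matrix as an annotation set.

    Ties break toward the earlier label in the score matrix's label order.
    ``points`` optionally supplies pixel coordinates for the keys.
    """
    ls = label_set or LabelSet(scores.labels)
    out = AnnotationSet(annotator_id, ls)
    for key in scores.keys():
        rc = points.get(key) if points else None
        row, col = rc if rc is not None else (None, None)
        out.add(PointAnnotation(key[0], key[1], row, col, scores.argmax_label(key)))
    return out
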