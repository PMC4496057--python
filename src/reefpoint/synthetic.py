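"""Synthetic benthic-like imagery, simulated annotators, simulated scores.

Real photoquadrats come with no pixel-level ground truth, so every stage of
the annotation pipeline is exercised here on surrogates that do:

* :func:`generate_mosaic` renders a Voronoi partition of the canvas into
  contiguous textured regions — each class has a base colour and an
  oriented sinusoidal texture — together with an exact per-pixel label map.
* :func:`simulate_annotator` draws a human-like labelling from a
  row-stochastic confusion matrix applied independently per point.
* :func:`simulate_scores` emulates a one-versus-rest classifier whose
  maximum score is informative of correctness: the argmax label follows a
  confusion row, and the max score is drawn from one normal distribution
  when the argmax is right and a lower-mean one when it is wrong.  That
  separation is precisely the premise that makes confidence-based deferral
  worthwhile.

All generators take explicit seeds and never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .confusion import ConfusionMatrix
from .core import AnnotationSet, PointAnnotation
from .labelset import LabelSet

__all__ = [
    "ClassAppearance",
    "MosaicSpec",
    "AnnotatorSpec",
    "ScoreSimSpec",
    "default_palette",
    "generate_mosaic",
    "annotate_truth",
    "simulate_annotator",
    "simulate_scores",
]


@dataclass(frozen=True)
class ClassAppearance:
    """Rendering parameters of one substratum class.

    ``color`` is the RGB base colour in [0, 1]; the texture is a sinusoid
    of the given spatial frequency (cycles/px) and orientation (radians)
    with amplitude ``texture_amp`` added to all channels.
    """

    name: str
    color: tuple[float, float, float]
    texture_freq: float = 0.1
    texture_orient: float = 0.0
    texture_amp: float = 0.08


def default_palette(
    n_classes: int = 4, separation: float = 1.0
) -> list[ClassAppearance]:
    """Evenly spread class appearances.

    ``separation`` in [0, 1] scales how far base colours spread from
    mid-grey *and* how much the per-class texture frequency and orientation
    diverge; at 0 every class renders identically, so classification is at
    chance by construction."""
    base = np.array([0.5, 0.5, 0.5])
    anchors = np.array(
        [
            [0.85, 0.35, 0.30],  # coral-like pink
            [0.25, 0.55, 0.30],  # algal green
            [0.75, 0.65, 0.80],  # pale CCA mauve
            [0.80, 0.75, 0.55],  # sandy ochre
            [0.30, 0.40, 0.70],
            [0.60, 0.30, 0.60],
            [0.35, 0.65, 0.65],
            [0.70, 0.50, 0.25],
        ]
    )
    if n_classes > len(anchors):
        raise ValueError(f"at most {len(anchors)} default classes")
    out = []
    for i in range(n_classes):
        color = tuple(base + separation * (anchors[i] - base))
        out.append(
            ClassAppearance(
                name=f"class{i}",
                color=color,
                texture_freq=0.08 + 0.05 * i * separation,
                texture_orient=np.pi * i * separation / max(1, n_classes),
            )
        )
    return out


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of one synthetic photoquadrat."""

    width: int = 256
    height: int = 256
    n_regions: int = 12
    classes: tuple[ClassAppearance, ...] = field(
        default_factory=lambda: tuple(default_palette())
    )
    noise_sigma: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.n_regions < len(self.classes):
            raise ValueError("n_regions must be >= number of classes")


def generate_mosaic(spec: MosaicSpec, with_seeds: bool = False):
    """Render a textured Voronoi mosaic and its ground-truth label map.

    Returns ``(image, label_map)``: a uint8 HxWx3 raster and an int HxW
    map of palette indices into ``spec.classes``.  Every pixel's class is
    that of its nearest region seed; each class appears in at least one
    region.  Deterministic for a given spec.  ``with_seeds`` additionally
    returns ``(seeds, region_class)`` for partition auditing.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w, k = spec.height, spec.width, spec.n_regions
    seeds = np.column_stack(
        [rng.uniform(0, h, size=k), rng.uniform(0, w, size=k)]
    )
    n_cls = len(spec.classes)
    # first one region per class, remaining regions random
    region_class = np.concatenate(
        [np.arange(n_cls), rng.integers(0, n_cls, size=k - n_cls)]
    )
    rng.shuffle(region_class)
    rows, cols = np.mgrid[0:h, 0:w]
    grid = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    _, nearest = cKDTree(seeds).query(grid)
    label_map = region_class[nearest].reshape(h, w)

    image = np.zeros((h, w, 3))
    y = rows.astype(float)
    x = cols.astype(float)
    for idx, cls in enumerate(spec.classes):
        mask = label_map == idx
        if not mask.any():
            continue
        phase = 2 * np.pi * cls.texture_freq * (
            x * np.cos(cls.texture_orient) + y * np.sin(cls.texture_orient)
        )
        tex = cls.texture_amp * np.sin(phase)
        for ch in range(3):
            image[:, :, ch][mask] = cls.color[ch] + tex[mask]
    image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    raster = (image * 255).round().astype(np.uint8)
    if with_seeds:
        return raster, label_map, seeds, region_class
    return raster, label_map


def annotate_truth(
    label_map: np.ndarray,
    points,
    class_names,
    image_id: str = "img",
    label_set: LabelSet | None = None,
    annotator_id: str = "Archived",
) -> AnnotationSet:
    """Read ground-truth labels off the map at the given (row, col) points."""
    class_names = [
        c.name if isinstance(c, ClassAppearance) else str(c) for c in class_names
    ]
    ls = label_set or LabelSet(tuple(class_names))
    out = AnnotationSet(annotator_id, ls)
    h, w = label_map.shape
    for k, (row, col) in enumerate(points):
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"point ({row}, {col}) out of bounds for {h}x{w} map")
        out.add(
            PointAnnotation(image_id, k, row, col, class_names[label_map[row, col]])
        )
    return out


@dataclass(frozen=True)
class AnnotatorSpec:
    """A simulated human annotator: a confusion matrix and a seed."""

    confusion: ConfusionMatrix
    rng_seed: int = 0


def simulate_annotator(truth: AnnotationSet, spec: AnnotatorSpec) -> AnnotationSet:
    """Draw each point's label from its true label's confusion row."""
    labels = spec.confusion.labels
    rates = spec.confusion.rates
    row_of = {lab: i for i, lab in enumerate(labels)}
    missing = sorted({l for l in truth.labels() if l not in row_of})
    if missing:
        raise ValueError(f"truth labels without a confusion row: {missing}")
    zero = set(spec.confusion.zero_rows)
    bad = sorted({l for l in truth.labels() if l in zero})
    if bad:
        raise ValueError(f"confusion rows with no probability mass: {bad}")
    rng = np.random.default_rng(spec.rng_seed)
    keys = truth.keys()
    true_rows = np.array([row_of[truth.label(k)] for k in keys])
    # one categorical draw per point via inverse-cdf on the point's row
    cdf = np.cumsum(rates, axis=1)
    u = rng.random(len(keys))
    drawn = (u[:, None] > cdf[true_rows]).sum(axis=1)
    new = {k: labels[j] for k, j in zip(keys, drawn)}
    out = AnnotationSet(f"sim-{spec.rng_seed}", truth.label_set)
    for k in keys:
        ann = truth[k]
        out.add(PointAnnotation(ann.image_id, ann.point_index, ann.row, ann.col, new[k]))
    return out


@dataclass(frozen=True)
class ScoreSimSpec:
    """Simulated classifier scores with correctness-informative maxima.

    The argmax label follows ``confusion``; the maximum score is
    ``Normal(mu_correct, sigma)`` when the argmax equals the true label and
    ``Normal(mu_error, sigma)`` otherwise.  ``mu_correct`` may not fall
    below ``mu_error``; setting them equal gives the degenerate case of an
    uninformative maximum (confidence-based deferral then buys nothing).
    """

    confusion: ConfusionMatrix
    mu_correct: float = 2.0
    mu_error: float = 0.0
    sigma: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_correct < self.mu_error:
            raise ValueError("mu_correct must not be below mu_error")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def simulate_scores(truth: AnnotationSet, spec: ScoreSimSpec) -> "ScoreMatrix":
    """Emulate one-versus-rest score vectors for every truth point."""
    from .annotator import ScoreMatrix  # local import to avoid a cycle

    labels = spec.confusion.labels
    rates = spec.confusion.rates
    row_of = {lab: i for i, lab in enumerate(labels)}
    rng = np.random.default_rng(spec.rng_seed)
    keys = truth.keys()
    true_rows = np.array([row_of[truth.label(k)] for k in keys])
    cdf = np.cumsum(rates, axis=1)
    u = rng.random(len(keys))
    argmax = (u[:, None] > cdf[true_rows]).sum(axis=1)
    correct = argmax == true_rows
    mu = np.where(correct, spec.mu_correct, spec.mu_error)
    mx = rng.normal(mu, spec.sigma)
    # remaining labels sit below the max by random positive gaps
    gaps = rng.uniform(0.05, 1.0, size=(len(keys), len(labels))) * max(
        spec.sigma, 0.1
    )
    vecs = mx[:, None] - gaps
    vecs[np.arange(len(keys)), argmax] = mx
    sm = ScoreMatrix(labels)
    for k, v in zip(keys, vecs):
        sm.add(k, v)
    return sm
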