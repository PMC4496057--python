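"""Annotation data model, CSV I/O, and survey pre-/post-processing rules.

The central container is :class:`AnnotationSet`: one annotator's labels at a
set of ``(image_id, point_index)`` keys.  On top of it live the rules a
multi-annotator survey needs before analysis:

* :func:`remap_labels` — many-to-one vocabulary reconciliation;
* :func:`harmonize_transect_hardware` — majority rule that propagates a
  "Transect hardware" call made by at least ``threshold`` annotators to all
  annotators at that point;
* :func:`rebalance_reference` — discard a random subset of out-of-group
  training annotations so that the group's proportion rises by a chosen
  relative amount (a guard against training and deployment data sharing
  identical class priors by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .labelset import LabelSet

__all__ = [
    "PointAnnotation",
    "AnnotationSet",
    "AnnotationFormatError",
    "AnnotationValidationError",
    "read_annotations",
    "write_annotations",
    "remap_labels",
    "harmonize_transect_hardware",
    "rebalance_reference",
]

Key = tuple[str, int]

_COLUMNS = ["image_id", "point_index", "row", "col", "label"]


class AnnotationFormatError(ValueError):
    """Malformed annotation table (missing columns, bad types)."""


class AnnotationValidationError(ValueError):
    """Annotation content violates the label-set or set invariants."""


@dataclass(frozen=True)
class PointAnnotation:
    """A single labelled point location.

    ``row``/``col`` are 0-based pixel coordinates with row 0 at the image
    top; they may be ``None`` for derived sets (e.g. automated labels
    produced from a score matrix) where geometry is not tracked.
    """

    image_id: str
    point_index: int
    row: int | None
    col: int | None
    label: str

    def __post_init__(self) -> None:
        if self.point_index < 0:
            raise AnnotationValidationError(
                f"point_index must be >= 0, got {self.point_index}"
            )
        for name in ("row", "col"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise AnnotationValidationError(f"{name} must be >= 0, got {v}")


class AnnotationSet:
    """One annotator's labels over a collection of image points.

    Keys are ``(image_id, point_index)``; at most one annotation per key.
    All labels must belong to the set's :class:`~reefpoint.labelset.LabelSet`.
    """

    def __init__(
        self,
        annotator_id: str,
        label_set: LabelSet,
        annotations: Iterable[PointAnnotation] = (),
    ) -> None:
        self.annotator_id = str(annotator_id)
        self.label_set = label_set
        self._points: dict[Key, PointAnnotation] = {}
        for ann in annotations:
            self.add(ann)

    def add(self, ann: PointAnnotation) -> None:
        if ann.label not in self.label_set:
            raise AnnotationValidationError(
                f"label {ann.label!r} not in label-set of {self.annotator_id!r}"
            )
        key = (ann.image_id, ann.point_index)
        if key in self._points:
            raise AnnotationValidationError(f"duplicate annotation at {key}")
        self._points[key] = ann

    # ------------------------------------------------------------ accessors
    def keys(self) -> list[Key]:
        return sorted(self._points)

    def __iter__(self) -> Iterator[PointAnnotation]:
        for k in self.keys():
            yield self._points[k]

    def __len__(self) -> int:
        return len(self._points)

    def __contains__(self, key: Key) -> bool:
        return key in self._points

    def __getitem__(self, key: Key) -> PointAnnotation:
        return self._points[key]

    def label(self, key: Key) -> str:
        return self._points[key].label

    def labels(self, keys: Sequence[Key] | None = None) -> list[str]:
        if keys is None:
            keys = self.keys()
        return [self._points[k].label for k in keys]

    def image_ids(self) -> list[str]:
        return sorted({k[0] for k in self._points})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.annotator_id == other.annotator_id
            and self._points == other._points
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AnnotationSet({self.annotator_id!r}, {len(self)} points, "
            f"{len(self.image_ids())} images)"
        )

    def replace_labels(
        self, new_labels: Mapping[Key, str], annotator_id: str | None = None
    ) -> "AnnotationSet":
        """Copy with some labels substituted (keys not listed are kept)."""
        out = AnnotationSet(annotator_id or self.annotator_id, self.label_set)
        for key, ann in self._points.items():
            lab = new_labels.get(key, ann.label)
            out.add(replace(ann, label=lab))
        return out

    def subset(self, keys: Iterable[Key]) -> "AnnotationSet":
        out = AnnotationSet(self.annotator_id, self.label_set)
        for k in keys:
            out.add(self._points[k])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a.image_id, a.point_index, a.row, a.col, a.label) for a in self
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)


# ---------------------------------------------------------------------- I/O


def read_annotations(
    path,
    label_set: LabelSet,
    annotator_id: str = "annotator",
    apply_remaps: bool = True,
) -> AnnotationSet:
    """Read a delimited annotation table into a validated set.

    The file must carry the header ``image_id,point_index,row,col,label``.
    Labels are passed through the label-set's remaps (when ``apply_remaps``)
    before validation; any label that is neither declared nor remappable is
    reported with its 1-based data row number.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "label": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing required columns {missing}"
        )
    out = AnnotationSet(annotator_id, label_set)
    bad: list[tuple[int, str]] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        label = label_set.resolve(rec.label) if apply_remaps else rec.label
        if label not in label_set:
            bad.append((i, rec.label))
            continue
        row = None if pd.isna(rec.row) else int(rec.row)
        col = None if pd.isna(rec.col) else int(rec.col)
        out.add(
            PointAnnotation(str(rec.image_id), int(rec.point_index), row, col, label)
        )
    if bad:
        listing = ", ".join(f"row {i}: {lab!r}" for i, lab in bad[:20])
        raise AnnotationValidationError(
            f"{path}: {len(bad)} unknown label(s): {listing}"
        )
    return out


def write_annotations(annset: AnnotationSet, path) -> None:
    """Write the set as a CSV round-trippable by :func:`read_annotations`."""
    df = annset.to_frame()
    df["row"] = df["row"].astype("Int64")
    df["col"] = df["col"].astype("Int64")
    df.to_csv(path, index=False)


# ------------------------------------------------------------ processing


def remap_labels(
    annset: AnnotationSet, remap: Sequence[tuple[str, str]]
) -> AnnotationSet:
    """Apply a many-to-one label substitution; point count is unchanged."""
    declared = set(annset.label_set.labels)
    bad = [t for _, t in remap if t not in declared]
    if bad:
        raise AnnotationValidationError(f"remap targets not in label-set: {bad}")
    table = dict(remap)
    new = {
        key: table[ann.label]
        for key, ann in zip(annset.keys(), annset)
        if ann.label in table
    }
    return annset.replace_labels(new)


def harmonize_transect_hardware(
    sets: Sequence[AnnotationSet],
    threshold: int = 2,
    hardware_label: str = "Transect hardware",
) -> list[AnnotationSet]:
    """Propagate majority "Transect hardware" calls to every annotator.

    Wherever at least ``threshold`` of the sets carry ``hardware_label`` at
    a point, all sets are rewritten to carry it there.  The rule corrects
    annotators who labelled the substratum they inferred to lie beneath the
    hardware.  Idempotent: applying it twice changes nothing further.
    """
    if not sets:
        return []
    keys = sets[0].keys()
    for s in sets[1:]:
        if s.keys() != keys:
            raise AnnotationValidationError(
                "annotation sets do not share (image_id, point_index) keys"
            )
    counts = {
        key: sum(s.label(key) == hardware_label for s in sets) for key in keys
    }
    forced = {k: hardware_label for k, c in counts.items() if c >= threshold}
    return [s.replace_labels(forced) for s in sets]


def rebalance_reference(
    annset: AnnotationSet,
    group: str | Sequence[str],
    increase: float = 0.10,
    rng_seed: int = 0,
) -> AnnotationSet:
    """Discard random out-of-group annotations to raise the group proportion.

    With ``C`` in-group and ``N`` out-of-group annotations, the group
    proportion is ``p = C/(C+N)``; the target is ``p*(1+increase)``.  All
    in-group annotations are kept, and the retained out-of-group count
    ``N'`` is the integer minimising the distance between the achieved and
    target proportion (ties resolved toward fewer discards).  The discarded
    subset is drawn uniformly at random, reproducibly for a given seed.
    """
    if isinstance(group, str):
        members = set(annset.label_set.group(group))
    else:
        members = set(group)
    keys = annset.keys()
    in_keys = [k for k in keys if annset.label(k) in members]
    out_keys = [k for k in keys if annset.label(k) not in members]
    C, N = len(in_keys), len(out_keys)
    if N == 0:
        raise AnnotationValidationError("no out-of-group annotations to discard")
    p = C / (C + N)
    target = p * (1.0 + increase)
    if target > 1.0:
        raise AnnotationValidationError(
            f"target proportion {target:.4f} exceeds 1; infeasible"
        )
    if increase == 0.0:
        return annset.subset(keys)
    # achieved(N') = C/(C+N') is monotone in N'; check the two integers
    # bracketing the real-valued optimum, ties toward larger N'.
    if target == 0.0:
        n_keep = N
    else:
        exact = C * (1.0 - target) / target
        cands = {min(N, max(0, math.floor(exact))), min(N, max(0, math.ceil(exact)))}
        n_keep = min(
            sorted(cands, reverse=True),
            key=lambda n: abs(C / (C + n) - target),
        )
    rng = np.random.default_rng(rng_seed)
    kept_idx = rng.choice(N, size=n_keep, replace=False)
    kept = {out_keys[i] for i in kept_idx}
    return annset.subset(in_keys + [k for k in out_keys if k in kept])
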