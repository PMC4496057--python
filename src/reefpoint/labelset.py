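"""Label-set definitions for benthic point annotation.

A :class:`LabelSet` is the controlled vocabulary against which every point
annotation is validated.  It carries, besides the ordered label list, two
pieces of survey configuration:

* named *label groups* (functional groups such as ``coral`` or ``turf``)
  used for binary agreement statistics and group cover estimates, and
* dataset-scoped *remaps*, many-to-one label substitutions applied on
  ingest to reconcile a legacy vocabulary with the consensus one (for
  example collapsing coral genera to "Other scleractinians", or mapping
  "Bare space" to crustose coralline algae where bare rock is in practice
  CCA-covered).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "LabelSet",
    "consensus_labelset",
    "CORAL_GENERA",
    "PRESET_REMAPS",
]

#: Scleractinian coral genera resolved individually in the consensus vocabulary.
CORAL_GENERA: tuple[str, ...] = (
    "Acropora",
    "Favia",
    "Favites",
    "Montastraea",
    "Pavona",
    "Platygyra",
    "Pocillopora",
    "Porites",
)

_CONSENSUS_LABELS: tuple[str, ...] = CORAL_GENERA + (
    "Other scleractinians",
    "Millepora",
    "Sponges",
    "Soft coral",
    "Crustose coralline algae",
    "Turf algae",
    "Macroalgae",
    "Sand",
    "Bare space",
    "Transect hardware",
    "Unclear",
    "All other labels",
)

_CONSENSUS_GROUPS: dict[str, tuple[str, ...]] = {
    "coral": CORAL_GENERA + ("Other scleractinians",),
    "macroalgae": ("Macroalgae",),
    "CCA": ("Crustose coralline algae",),
    "turf": ("Turf algae",),
}

#: Named remap presets for survey locations whose legacy vocabulary differs
#: from the consensus one.  ``moorea``: bare rock is CCA-covered there, so
#: "Bare space" folds into CCA.  ``heron``: corals were never resolved to
#: genus, so every genus folds into "Other scleractinians".
PRESET_REMAPS: dict[str, tuple[tuple[str, str], ...]] = {
    "moorea": (("Bare space", "Crustose coralline algae"),),
    "heron": tuple((g, "Other scleractinians") for g in CORAL_GENERA),
}


class LabelSetError(ValueError):
    """Raised for an inconsistent label-set definition."""


@dataclass(frozen=True)
class LabelSet:
    """Ordered label vocabulary with named groups and ingest remaps.

    Parameters
    ----------
    labels:
        Ordered, unique label names.  The order is significant: it fixes the
        column order of score matrices and confusion matrices, and breaks
        score ties.
    groups:
        Mapping from group name to the member labels.  Every member must be
        a declared label.
    remaps:
        ``(source, target)`` pairs applied on ingest.  Targets must be
        declared labels; sources may belong to a foreign vocabulary.
    """

    labels: tuple[str, ...]
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    remaps: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if list(labels).count(l) > 1})
            raise LabelSetError(f"duplicate labels: {dupes}")
        groups = {k: tuple(v) for k, v in dict(self.groups).items()}
        object.__setattr__(self, "groups", groups)
        declared = set(labels)
        for name, members in groups.items():
            missing = [m for m in members if m not in declared]
            if missing:
                raise LabelSetError(
                    f"group {name!r} members not in label-set: {missing}"
                )
        remaps = tuple((str(s), str(t)) for s, t in self.remaps)
        object.__setattr__(self, "remaps", remaps)
        bad_targets = [t for _, t in remaps if t not in declared]
        if bad_targets:
            raise LabelSetError(f"remap targets not in label-set: {bad_targets}")

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def group(self, name: str) -> tuple[str, ...]:
        try:
            return tuple(self.groups[name])
        except KeyError:
            raise LabelSetError(f"no group named {name!r}") from None

    def resolve(self, label: str) -> str:
        """Apply remaps to ``label``; return it unchanged if unmapped."""
        for src, tgt in self.remaps:
            if label == src:
                return tgt
        return label

    def with_remaps(self, remaps: Iterable[tuple[str, str]]) -> "LabelSet":
        """A copy with the given remaps appended (later pairs win on repeats)."""
        return LabelSet(self.labels, self.groups, tuple(remaps) + self.remaps)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "groups": {k: list(v) for k, v in self.groups.items()},
            "remaps": [list(p) for p in self.remaps],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LabelSet":
        return cls(
            tuple(d["labels"]),
            {k: tuple(v) for k, v in d.get("groups", {}).items()},
            tuple(tuple(p) for p in d.get("remaps", [])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LabelSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def consensus_labelset(
    remap_preset: str | None = None,
    extra_remaps: Sequence[tuple[str, str]] = (),
) -> LabelSet:
    """The 20-label consensus vocabulary used across Pacific reef surveys.

    Eight coral genera plus a catch-all scleractinian label, three algal
    functional groups (macroalgae, crustose coralline algae, turf algae) and
    nine further substratum labels.  ``remap_preset`` selects a named entry
    of :data:`PRESET_REMAPS`.
    """
    remaps: tuple[tuple[str, str], ...] = tuple(extra_remaps)
    if remap_preset is not None:
        try:
            remaps = remaps + PRESET_REMAPS[remap_preset]
        except KeyError:
            raise LabelSetError(
                f"unknown remap preset {remap_preset!r}; "
                f"known: {sorted(PRESET_REMAPS)}"
            ) from None
    return LabelSet(_CONSENSUS_LABELS, _CONSENSUS_GROUPS, remaps)
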