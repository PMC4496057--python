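"""Row-stochastic confusion matrices over a label vocabulary.

The same container serves two roles: an evaluation matrix (how one
annotator's labels redistribute another's) and the cross-validated error
model of the automated classifier that the Abundance cover correction
inverts.  Rows index the reference label, columns the assigned label; the
``rates`` view row-normalises the counts, leaving rows with no reference
annotations at zero and flagging them in :attr:`zero_rows`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix"]


class ConfusionMatrix:
    """Integer confusion counts with a row-normalised rate view."""

    def __init__(self, labels: Sequence[str], counts) -> None:
        self.labels = tuple(labels)
        counts = np.asarray(counts)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @classmethod
    def from_pairs(
        cls,
        reference: Sequence[str],
        assigned: Sequence[str],
        labels: Sequence[str],
    ) -> "ConfusionMatrix":
        """Tally (reference, assigned) label pairs over a fixed label order."""
        if len(reference) != len(assigned):
            raise ValueError("reference and assigned label sequences differ in length")
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for r, c in zip(reference, assigned):
            counts[index[r], index[c]] += 1
        return cls(labels, counts)

    # ------------------------------------------------------------- views
    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def zero_rows(self) -> list[str]:
        """Labels with no reference annotations (undefined rates)."""
        return [lab for lab, t in zip(self.labels, self.row_totals) if t == 0]

    @property
    def rates(self) -> np.ndarray:
        """Row-stochastic rates; rows with zero count are left at zero."""
        totals = self.row_totals.astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe[:, None]

    def rates_filled(self) -> np.ndarray:
        """Rates with zero-count rows replaced by the identity row.

        This is the form used before matrix inversion: an unobserved label
        is modelled as classified perfectly, which leaves the corresponding
        cover coordinate untouched by the correction.
        """
        r = self.rates.copy()
        for i, t in enumerate(self.row_totals):
            if t == 0:
                r[i, i] = 1.0
        return r

    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConfusionMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.counts, other.counts
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ConfusionMatrix({len(self.labels)} labels, n={self.counts.sum()})"

    # --------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "reference"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels disagree")
        return cls(tuple(df.columns), df.to_numpy())
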