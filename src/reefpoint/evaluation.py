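"""Agreement statistics, cover errors, and resampling inference.

Agreement between two annotators is summarised by Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),

with ``p_o`` the observed agreement and ``p_e`` the chance agreement under
the two annotators' marginal label distributions; ``kappa_group`` collapses
the vocabulary to a binary in-group / out-of-group task first.  Cover is
the per-image fraction of points on each label; differences against a
reference annotator yield per-image errors ``d``, their mean (bias) ``e``,
and a mean absolute error over a chosen grouping of (survey, label) cells.

Inference on cover differences is nonparametric: a one-sample sign-flip
permutation t-test of zero mean (exact enumeration of all 2^n sign
patterns for small n), Bonferroni-corrected across the compared annotators
and modes, and a percentile-t bootstrap confidence interval.  Standard
nonparametric comparisons (Mann-Whitney U, Kruskal-Wallis, one-sample
Kolmogorov-Smirnov, Pearson correlation) delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .confusion import ConfusionMatrix
from .core import AnnotationSet
from .labelset import LabelSet

__all__ = [
    "CoverTable",
    "CoverDiffSummary",
    "AgreementReport",
    "cover",
    "group_cover",
    "aggregate_proportion",
    "confusion",
    "cohens_kappa",
    "kappa_group",
    "agreement_report",
    "cover_diffs",
    "permutation_mean_test",
    "PermutationTestResult",
    "bootstrap_percentile_t_ci",
    "standard_tests",
]


# ------------------------------------------------------------------ cover


@dataclass
class CoverTable:
    """Per-image cover fractions for one annotator.

    ``frame`` is images x labels; each row sums to 1 for annotation-derived
    covers, while confusion-corrected covers may carry negative entries but
    still conserve the row total.
    """

    annotator_id: str
    frame: pd.DataFrame

    def labels(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def group(self, members: Sequence[str]) -> pd.Series:
        cols = [c for c in self.frame.columns if c in set(members)]
        return self.frame[cols].sum(axis=1)

    def mean_cover(self) -> pd.Series:
        return self.frame.mean(axis=0)


def cover(annset: AnnotationSet, labels: Sequence[str] | None = None) -> CoverTable:
    """Fraction of points per label in each image."""
    if len(annset) == 0:
        raise ValueError("empty annotation set has no cover")
    labels = tuple(labels) if labels is not None else tuple(annset.label_set.labels)
    df = annset.to_frame()
    tab = (
        df.groupby("image_id")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=labels, fill_value=0.0)
    )
    tab.columns.name = None
    return CoverTable(annset.annotator_id, tab)


def group_cover(annset: AnnotationSet, group: str | Sequence[str]) -> pd.Series:
    """Per-image cover of a functional group."""
    members = (
        annset.label_set.group(group) if isinstance(group, str) else tuple(group)
    )
    return cover(annset).group(members)


def aggregate_proportion(annset: AnnotationSet, group: str | Sequence[str]) -> float:
    """Pooled fraction of all points carrying an in-group label."""
    members = set(
        annset.label_set.group(group) if isinstance(group, str) else group
    )
    labs = annset.labels()
    return sum(l in members for l in labs) / len(labs)


# -------------------------------------------------------------- agreement


def _paired_labels(
    reference: AnnotationSet,
    test: AnnotationSet,
    exclude_labels: Sequence[str] = (),
) -> tuple[list[str], list[str]]:
    shared = sorted(set(reference.keys()) & set(test.keys()))
    if exclude_labels:
        drop = set(exclude_labels)
        shared = [
            k
            for k in shared
            if reference.label(k) not in drop and test.label(k) not in drop
        ]
    if not shared:
        raise ValueError("annotation sets share no (image_id, point_index) keys")
    return reference.labels(shared), test.labels(shared)


def confusion(
    reference: AnnotationSet, test: AnnotationSet, label_set: LabelSet
) -> ConfusionMatrix:
    """Counts of reference label r assigned as label c over shared keys."""
    ref, tst = _paired_labels(reference, test)
    return ConfusionMatrix.from_pairs(ref, tst, label_set.labels)


def _kappa_from_sequences(a: Sequence[str], b: Sequence[str]) -> float:
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    labels = set(a) | set(b)
    pa = {lab: sum(x == lab for x in a) / n for lab in labels}
    pb = {lab: sum(x == lab for x in b) / n for lab in labels}
    p_e = sum(pa[lab] * pb[lab] for lab in labels)
    if p_e >= 1.0 - 1e-15:
        # both marginals concentrated on the same single label
        return 1.0 if p_o >= 1.0 - 1e-15 else float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def cohens_kappa(
    reference: AnnotationSet,
    test: AnnotationSet,
    exclude_labels: Sequence[str] = (),
) -> float:
    """Chance-corrected agreement over the shared keys of two sets.

    Points present in only one set are dropped pairwise, as are points
    carrying a label in ``exclude_labels`` for either annotator (useful for
    dropping "Unclear" calls from the comparison).  When both sets are the
    same constant labelling, agreement is perfect and kappa is 1 by
    convention (the chance term is degenerate there).
    """
    ref, tst = _paired_labels(reference, test, exclude_labels)
    return _kappa_from_sequences(ref, tst)


def kappa_group(
    reference: AnnotationSet,
    test: AnnotationSet,
    group: str | Sequence[str],
    exclude_labels: Sequence[str] = (),
) -> float:
    """Kappa of the binary in-group / out-of-group task."""
    members = set(
        reference.label_set.group(group) if isinstance(group, str) else group
    )
    if not members:
        raise ValueError("group is empty")
    ref, tst = _paired_labels(reference, test, exclude_labels)
    collapse = lambda labs: ["in" if l in members else "out" for l in labs]
    return _kappa_from_sequences(collapse(ref), collapse(tst))


@dataclass
class AgreementReport:
    """Kappa on the full vocabulary, per-group kappas, and the confusion."""

    annotator_id: str
    kappa_full: float
    kappa_group: dict[str, float]
    confusion: ConfusionMatrix


def agreement_report(
    reference: AnnotationSet,
    test: AnnotationSet,
    label_set: LabelSet,
    groups: Sequence[str] = ("coral", "macroalgae", "CCA", "turf"),
) -> AgreementReport:
    return AgreementReport(
        annotator_id=test.annotator_id,
        kappa_full=cohens_kappa(reference, test),
        kappa_group={
            g: kappa_group(reference, test, label_set.group(g)) for g in groups
        },
        confusion=confusion(reference, test, label_set),
    )


# ------------------------------------------------------------ cover errors


@dataclass
class CoverDiffSummary:
    """Per-image cover differences against a reference annotator.

    ``d[a]`` is the images x labels difference table for annotator ``a``;
    ``e`` the annotators x labels bias (mean difference over images).
    ``p_value``/``ci_low``/``ci_high`` are filled by :meth:`add_inference`.
    """

    reference: str
    d: dict[str, pd.DataFrame]
    e: pd.DataFrame
    p_value: pd.DataFrame | None = None
    alpha_corrected: float | None = None
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None

    def mae(
        self,
        labels: Sequence[str] | None = None,
        annotators: Sequence[str] | None = None,
    ) -> float:
        """Mean absolute bias over the selected (annotator, label) cells."""
        e = self.e
        if annotators is not None:
            e = e.loc[list(annotators)]
        if labels is not None:
            e = e[list(labels)]
        return float(e.abs().to_numpy().mean())

    def add_inference(
        self,
        n_perm: int = 10_000,
        n_boot: int = 2_000,
        rng_seed: int = 0,
        comparisons: int = 8,
        alpha: float = 0.05,
    ) -> "CoverDiffSummary":
        """Attach permutation p-values and percentile-t intervals per cell."""
        annos = list(self.e.index)
        labels = list(self.e.columns)
        p = pd.DataFrame(index=annos, columns=labels, dtype=float)
        lo = pd.DataFrame(index=annos, columns=labels, dtype=float)
        hi = pd.DataFrame(index=annos, columns=labels, dtype=float)
        for ai, a in enumerate(annos):
            for li, lab in enumerate(labels):
                dvals = self.d[a][lab].to_numpy()
                seed = rng_seed + 1009 * ai + li
                res = permutation_mean_test(
                    dvals, n_perm=n_perm, rng_seed=seed, comparisons=comparisons,
                    alpha=alpha,
                )
                p.loc[a, lab] = res.p_value
                lo.loc[a, lab], hi.loc[a, lab] = bootstrap_percentile_t_ci(
                    dvals, alpha=alpha, n_boot=n_boot, rng_seed=seed
                )
                self.alpha_corrected = res.alpha_corrected
        self.p_value, self.ci_low, self.ci_high = p, lo, hi
        return self


def cover_diffs(
    covers: Mapping[str, CoverTable], reference_annotator: str
) -> CoverDiffSummary:
    """Differences d, per-label bias e for every annotator vs the reference.

    Annotators missing images covered by the reference are compared on
    their common images only (the reference must span every image).
    """
    try:
        ref = covers[reference_annotator].frame
    except KeyError:
        raise ValueError(
            f"reference annotator {reference_annotator!r} not in covers"
        ) from None
    d: dict[str, pd.DataFrame] = {}
    e_rows = {}
    for a, table in covers.items():
        if a == reference_annotator:
            continue
        missing = set(table.frame.index) - set(ref.index)
        if missing:
            raise ValueError(
                f"annotator {a!r} covers images absent from the reference: "
                f"{sorted(missing)[:5]}"
            )
        aligned_ref = ref.loc[table.frame.index, table.frame.columns]
        diff = table.frame - aligned_ref
        d[a] = diff
        e_rows[a] = diff.mean(axis=0)
    e = pd.DataFrame(e_rows).T
    return CoverDiffSummary(reference=reference_annotator, d=d, e=e)


# --------------------------------------------------------------- inference


@dataclass
class PermutationTestResult:
    p_value: float
    alpha_corrected: float
    n: int
    exact: bool


def _t_stat(x: np.ndarray) -> float:
    n = x.size
    m = x.mean()
    s = x.std(ddof=1) if n > 1 else 0.0
    if s == 0.0:
        return 0.0 if m == 0.0 else np.sign(m) * np.inf
    return m / (s / np.sqrt(n))


def permutation_mean_test(
    d: Sequence[float],
    n_perm: int = 10_000,
    rng_seed: int = 0,
    comparisons: int = 8,
    alpha: float = 0.05,
    force_monte_carlo: bool = False,
) -> PermutationTestResult:
    """One-sample sign-flip permutation t-test of zero mean (two-sided).

    The t statistic is recomputed under random sign flips of the data; for
    n <= 12 every one of the 2^n flip patterns is enumerated exactly,
    otherwise ``n_perm`` random patterns are drawn (the observed pattern is
    always counted in numerator and denominator; ``force_monte_carlo``
    disables the exact path for convergence auditing).  ``alpha_corrected`` is
    the Bonferroni-adjusted threshold ``alpha / comparisons`` — 0.00625 for
    the default eight compared annotators and modes.
    """
    x = np.asarray(d, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty difference vector")
    alpha_corrected = alpha / comparisons
    n = x.size
    if np.all(x == 0.0):
        return PermutationTestResult(1.0, alpha_corrected, n, True)
    t_obs = abs(_t_stat(x))
    if n <= 12 and not force_monte_carlo:
        patterns = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
        exact = True
        total = patterns.shape[0]
    else:
        rng = np.random.default_rng(rng_seed)
        patterns = rng.choice((-1, 1), size=(n_perm - 1, n))
        patterns = np.vstack([np.ones((1, n), dtype=int), patterns])
        exact = False
        total = n_perm
    flipped = patterns * x
    with np.errstate(divide="ignore", invalid="ignore"):
        means = flipped.mean(axis=1)
        sds = flipped.std(axis=1, ddof=1) if n > 1 else np.zeros(total)
        ts = np.where(
            sds == 0.0,
            np.where(means == 0.0, 0.0, np.inf),
            np.abs(means) / (sds / np.sqrt(n)),
        )
    hits = int(np.sum(ts >= t_obs - 1e-12))
    return PermutationTestResult(hits / total, alpha_corrected, n, exact)


def bootstrap_percentile_t_ci(
    d: Sequence[float],
    alpha: float = 0.05,
    n_boot: int = 2_000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Percentile-t bootstrap confidence interval for the mean.

    Bootstraps the studentised statistic ``t* = (mean* - mean)/se*`` and
    returns ``(mean - q_{1-alpha/2} se, mean - q_{alpha/2} se)``.  Constant
    input yields the degenerate zero-width interval at that value.
    """
    x = np.asarray(d, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sample")
    m = x.mean()
    if np.all(x == x[0]):
        return (float(x[0]), float(x[0]))
    n = x.size
    se = x.std(ddof=1) / np.sqrt(n)
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = x[idx]
    bm = samples.mean(axis=1)
    bse = samples.std(axis=1, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(bse == 0.0, np.where(bm == m, 0.0, np.sign(bm - m) * np.inf), (bm - m) / bse)
    ts = ts[np.isfinite(ts)]
    if ts.size == 0:
        return (float(m), float(m))
    q_lo, q_hi = np.quantile(ts, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(m - q_hi * se), float(m - q_lo * se))


# ------------------------------------------------- standard test delegation

_TEST_ALIASES = {
    "mann_whitney": "mann_whitney",
    "mannwhitneyu": "mann_whitney",
    "kruskal": "kruskal",
    "kruskal_wallis": "kruskal",
    "ks": "ks",
    "kolmogorov_smirnov": "ks",
    "pearson": "pearson",
}


def standard_tests(test_name: str, *samples, **kwargs) -> tuple[float, float]:
    """Thin delegation to scipy's nonparametric tests and Pearson's r.

    ``mann_whitney`` (two samples), ``kruskal_wallis`` (two or more),
    ``kolmogorov_smirnov`` (one sample against a distribution, default
    ``cdf='norm'``), and ``pearson`` (two paired samples).  Returns the
    (statistic, p-value) pair unchanged.
    """
    try:
        name = _TEST_ALIASES[test_name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown test {test_name!r}; known: {sorted(set(_TEST_ALIASES.values()))}"
        ) from None
    if name == "mann_whitney":
        if len(samples) != 2:
            raise ValueError("Mann-Whitney U requires exactly two samples")
        res = stats.mannwhitneyu(*samples, **kwargs)
    elif name == "kruskal":
        if len(samples) < 2:
            raise ValueError("Kruskal-Wallis requires at least two samples")
        res = stats.kruskal(*samples, **kwargs)
    elif name == "ks":
        if len(samples) != 1:
            raise ValueError("one-sample Kolmogorov-Smirnov requires one sample")
        kwargs.setdefault("cdf", "norm")
        res = stats.kstest(samples[0], **kwargs)
    else:  # pearson
        if len(samples) != 2:
            raise ValueError("Pearson correlation requires two paired samples")
        res = stats.pearsonr(*samples, **kwargs)
    return (float(res.statistic), float(res.pvalue))
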