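import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reefpoint.annotator import FeatureSet, ScoreMatrix
from reefpoint.confusion import ConfusionMatrix
from reefpoint.core import AnnotationSet, PointAnnotation
from reefpoint.labelset import LabelSet
from reefpoint.modes import (
    abundance_correct,
    abundance_mode,
    alleviate,
    alleviation_curve,
    epsilon_for_level,
    estimate_confusion_cv,
    refine_suggestions,
)
from reefpoint import evaluation

from conftest import make_annset


def _score_matrix(max_scores, labels=("A", "B")):
    """One point per max score; the max sits on label A, rest trail by 1."""
    sm = ScoreMatrix(labels)
    for k, mx in enumerate(max_scores):
        vec = np.full(len(labels), mx - 1.0)
        vec[0] = mx
        sm.add(("img", k), vec)
    return sm


@pytest.fixture
def toy_human(toy_ls):
    def make(n):
        return make_annset(["B"] * n, toy_ls, annotator_id="Host")

    return make


class TestAlleviate:
    def test_epsilon_above_all_scores_keeps_human(self, toy_ls, toy_human):
        sm = _score_matrix([0.2, 0.6, 0.9], labels=toy_ls.labels)
        res = alleviate(sm, toy_human(3), epsilon=1.5)
        assert res.level == 0.0
        assert res.annotations.labels() == ["B", "B", "B"]
        assert res.deferred_keys == set(sm.keys())

    def test_epsilon_below_all_scores_is_fully_automated(self, toy_ls, toy_human):
        sm = _score_matrix([0.2, 0.6, 0.9], labels=toy_ls.labels)
        res = alleviate(sm, toy_human(3), epsilon=0.0)
        assert res.level == 1.0
        assert res.annotations.labels() == ["A", "A", "A"]

    def test_mixed_threshold_counts_by_hand(self, toy_ls, toy_human):
        sm = _score_matrix([0.2, 0.6, 0.9], labels=toy_ls.labels)
        res = alleviate(sm, toy_human(3), epsilon=0.5)
        assert res.level == pytest.approx(2 / 3)
        assert res.annotations.labels() == ["B", "A", "A"]
        assert res.deferred_keys == {("img", 0)}

    def test_strict_inequality_at_threshold(self, toy_ls, toy_human):
        sm = _score_matrix([0.5], labels=toy_ls.labels)
        res = alleviate(sm, toy_human(1), epsilon=0.5)
        assert res.level == 0.0  # equal score defers to the human

    def test_key_mismatch_listed(self, toy_ls, toy_human):
        sm = _score_matrix([0.2, 0.6], labels=toy_ls.labels)
        with pytest.raises(ValueError, match="img.*2"):
            alleviate(sm, toy_human(3), epsilon=0.5)

    def test_monotone_automated_subset_in_epsilon(self, toy_ls, toy_human, rng):
        sm = _score_matrix(rng.random(40), labels=toy_ls.labels)
        human = toy_human(40)
        keys = set(sm.keys())
        prev = None
        for eps in (0.1, 0.3, 0.5, 0.7, 0.9):
            auto = keys - alleviate(sm, human, eps).deferred_keys
            if prev is not None:
                assert auto <= prev
            prev = auto


class TestEpsilonForLevel:
    def test_target_zero_returns_global_max(self, toy_ls):
        sm = _score_matrix([1.0, 2.0, 4.0], labels=toy_ls.labels)
        eps = epsilon_for_level(sm, 0.0)
        assert eps == 4.0
        assert alleviate(sm, make_annset(["B"] * 3, toy_ls), eps).level == 0.0

    def test_half_level_on_distinct_scores(self, toy_ls):
        sm = _score_matrix([1.0, 2.0, 3.0, 4.0], labels=toy_ls.labels)
        eps = epsilon_for_level(sm, 0.5)
        assert eps == 2.0
        assert alleviate(sm, make_annset(["B"] * 4, toy_ls), eps).level == 0.5

    def test_tied_scores_resolve_to_lower_level(self, toy_ls):
        sm = _score_matrix([1.0, 1.0, 1.0], labels=toy_ls.labels)
        eps = epsilon_for_level(sm, 0.5)
        res = alleviate(sm, make_annset(["B"] * 3, toy_ls), eps)
        assert res.level == 0.0  # achievable levels are {0, 1}; ties go low

    def test_step_function_scan_matches_enumeration(self, toy_ls, rng):
        mx = rng.random(23)
        sm = _score_matrix(mx, labels=toy_ls.labels)
        human = make_annset(["B"] * 23, toy_ls)
        for target in (0.0, 0.2, 0.5, 0.8, 1.0):
            eps = epsilon_for_level(sm, target)
            achieved = alleviate(sm, human, eps).level
            # no other threshold gets strictly closer
            best = min(
                abs(np.mean(mx > v) - target)
                for v in np.concatenate([mx, [mx.min() - 1]])
            )
            assert abs(achieved - target) == pytest.approx(best)

    def test_empty_matrix_rejected(self, toy_ls):
        with pytest.raises(ValueError, match="empty"):
            epsilon_for_level(ScoreMatrix(toy_ls.labels), 0.5)


class TestAlleviationCurve:
    def _setup(self, toy_ls, rng, n=60):
        truth = make_annset(rng.choice(["A", "B"], n), toy_ls, "Archived")
        human = make_annset(rng.choice(["A", "B"], n), toy_ls, "Host")
        sm = ScoreMatrix(toy_ls.labels)
        for k in range(n):
            sm.add(("img", k), rng.random(3))
        return sm, human, truth

    def test_endpoints_equal_human_and_automated_kappa(self, toy_ls, rng):
        sm, human, truth = self._setup(toy_ls, rng)
        curve = alleviation_curve(sm, human, truth, group=None, grid=(0.0, 1.0))
        from reefpoint.annotator import automated_annotations

        auto = automated_annotations(sm, label_set=toy_ls)
        assert curve[0][1] == evaluation.cohens_kappa(truth, human)
        assert curve[1][1] == evaluation.cohens_kappa(truth, auto)

    def test_group_curve_uses_binary_kappa(self, toy_ls, rng):
        sm, human, truth = self._setup(toy_ls, rng)
        curve = alleviation_curve(sm, human, truth, group=("A",), grid=(0.0,))
        assert curve[0][1] == evaluation.kappa_group(truth, human, ("A",))


def _onehot_features(labels, label_order, images, noise, rng):
    """Linearly separable features: one-hot of the label plus tiny noise."""
    fs = FeatureSet("onehot", len(label_order))
    ls = LabelSet(tuple(label_order))
    ann = AnnotationSet("ref", ls)
    for k, lab in enumerate(labels):
        img = f"i{k % images:02d}"
        vec = np.zeros(len(label_order))
        vec[label_order.index(lab)] = 1.0
        fs.add((img, k), vec + rng.normal(0, noise, len(label_order)))
        ann.add(PointAnnotation(img, k, None, None, lab))
    return fs, ann


class TestConfusionCV:
    def test_separable_features_give_identity_rates(self, rng):
        labels = (["A", "B", "C"] * 20)
        fs, ann = _onehot_features(labels, ("A", "B", "C"), 10, 0.01, rng)
        q = estimate_confusion_cv(fs, ann, folds=5, rng_seed=0)
        assert np.allclose(q.rates, np.eye(3))

    def test_fold_count_equal_to_images_matches_explicit_loo(self, rng):
        from reefpoint.annotator import score_points, train_classifier

        labels = ["A", "B"] * 12
        fs, ann = _onehot_features(labels, ("A", "B"), 6, 0.3, rng)
        q_cv = estimate_confusion_cv(fs, ann, folds=6, rng_seed=0)
        # explicit leave-one-image-out oracle
        counts = np.zeros((2, 2), dtype=int)
        order = ("A", "B")
        for img in sorted({k[0] for k in fs.keys()}):
            test = [k for k in fs.keys() if k[0] == img]
            train = [k for k in fs.keys() if k[0] != img]
            clf = train_classifier(
                fs.matrix(train), ann.labels(train), reg_strength=1.0,
                rng_seed=0, label_order=order,
            )
            pred = score_points(clf, fs.subset(test))
            for k in test:
                counts[order.index(ann.label(k)), order.index(pred.argmax_label(k))] += 1
        assert np.array_equal(q_cv.counts, counts)

    def test_rare_label_warns(self, rng):
        labels = ["A"] * 20 + ["B"] * 20 + ["C"]
        fs, ann = _onehot_features(labels, ("A", "B", "C"), 5, 0.01, rng)
        with pytest.warns(UserWarning, match="fewer images"):
            estimate_confusion_cv(fs, ann, folds=4, rng_seed=0)

    def test_too_many_folds_rejected(self, rng):
        fs, ann = _onehot_features(["A", "B"] * 4, ("A", "B"), 4, 0.1, rng)
        with pytest.raises(ValueError, match="folds"):
            estimate_confusion_cv(fs, ann, folds=10)


class TestAbundanceCorrect:
    def test_identity_confusion_is_noop(self):
        q = ConfusionMatrix(("A", "B"), np.eye(2, dtype=int) * 10)
        cover = np.array([0.3, 0.7])
        assert np.allclose(abundance_correct(q, cover), cover)

    def test_two_label_matrix_algebra_example(self):
        # rates [[0.9, 0.1], [0.2, 0.8]]; mixing [0.5, 0.5] gives [0.55, 0.45]
        q = ConfusionMatrix(("A", "B"), [[9, 1], [2, 8]])
        out = abundance_correct(q, np.array([0.55, 0.45]))
        assert np.allclose(out, [0.5, 0.5], atol=1e-6)

    def test_singular_rates_fall_back_to_pseudo_inverse(self):
        q = ConfusionMatrix(("A", "B"), [[5, 5], [5, 5]])
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            out = abundance_correct(q, np.array([0.5, 0.5]))
        assert np.all(np.isfinite(out))

    def test_non_simplex_cover_rejected(self):
        q = ConfusionMatrix(("A", "B"), np.eye(2, dtype=int))
        with pytest.raises(ValueError, match="sums"):
            abundance_correct(q, np.array([0.5, 0.6]))

    def test_clip_renormalizes_for_display(self):
        q = ConfusionMatrix(("A", "B"), [[9, 1], [2, 8]])
        out = abundance_correct(q, np.array([0.95, 0.05]), clip_negative=True)
        assert np.all(out >= 0) and out.sum() == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        data=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
        diag=st.integers(6, 30),
    )
    def test_mix_then_correct_recovers_simplex_vector(self, data, diag):
        cover = np.array(data) / np.sum(data)
        q = ConfusionMatrix(
            ("A", "B", "C"), np.eye(3, dtype=int) * diag + 1
        )
        mixed = q.rates.T @ cover
        out = abundance_correct(q, mixed)
        assert np.allclose(out, cover, atol=1e-6)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)


class TestAbundanceMode:
    def test_identity_confusion_preserves_covers(self, toy_ls, rng):
        ann = make_annset(rng.choice(toy_ls.labels, 60), toy_ls, "Automated",
                          per_image=10)
        q = ConfusionMatrix(toy_ls.labels, np.eye(3, dtype=int) * 10)
        corrected = abundance_mode(q, ann)
        raw = evaluation.cover(ann, labels=toy_ls.labels)
        assert np.allclose(corrected.frame.to_numpy(), raw.frame.to_numpy())

    def test_mass_conserved_per_image(self, toy_ls, rng):
        ann = make_annset(rng.choice(toy_ls.labels, 80), toy_ls, "Automated",
                          per_image=10)
        q = ConfusionMatrix(toy_ls.labels, np.eye(3, dtype=int) * 8 + 1)
        corrected = abundance_mode(q, ann)
        assert np.allclose(corrected.frame.sum(axis=1), 1.0, atol=1e-6)


class TestRefine:
    def test_full_ranking_when_k_equals_labels(self):
        sm = ScoreMatrix(("A", "B", "C"), {("i", 0): [0.1, 0.9, 0.5]})
        assert refine_suggestions(sm, k=3)[("i", 0)] == ["B", "C", "A"]

    def test_top_two_by_hand(self):
        sm = ScoreMatrix(("A", "B", "C"), {("i", 0): [0.1, 0.9, 0.5]})
        assert refine_suggestions(sm, k=2)[("i", 0)] == ["B", "C"]

    def test_tie_breaks_by_label_order(self):
        sm = ScoreMatrix(("A", "B", "C"), {("i", 0): [0.5, 0.5, 0.5]})
        assert refine_suggestions(sm, k=3)[("i", 0)] == ["A", "B", "C"]

    def test_k_larger_than_vocabulary_rejected(self):
        sm = ScoreMatrix(("A", "B"), {("i", 0): [0.1, 0.2]})
        with pytest.raises(ValueError, match="vocabulary"):
            refine_suggestions(sm, k=3)

    def test_topk_hit_rate_dominates_top1(self, toy_ls, rng):
        truth = make_annset(rng.choice(toy_ls.labels, 200), toy_ls, "Archived")
        sm = ScoreMatrix(toy_ls.labels)
        for k in truth.keys():
            sm.add(k, rng.random(3))
        top1 = refine_suggestions(sm, k=1)
        top2 = refine_suggestions(sm, k=2)
        hit1 = np.mean([truth.label(k) in top1[k] for k in sm.keys()])
        hit2 = np.mean([truth.label(k) in top2[k] for k in sm.keys()])
        assert hit2 >= hit1
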