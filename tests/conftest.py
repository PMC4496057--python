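import numpy as np
import pytest

from reefpoint.core import AnnotationSet, PointAnnotation
from reefpoint.labelset import LabelSet, consensus_labelset


@pytest.fixture(scope="session")
def consensus():
    return consensus_labelset()


@pytest.fixture
def toy_ls():
    """Three plain labels with a one-member group, for hand-sized examples."""
    return LabelSet(("A", "B", "C"), groups={"ab": ("A", "B")})


def make_annset(labels, label_set, annotator_id="x", image_id="img", per_image=None):
    """Annotation set from a flat label sequence (coordinates synthetic).

    ``per_image`` splits the sequence into images of that many points.
    """
    out = AnnotationSet(annotator_id, label_set)
    for k, lab in enumerate(labels):
        if per_image:
            img = f"{image_id}{k // per_image:03d}"
            idx = k % per_image
        else:
            img, idx = image_id, k
        out.add(PointAnnotation(img, idx, k % 7, k % 11, lab))
    return out


@pytest.fixture
def make_set():
    return make_annset


@pytest.fixture(scope="session")
def trained_mosaic_pipeline():
    """Shared small end-to-end artifacts: features, classifier, scores.

    Session-scoped because patch encoding dominates test runtime.
    """
    from reefpoint.workflows import RunConfig, build_synthetic_survey
    from reefpoint.annotator import score_points, train_classifier

    config = RunConfig(
        seed=7, image_size=72, n_regions=8, points_per_image=30,
        n_train_images=8, n_eval_images=5, patch_size=15,
    )
    train = build_synthetic_survey(config, config.n_train_images, 1700, "tr")
    eval_ = build_synthetic_survey(config, config.n_eval_images, 2700, "ev")
    clf = train_classifier(
        train.features.matrix(),
        train.truth.labels(),
        reg_strength=1.0,
        rng_seed=7,
        label_order=eval_.label_order,
        encoder_id=train.features.encoder_id,
    )
    scores = score_points(clf, eval_.features)
    return {
        "config": config,
        "train": train,
        "eval": eval_,
        "clf": clf,
        "scores": scores,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151)
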