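"""Shared fixtures: synthetic slides and a trained hemorrhage classifier.

Everything is generated programmatically and seed-pinned; session scope keeps
the expensive artifacts (slide rendering, SVM teaching) to one build each.
"""

import numpy as np
import pytest

from ki67hotspot import synthetic_slides
from ki67hotspot.pipeline import run_hotspots, train_synthetic_classifier


SLIDE_SEED = 11
CLASSIFIER_SEED = 500


@pytest.fixture(scope="session")
def slide_and_truth():
    params = synthetic_slides.SynthParams(seed=SLIDE_SEED)
    return synthetic_slides.generate_slide(params)


@pytest.fixture(scope="session")
def hemorrhage_svm():
    return train_synthetic_classifier(seed=CLASSIFIER_SEED, n_slides=2)


@pytest.fixture(scope="session")
def pipeline_result(slide_and_truth, hemorrhage_svm):
    img, truth = slide_and_truth
    return run_hotspots(img, truth.params.fov, classifier=hemorrhage_svm,
                        block=8, slide_id="fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def downsample_mask(mask, factor=8):
    H, W = mask.shape
    h, w = H // factor, W // factor
    return mask[:h * factor, :w * factor].reshape(
        h, factor, w, factor).mean(axis=(1, 3)) > 0.5
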