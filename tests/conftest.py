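"""Shared fixtures: synthetic benchmarks at the default study conditions.

The two heavy session fixtures — the 600-tiles-per-class classifier
benchmark and the n=600 simulated survival cohort — are built once and
shared by the unit and acceptance suites.
"""

import numpy as np
import pytest

from histoscore import synthgen, tissue_classifier as tc
from histoscore.signatures import cohort_signatures


@pytest.fixture(scope="session")
def bench():
    """Default tile-classification benchmark: 600/class, 96 px, seed 1."""
    tiles = synthgen.generate_labeled_tiles(600, 96, seed=1)
    train, val, test = tc.split_dataset(tiles, seed=1)
    model = tc.train_classifier(train, val, tc.TrainConfig(seed=1))
    report = tc.evaluate(model, test)
    return {
        "tiles": tiles,
        "train": train,
        "val": val,
        "test": test,
        "model": model,
        "report": report,
    }


def make_default_cohort(seed: int):
    """Default survival cohort at one seed (n=600, 30% censoring)."""
    slides = synthgen.generate_cohort_slides(600, seed)
    X = cohort_signatures(slides)
    spec = synthgen.CohortSpec(n_patients=600, seed=seed)
    cohort = synthgen.simulate_cohort(spec, slides, X=X)
    return X, cohort


@pytest.fixture(scope="session")
def cohort600():
    """The default cohort at its default seed 7."""
    return make_default_cohort(7)


@pytest.fixture(scope="session")
def small_slides():
    """50 heterogeneous slides for generator/signature statistics."""
    return synthgen.generate_cohort_slides(50, seed=11)


@pytest.fixture(scope="session")
def small_model():
    """A quickly trained classifier for map-assembly tests."""
    tiles = synthgen.generate_labeled_tiles(100, 96, seed=0)
    train, val, _ = tc.split_dataset(tiles, seed=0)
    return tc.train_classifier(train, val, tc.TrainConfig(seed=0, max_trees=150))
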