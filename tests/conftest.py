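"""Shared fixtures: tiny simulated cohorts and a quickly-trained predictor.

Unit tests run on deliberately small cohorts and short training schedules —
they exercise contracts and plumbing, not the study conditions (those live in
the acceptance tests).
"""

from __future__ import annotations

import numpy as np
import pytest

import oral2gut as og


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject paired cohort with learnable structure."""
    config = og.SimulationConfig(n_samples=60, n_genera=30, seed=11)
    oral, stool, truth = og.simulate_paired_cohort(config)
    return oral, stool, truth


@pytest.fixture(scope="session")
def trained_predictor(small_cohort):
    """A predictor fitted with a short schedule, for plumbing tests."""
    oral, stool, _ = small_cohort
    predictor = og.GutFromOralPredictor(
        epochs=30, k_folds=2, seed=3
    ).fit(oral, stool)
    return predictor


@pytest.fixture()
def family_pair():
    """Aligned (pred, truth) closed family tables with known errors."""
    rng = np.random.default_rng(5)
    families = [*og.DEFAULT_FAMILIES, "Other"]
    sample_ids = [f"s{i}" for i in range(5)]

    def closed(mat):
        mat = np.clip(mat, 0, None)
        mat = mat * (100.0 / mat.sum(axis=1, keepdims=True))
        mat[:, -1] += 100.0 - mat.sum(axis=1)
        return og.FamilyTable(list(sample_ids), list(families), mat)

    truth = closed(rng.uniform(0.5, 10.0, (5, 13)))
    pred = closed(truth.values + rng.normal(0, 1.0, (5, 13)))
    return pred, truth
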