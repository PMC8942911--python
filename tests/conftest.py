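"""Shared fixtures: bundled counts and the (expensive) joint model fits."""

from __future__ import annotations

import numpy as np
import pytest

from recmodels.datasets import study_counts
from recmodels.htm import build_combined_model, build_joint_experiment_model, data_for_model
from recmodels.mpt import MPTModel, fit_mpt


@pytest.fixture(scope="session")
def counts():
    """Pooled counts reconstructed from the bundled proportion tables."""
    return study_counts()


@pytest.fixture(scope="session")
def count_rows(counts):
    return list(counts.values())


@pytest.fixture(scope="session")
def fit_exp1(count_rows):
    model = build_joint_experiment_model("exp1")
    return fit_mpt(model, data_for_model(model, count_rows), n_starts=20, seed=0)


@pytest.fixture(scope="session")
def fit_exp2(count_rows):
    model = build_joint_experiment_model("exp2")
    return fit_mpt(model, data_for_model(model, count_rows), n_starts=20, seed=1)


@pytest.fixture(scope="session")
def fit_combined(count_rows):
    model = build_combined_model()
    return fit_mpt(model, data_for_model(model, count_rows), n_starts=20, seed=2)


def enumerate_probabilities(model: MPTModel, params: dict[str, float]) -> dict[str, np.ndarray]:
    """Brute-force branch-path enumerator, independent of the engine internals.

    Resolves each slot through the binding by hand and accumulates plain
    Python products branch by branch.
    """
    from recmodels.mpt import Fixed, Free, Scaled

    def slot_value(slot: str) -> float:
        b = model.binding(slot)
        if isinstance(b, Fixed):
            return b.value
        if isinstance(b, Free):
            return params[b.name]
        assert isinstance(b, Scaled)
        return params[b.scale] * params[b.base]

    out = {}
    for tree in model.trees:
        probs = dict.fromkeys(tree.categories, 0.0)
        for branch in tree.branches:
            prod = 1.0
            for slot, complement in branch.factors:
                v = slot_value(slot)
                prod *= (1.0 - v) if complement else v
            probs[branch.category] += prod
        out[tree.name] = np.array([probs[c] for c in tree.categories])
    return out
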