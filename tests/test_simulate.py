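"""Synthetic-data generator: determinism, convergence, presets."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from recmodels.design import ExperimentDesign
from recmodels.htm import class_probabilities
from recmodels.simulate import (
    BASELINE_2HTM,
    BASELINE_UVSDT,
    GeneratorSpec,
    scenario,
    scenario_null_interaction,
    scenario_word_like,
    simulate_2htm,
    simulate_uvsdt,
)
from recmodels.uvsdt import fit_uvsdt

SMALL_DESIGN = ExperimentDesign(
    label="small",
    n_participants={"colour": 4, "category": 4},
    trials_per_item_class={"target": 6, "category_lure": 3, "colour_lure": 3, "critical_lure": 3},
)


def _spec_2htm(params_update=None, design=SMALL_DESIGN, seed=0):
    params = {c: dict(BASELINE_2HTM, **(params_update or {})) for c in design.conditions}
    return GeneratorSpec(model="2htm", params=params, design=design, seed=seed)


class Test2HTMGenerator:
    def test_certain_detection_rates_all_targets_definitely_old(self):
        sim = simulate_2htm(_spec_2htm({"Do": 1.0, "s": 1.0}))
        targets = sim.trials[sim.trials.item_class == "target"]
        assert (targets.rating == 4).all()

    def test_same_seed_reproduces_dataset_exactly(self):
        a = simulate_2htm(_spec_2htm(seed=5))
        b = simulate_2htm(_spec_2htm(seed=5))
        assert a.counts == b.counts
        pd.testing.assert_frame_equal(a.trials, b.trials)
        c = simulate_2htm(_spec_2htm(seed=5), replicate=1)
        assert c.counts != a.counts

    def test_pooled_counts_satisfy_design_totals(self):
        sim = simulate_2htm(_spec_2htm())
        for rc in sim.counts:
            assert rc.total == SMALL_DESIGN.pooled_trials(rc.condition, rc.item_class)
        # pooled counts aggregate the trial table exactly
        for rc in sim.counts:
            sub = sim.trials[
                (sim.trials.condition == rc.condition) & (sim.trials.item_class == rc.item_class)
            ]
            assert tuple(np.bincount(sub.rating - 1, minlength=4)) == rc.counts

    def test_pooled_frequencies_converge_to_tree_probabilities(self):
        big = ExperimentDesign(
            label="big",
            n_participants={"colour": 10},
            trials_per_item_class={"target": 25_000, "category_lure": 25_000,
                                   "colour_lure": 25_000, "critical_lure": 25_000},
        )
        spec = GeneratorSpec(model="2htm", params={"colour": dict(BASELINE_2HTM)},
                             design=big, seed=2)
        sim = simulate_2htm(spec, replicate=0)
        for rc in sim.counts:
            expected = class_probabilities(BASELINE_2HTM, rc.item_class)
            assert np.abs(rc.proportions() - expected).max() < 0.005

    def test_heterogeneity_changes_data_but_keeps_margins(self):
        hom = simulate_2htm(_spec_2htm())
        spec = GeneratorSpec(model="2htm",
                             params={c: dict(BASELINE_2HTM) for c in SMALL_DESIGN.conditions},
                             design=SMALL_DESIGN, seed=0, heterogeneity=30.0)
        het = simulate_2htm(spec)
        assert het.counts != hom.counts
        for rc in het.counts:
            assert rc.total == SMALL_DESIGN.pooled_trials(rc.condition, rc.item_class)


class TestUVSDTGenerator:
    def _spec(self, params_update=None, design=SMALL_DESIGN, seed=0):
        params = {c: dict(BASELINE_UVSDT, **(params_update or {})) for c in design.conditions}
        return GeneratorSpec(model="uvsdt", params=params, design=design, seed=seed)

    def test_null_sensitivity_makes_old_and_new_indistinguishable(self):
        design = ExperimentDesign(
            label="n", n_participants={"colour": 20},
            trials_per_item_class={"target": 100, "category_lure": 100,
                                   "colour_lure": 100, "critical_lure": 100},
        )
        sim = simulate_uvsdt(self._spec({"target": (0.0, 1.0)}, design=design))
        by_class = {rc.item_class: rc.counts for rc in sim.counts}
        table = np.array([by_class["target"], by_class["colour_lure"]])
        assert chi2_contingency(table).pvalue > 0.01

    def test_recovery_of_generating_mean_at_large_n(self):
        design = ExperimentDesign(
            label="n", n_participants={"colour": 1},
            trials_per_item_class={"target": 100_000, "category_lure": 100_000,
                                   "colour_lure": 100_000, "critical_lure": 100_000},
        )
        sim = simulate_uvsdt(self._spec(design=design, seed=9))
        by_class = {rc.item_class: rc for rc in sim.counts}
        fit = fit_uvsdt(by_class["target"], by_class["colour_lure"])
        mu, sigma = BASELINE_UVSDT["target"]
        assert abs(fit.params.mu - mu) < 3 * np.sqrt(fit.cov[0, 0])
        assert abs(fit.params.sigma - sigma) < 3 * np.sqrt(fit.cov[1, 1])

    def test_extreme_criteria_collapse_ratings(self):
        sim = simulate_uvsdt(self._spec({"criteria": (1e6, 2e6, 3e6)}))
        assert (sim.trials.rating == 1).all()


class TestPresets:
    def test_presets_are_seed_reproducible(self):
        for name in ("null-interaction", "word-like", "picture-like"):
            a = simulate_2htm(scenario(name, seed=3))
            b = simulate_2htm(scenario(name, seed=3))
            assert a.counts == b.counts

    def test_word_like_sets_colour_lure_detection_contrast(self):
        spec = scenario_word_like()
        assert spec.params["colour"]["Dn_col"] == 0.35
        assert spec.params["category"]["Dn_col"] == 0.75

    def test_null_preset_has_no_condition_differences(self):
        spec = scenario_null_interaction()
        assert spec.params["colour"] == spec.params["category"]

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown preset"):
            scenario("doors-only")

    def test_invalid_parameter_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            GeneratorSpec(
                model="2htm",
                params={c: dict(BASELINE_2HTM, Do=1.2) for c in SMALL_DESIGN.conditions},
                design=SMALL_DESIGN,
            )
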