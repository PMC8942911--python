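"""Generic MPT engine: probabilities, fitting, tests, bootstrap, model files."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recmodels.htm import build_2htm_trees, build_joint_experiment_model
from recmodels.mpt import (
    Branch,
    MPTModel,
    Tree,
    bootstrap_parameters,
    category_probabilities,
    check_identifiability,
    delta_g2,
    fit_mpt,
    read_eqn,
    write_eqn,
)

from conftest import enumerate_probabilities


def chain_tree(n_cat: int = 4) -> MPTModel:
    """Saturated stick-breaking tree: theta1, (1-theta1)theta2, ..."""
    branches = []
    for i in range(n_cat):
        factors = [(f"t{j}", True) for j in range(i)]
        if i < n_cat - 1:
            factors.append((f"t{i}", False))
        branches.append(Branch(category=str(i), factors=tuple(factors)))
    return MPTModel([Tree("chain", tuple(str(i) for i in range(n_cat)), tuple(branches))])


@pytest.fixture(scope="module")
def joint_model():
    return build_joint_experiment_model()


class TestCategoryProbabilities:
    def test_certain_detection_high_confidence(self):
        model = MPTModel(build_2htm_trees("colour", shared_guessing_scope=""))
        params = dict.fromkeys(model.unit_parameters, 0.5)
        params["Do.colour"] = 1.0
        params["s.colour"] = 1.0
        p = category_probabilities(model, params)["colour:target"]
        assert p == pytest.approx([0, 0, 0, 1], abs=1e-12)

    def test_pure_symmetric_guessing_is_uniform(self):
        model = MPTModel(build_2htm_trees("colour", shared_guessing_scope=""))
        params = dict.fromkeys(model.unit_parameters, 0.5)
        params["Do.colour"] = 0.0
        p = category_probabilities(model, params)["colour:target"]
        assert p == pytest.approx([0.25, 0.25, 0.25, 0.25], abs=1e-12)

    def test_lure_tree_example(self):
        model = MPTModel(build_2htm_trees("colour", shared_guessing_scope=""))
        params = dict.fromkeys(model.unit_parameters, 0.5)
        params.update(
            {"Dn_cat.colour": 0.6, "n_cat.colour": 0.8, "g": 0.2, "a_n": 0.9, "a_o": 0.5}
        )
        p = category_probabilities(model, params)["colour:category_lure"]
        assert p == pytest.approx([0.768, 0.152, 0.04, 0.04], abs=1e-12)

    def test_unbound_parameter_raises(self, joint_model):
        with pytest.raises(KeyError, match="unbound"):
            category_probabilities(joint_model, {"Do.colour": 0.5})

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_probabilities_sum_to_one_and_match_enumerator(self, data, joint_model):
        """Engine output equals a brute-force branch enumerator and is a distribution."""
        params = {
            name: data.draw(st.floats(0.01, 0.99), label=name)
            for name in joint_model.unit_parameters
        }
        probs = category_probabilities(joint_model, params)
        brute = enumerate_probabilities(joint_model, params)
        for tree_name, p in probs.items():
            assert p.sum() == pytest.approx(1.0, abs=1e-10)
            assert (p >= 0).all()
            assert p == pytest.approx(brute[tree_name], abs=1e-12)


class TestFit:
    def test_exact_data_gives_zero_g2_and_recovery(self, joint_model):
        rng = np.random.default_rng(0)
        truth = {n: rng.uniform(0.2, 0.8) for n in joint_model.unit_parameters}
        probs = category_probabilities(joint_model, truth)
        data = {name: 1000 * p for name, p in probs.items()}
        fit = fit_mpt(joint_model, data, n_starts=5, seed=0)
        assert fit.g2 == pytest.approx(0.0, abs=1e-5)
        # the likelihood surface is extremely flat near the optimum, so the
        # parameter tolerance is looser than the G^2 one
        for name, v in truth.items():
            assert fit.estimates[name] == pytest.approx(v, abs=0.01)

    def test_one_parameter_tree_matches_grid_search(self):
        model = chain_tree(3)
        model = model.fix("t1", 0.5)  # leaves t0 as the single free parameter
        counts = {"chain": np.array([30.0, 25.0, 45.0])}
        fit = fit_mpt(model, counts, n_starts=5, seed=0)
        grid = np.arange(1e-6, 1, 1e-6)
        p0, p1, p2 = grid, (1 - grid) * 0.5, (1 - grid) * 0.5
        ll = 30 * np.log(p0) + 25 * np.log(p1) + 45 * np.log(p2)
        assert fit.estimates["t0"] == pytest.approx(grid[np.argmax(ll)], abs=2e-6)

    def test_permutation_invariance(self, joint_model, count_rows):
        from recmodels.htm import data_for_model

        data = data_for_model(joint_model, count_rows)
        shuffled = MPTModel(
            [
                Tree(t.name, t.categories, tuple(reversed(t.branches)))
                for t in reversed(joint_model.trees)
            ],
            joint_model.bindings,
        )
        f1 = fit_mpt(joint_model, data, n_starts=5, seed=0)
        f2 = fit_mpt(shuffled, data, n_starts=5, seed=3)
        assert f2.g2 == pytest.approx(f1.g2, abs=1e-5)

    def test_expected_counts_sum_to_tree_totals(self, fit_exp1):
        for name, exp in fit_exp1.expected.items():
            assert exp.sum() == pytest.approx(fit_exp1.data[name].sum(), abs=1e-8)

    def test_missing_tree_data_rejected(self, joint_model):
        with pytest.raises(ValueError, match="no counts"):
            fit_mpt(joint_model, {})

    def test_overparameterised_model_rejected(self):
        # target + one lure tree with per-tree guessing: 7 parameters, 6 free categories
        model = MPTModel(build_2htm_trees("colour", lure_types=("cat",),
                                          shared_guessing_scope=""))
        data = {t.name: np.array([10.0, 10, 10, 10]) for t in model.trees}
        with pytest.raises(ValueError, match="over-parameterised"):
            fit_mpt(model, data, n_starts=1)


class TestNestedTests:
    def test_constraint_at_ml_value_costs_nothing(self, fit_exp1):
        ml = fit_exp1.estimates["Do.colour.exp1"]
        constrained = fit_exp1.model.fix("Do.colour.exp1", ml)
        refit = fit_mpt(constrained, fit_exp1.data, n_starts=5, seed=0,
                        extra_starts=[fit_exp1.estimates])
        t = delta_g2(fit_exp1, refit)
        assert t.delta_g2 == pytest.approx(0.0, abs=0.01)
        assert t.df == 1

    def test_equality_constraint_never_improves_likelihood(self, joint_model):
        rng = np.random.default_rng(5)
        for seed in range(3):
            data = {
                t.name: rng.multinomial(300, rng.dirichlet(np.ones(4))).astype(float)
                for t in joint_model.trees
            }
            general = fit_mpt(joint_model, data, n_starts=5, seed=seed)
            con = joint_model.equate(["Dn_col.colour", "Dn_col.category"])
            refit = fit_mpt(con, data, n_starts=5, seed=seed,
                            extra_starts=[{n: 0.5 for n in con.free_parameters}])
            assert refit.g2 >= general.g2 - 1e-6

    def test_same_model_twice_is_not_a_nested_comparison(self, fit_exp1):
        with pytest.raises(ValueError, match="at least 1 df"):
            delta_g2(fit_exp1, fit_exp1)


class TestBootstrap:
    def test_zero_resamples_rejected(self):
        model = chain_tree(4)
        with pytest.raises(ValueError, match="B must be positive"):
            bootstrap_parameters(model, {"chain": [40, 30, 20, 10]}, B=0)

    def test_boundary_parameter_gives_truncated_asymmetric_interval(self):
        model = chain_tree(4)
        data = {"chain": np.array([197.0, 1.0, 1.0, 1.0])}  # t0 near 1
        boot = bootstrap_parameters(model, data, B=200, seed=0)
        lo, hi = boot.ci.loc["t0", "lo"], boot.ci.loc["t0", "hi"]
        med = boot.samples["t0"].median()
        assert hi <= 1.0
        assert (hi - med) < (med - lo)


class TestIdentifiability:
    def test_joint_model_has_one_flat_direction(self, joint_model):
        """The shared-guessing joint 2HTM carries an exact rank-1 ridge.

        Perturbing g while rescaling Do, s and every (Dn, n) pair leaves all
        category probabilities unchanged, so the Jacobian rank is 18, one
        short of the 19 nominal parameters.  Fixing g removes the ridge.
        """
        report = check_identifiability(joint_model, n_points=5, seed=0)
        assert report.n_free == 19
        assert report.ranks == (18,) * 5
        assert not report.identified
        fixed = joint_model.fix("g", 0.5)
        report = check_identifiability(fixed, n_points=5, seed=0)
        assert report.n_free == 18
        assert report.identified

    def test_product_parameterisation_detected_as_rank_deficient(self):
        model = MPTModel(
            [
                Tree(
                    "t",
                    ("hit", "miss"),
                    (
                        Branch("hit", (("a", False), ("b", False))),
                        Branch("miss", (("a", False), ("b", True))),
                        Branch("miss", (("a", True),)),
                    ),
                )
            ]
        )
        report = check_identifiability(model, n_points=3, seed=0)
        assert report.n_free == 2
        assert not report.identified
        assert all(r == 1 for r in report.ranks)

    def test_saturated_tree_rank_equals_free_categories(self):
        report = check_identifiability(chain_tree(4), n_points=3, seed=0)
        assert report.n_free == 3
        assert report.identified


class TestEqnFiles:
    def test_round_trip_preserves_structure_and_probabilities(self, joint_model, tmp_path):
        path = tmp_path / "model.eqn"
        write_eqn(joint_model, path)
        back = read_eqn(path)
        assert [t.name for t in back.trees] == [t.name for t in joint_model.trees]
        assert set(back.unit_parameters) == set(joint_model.unit_parameters)
        rng = np.random.default_rng(1)
        params = {n: rng.uniform(0.1, 0.9) for n in joint_model.unit_parameters}
        a = category_probabilities(joint_model, params)
        b = category_probabilities(back, params)
        # category order may differ after reading; compare per label
        cats_a = {t.name: t.categories for t in joint_model.trees}
        cats_b = {t.name: t.categories for t in back.trees}
        for name in a:
            by_label_b = dict(zip(cats_b[name], b[name]))
            for label, pa in zip(cats_a[name], a[name]):
                assert pa == pytest.approx(by_label_b[label], abs=1e-12)

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.eqn"
        path.write_text("1\ntree cat D_o*(2-s)\n")
        with pytest.raises(ValueError, match="malformed factor"):
            read_eqn(path)
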