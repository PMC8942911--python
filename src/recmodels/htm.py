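"""Two-high-threshold (2HTM) model builders and hypothesis tests.

The 2HTM is a discrete-state account of recognition with confidence ratings.
An old item is detected with probability ``Do``; detection yields a
"definitely old" (rating 4) response with probability ``s``, otherwise
"probably old" (rating 3).  An undetected item enters a guessing state:
guessed old with probability ``g`` (high-confidence with ``a_o``), guessed
new otherwise (high-confidence with ``a_n``).  A lure of type *k* is detected
as new with probability ``Dn_k``, answered "definitely new" (rating 1) with
probability ``n_k``, else "probably new" (rating 2); undetected lures share
the same guessing state as undetected targets.  Detection and confidence
parameters are condition-specific; the guessing parameters ``g``, ``a_o``,
``a_n`` are shared across the encoding conditions of an experiment (the
guessing state does not depend on how items were studied), which gives the
joint two-condition model 19 free parameters against 24 free categories
(5 df).  That sharing can be switched off via ``share_guessing``.

Interactions across experiments are tested on the ratio scale: the
colour-condition value of a parameter is rewritten as ``lambda_e`` times its
category-condition value, separately per experiment, and the invariance
``lambda_1 = lambda_2`` is tested with Delta G^2 (1 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .design import ITEM_CLASSES, RatingCounts
from .mpt import (
    Branch,
    MPTFit,
    MPTModel,
    TestResult,
    Tree,
    category_probabilities,
    delta_g2,
    fit_mpt,
)

__all__ = [
    "CONDITIONS",
    "LURE_TYPES",
    "InteractionTest",
    "build_2htm_trees",
    "build_joint_experiment_model",
    "build_combined_model",
    "class_probabilities",
    "data_for_model",
    "tree_name",
    "slot_name",
    "test_parameter_across_conditions",
    "test_parameter_across_lure_types",
    "interaction_test",
    "free_lambda_model",
]

CONDITIONS = ("colour", "category")

#: lure-type token -> item class
LURE_TYPES = {"cat": "category_lure", "col": "colour_lure", "crit": "critical_lure"}

RATINGS = ("1", "2", "3", "4")

#: condition-specific parameters of one condition's four trees
CONDITION_PARAMETERS = ("Do", "s", "Dn_cat", "n_cat", "Dn_col", "n_col", "Dn_crit", "n_crit")

#: guessing-state parameters (shared across conditions by default)
GUESSING_PARAMETERS = ("g", "a_o", "a_n")


def slot_name(param: str, condition: str | None = None, experiment: str | None = None) -> str:
    """Canonical slot name, e.g. ``Dn_col.colour.exp1`` or ``g.exp1`` or ``g``."""
    parts = [param]
    if condition is not None:
        parts.append(condition)
    if experiment is not None:
        parts.append(experiment)
    return ".".join(parts)


def tree_name(condition: str, item_class: str, experiment: str | None = None) -> str:
    return f"{experiment}:{condition}:{item_class}" if experiment else f"{condition}:{item_class}"


def _target_tree(name: str, Do: str, s: str, g: str, a_o: str, a_n: str) -> Tree:
    B = Branch
    return Tree(
        name=name,
        categories=RATINGS,
        branches=(
            B("4", ((Do, False), (s, False))),
            B("3", ((Do, False), (s, True))),
            B("4", ((Do, True), (g, False), (a_o, False))),
            B("3", ((Do, True), (g, False), (a_o, True))),
            B("1", ((Do, True), (g, True), (a_n, False))),
            B("2", ((Do, True), (g, True), (a_n, True))),
        ),
    )


def _lure_tree(name: str, Dn: str, n: str, g: str, a_o: str, a_n: str) -> Tree:
    B = Branch
    return Tree(
        name=name,
        categories=RATINGS,
        branches=(
            B("1", ((Dn, False), (n, False))),
            B("2", ((Dn, False), (n, True))),
            B("4", ((Dn, True), (g, False), (a_o, False))),
            B("3", ((Dn, True), (g, False), (a_o, True))),
            B("1", ((Dn, True), (g, True), (a_n, False))),
            B("2", ((Dn, True), (g, True), (a_n, True))),
        ),
    )


def build_2htm_trees(
    condition: str,
    experiment: str | None = None,
    *,
    lure_types: Sequence[str] = tuple(LURE_TYPES),
    shared_guessing_scope: str | None = None,
) -> list[Tree]:
    """The four trees (target + lures) of one encoding condition.

    ``shared_guessing_scope`` controls the suffix of the guessing slots:
    ``None`` names them per condition; an empty string or experiment label
    shares them across that scope (slots sharing a name share a parameter).
    """
    if shared_guessing_scope is None:
        g, a_o, a_n = (slot_name(p, condition, experiment) for p in GUESSING_PARAMETERS)
    else:
        scope = shared_guessing_scope or None
        g, a_o, a_n = (slot_name(p, experiment=scope) for p in GUESSING_PARAMETERS)
    trees = [
        _target_tree(
            tree_name(condition, "target", experiment),
            slot_name("Do", condition, experiment),
            slot_name("s", condition, experiment),
            g, a_o, a_n,
        )
    ]
    for token in lure_types:
        trees.append(
            _lure_tree(
                tree_name(condition, LURE_TYPES[token], experiment),
                slot_name(f"Dn_{token}", condition, experiment),
                slot_name(f"n_{token}", condition, experiment),
                g, a_o, a_n,
            )
        )
    return trees


def build_joint_experiment_model(
    experiment: str | None = None, *, share_guessing: bool = True
) -> MPTModel:
    """Joint two-condition 2HTM of one experiment: 8 trees, 19 free parameters.

    With ``share_guessing`` (the default) g, a_o, a_n are shared across the
    two encoding conditions, leaving 19 free parameters and 5 df.
    """
    scope = (experiment or "") if share_guessing else None
    trees: list[Tree] = []
    for cond in CONDITIONS:
        trees.extend(build_2htm_trees(cond, experiment, shared_guessing_scope=scope))
    return MPTModel(trees)


def build_combined_model(
    experiments: Sequence[str] = ("exp1", "exp2"), *, share_guessing: bool = True
) -> MPTModel:
    """Concatenation of per-experiment joint models with no cross-experiment sharing."""
    trees: list[Tree] = []
    for exp in experiments:
        trees.extend(build_joint_experiment_model(exp, share_guessing=share_guessing).trees)
    return MPTModel(trees)


def class_probabilities(params: Mapping[str, float], item_class: str) -> np.ndarray:
    """Rating probabilities for one item class under plain 2HTM parameter names.

    ``params`` uses the bare names Do, s, Dn_cat, ..., g, a_o, a_n.
    """
    if item_class not in ITEM_CLASSES:
        raise KeyError(f"unknown item class {item_class!r}")
    if item_class == "target":
        tree = _target_tree("t", "Do", "s", "g", "a_o", "a_n")
    else:
        token = {v: k for k, v in LURE_TYPES.items()}[item_class]
        tree = _lure_tree("t", f"Dn_{token}", f"n_{token}", "g", "a_o", "a_n")
    model = MPTModel([tree])
    return category_probabilities(model, {k: params[k] for k in model.unit_parameters})["t"]


def data_for_model(
    model: MPTModel, counts: Iterable[RatingCounts], experiment: str | None = None
) -> dict[str, np.ndarray]:
    """Arrange RatingCounts rows into the per-tree mapping ``fit_mpt`` expects.

    Rows are matched to trees by (experiment, condition, item_class); the
    ``experiment`` argument overrides empty row labels for single-experiment
    models.
    """
    wanted = {t.name for t in model.trees}
    out: dict[str, np.ndarray] = {}
    for row in counts:
        for name in (
            tree_name(row.condition, row.item_class, row.experiment or experiment),
            tree_name(row.condition, row.item_class),
        ):
            if name in wanted:
                out[name] = row.as_array()
                break
    missing = wanted - set(out)
    if missing:
        raise ValueError(f"no counts for trees: {sorted(missing)}")
    return out


def _experiment_of(fit: MPTFit) -> str | None:
    name = fit.model.trees[0].name
    return name.split(":")[0] if name.count(":") == 2 else None


def test_parameter_across_conditions(
    fit: MPTFit,
    param: str,
    *,
    experiment: str | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> TestResult:
    """Delta G^2 (1 df) for equating one parameter across encoding conditions."""
    if param not in CONDITION_PARAMETERS:
        raise KeyError(f"unknown condition-specific parameter {param!r}")
    experiment = experiment or _experiment_of(fit)
    slots = [slot_name(param, cond, experiment) for cond in CONDITIONS]
    constrained = fit.model.equate(slots)
    refit = fit_mpt(
        constrained, fit.data, n_starts=n_starts, seed=seed,
        extra_starts=[_constrained_start(fit, constrained)],
    )
    return delta_g2(fit, refit)


def test_parameter_across_lure_types(
    fit: MPTFit,
    condition: str,
    type_a: str,
    type_b: str,
    *,
    param: str = "Dn",
    experiment: str | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> TestResult:
    """Delta G^2 for equating detection (or confidence) across two lure types.

    ``type_a == type_b`` is the degenerate no-op constraint and returns a
    zero statistic test against 1 df.
    """
    for t in (type_a, type_b):
        if t not in LURE_TYPES:
            raise KeyError(f"unknown lure type {t!r}")
    experiment = experiment or _experiment_of(fit)
    if type_a == type_b:
        return TestResult(delta_g2=0.0, df=1, p_value=1.0,
                          constrained=(slot_name(f"{param}_{type_a}", condition, experiment),))
    slots = [slot_name(f"{param}_{t}", condition, experiment) for t in (type_a, type_b)]
    constrained = fit.model.equate(slots)
    refit = fit_mpt(
        constrained, fit.data, n_starts=n_starts, seed=seed,
        extra_starts=[_constrained_start(fit, constrained)],
    )
    return delta_g2(fit, refit)


def _constrained_start(fit: MPTFit, constrained: MPTModel) -> dict[str, float]:
    """Warm start for a constrained refit: average the equated estimates."""
    slot_est = fit.slot_estimates
    start: dict[str, float] = {}
    for name in constrained.unit_parameters:
        members = [s for s in constrained.slots
                   if getattr(constrained.binding(s), "name", None) == name]
        vals = [slot_est[s] for s in members if s in slot_est]
        start[name] = float(np.mean(vals)) if vals else 0.5
    for name in constrained.scale_parameters:
        start[name] = 1.0
    return start


@dataclass(frozen=True)
class InteractionTest:
    """Ratio-invariance interaction test across experiments.

    ``lambdas`` are the per-experiment shrinkage factors (colour-condition
    over category-condition value of the parameter) under the unconstrained
    combined model; ``lambda_shared`` is the common factor under the
    invariance constraint whose cost is ``delta_g2`` on 1 df.
    """

    param: str
    lambdas: dict[str, float]
    lambda_shared: float
    delta_g2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        for exp, lam in self.lambdas.items():
            if lam <= 0:
                raise ValueError(f"shrinkage factor for {exp} must be positive, got {lam}")


def free_lambda_model(model: MPTModel, param: str, experiments: Sequence[str]) -> MPTModel:
    """Reparametrize ``param``: colour-condition slot = lambda_e * category slot.

    With one free lambda per experiment this is a pure reparametrization of
    the combined model (identical maximum likelihood); with a single shared
    lambda it encodes ratio invariance.
    """
    out = model
    for exp in experiments:
        out = out.rebind_ratio(
            slot_name(param, "colour", exp),
            f"lam_{param}.{exp}",
            slot_name(param, "category", exp),
        )
    return out


def interaction_test(
    fit: MPTFit,
    param: str,
    *,
    experiments: Sequence[str] = ("exp1", "exp2"),
    n_starts: int = 20,
    seed: int = 0,
) -> InteractionTest:
    """Test whether the colour/category ratio of ``param`` differs across experiments.

    ``fit`` must be a combined-model fit covering both experiments.  The
    lambda-free reparametrization attains the combined model's likelihood
    exactly, so the unconstrained member of the comparison is the combined
    fit itself; the refit imposes a shared lambda.
    """
    slot_est = fit.slot_estimates
    lambdas = {}
    for exp in experiments:
        num = slot_est[slot_name(param, "colour", exp)]
        den = slot_est[slot_name(param, "category", exp)]
        lambdas[exp] = num / den

    constrained = model = fit.model
    for exp in experiments:
        constrained = constrained.rebind_ratio(
            slot_name(param, "colour", exp),
            f"lam_{param}",  # shared across experiments
            slot_name(param, "category", exp),
        )
    start = {n: v for n, v in fit.estimates.items() if n in constrained.unit_parameters}
    start[f"lam_{param}"] = float(np.exp(np.mean(np.log(list(lambdas.values())))))
    refit = fit_mpt(constrained, fit.data, n_starts=n_starts, seed=seed, extra_starts=[start])
    test = delta_g2(fit, refit)
    return InteractionTest(
        param=param,
        lambdas=lambdas,
        lambda_shared=float(refit.estimates[f"lam_{param}"]),
        delta_g2=test.delta_g2,
        df=test.df,
        p_value=test.p_value,
    )
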