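"""Synthetic confidence-rating data from 2HTM or UVSDT generative processes.

The generator mirrors the experiments' designs: two between-subject encoding
conditions, per-participant trial counts over the four item classes, and
4-point confidence responses produced either by the discrete-state 2HTM
branch process or by a continuous-strength unequal-variance signal-detection
process.  Participants are homogeneous by default, matching the
pooled-fitting assumption; an optional beta-distributed heterogeneity knob
perturbs each participant's unit-interval parameters around the condition
values.

Reproducibility uses a counter-based stream: replicate ``r`` of a spec with
seed ``s`` draws from ``np.random.default_rng([s, r])``, so any replicate is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import ExperimentDesign, RatingCounts
from .htm import CONDITION_PARAMETERS, GUESSING_PARAMETERS, class_probabilities

__all__ = [
    "GeneratorSpec",
    "SimulatedData",
    "simulate_2htm",
    "simulate_uvsdt",
    "scenario_null_interaction",
    "scenario_word_like",
    "scenario_picture_like",
    "scenario",
]

#: default design for generated experiments (word-experiment group sizes and
#: per-participant trial counts)
DEFAULT_DESIGN = ExperimentDesign(
    label="sim",
    n_participants={"colour": 27, "category": 26},
    trials_per_item_class={
        "target": 27, "category_lure": 9, "colour_lure": 9, "critical_lure": 9,
    },
)

#: baseline 2HTM parameter values typical of pooled recognition-rating fits
BASELINE_2HTM = {
    "Do": 0.60, "s": 0.85,
    "Dn_cat": 0.55, "n_cat": 0.65,
    "Dn_col": 0.55, "n_col": 0.65,
    "Dn_crit": 0.45, "n_crit": 0.60,
    "g": 0.45, "a_o": 0.40, "a_n": 0.35,
}

#: baseline UVSDT process: per-class (mu, sigma) plus shared criteria
BASELINE_UVSDT = {
    "criteria": (0.4, 1.1, 1.8),
    "target": (2.0, 1.3),
    "category_lure": (0.0, 1.0),
    "colour_lure": (0.0, 1.0),
    "critical_lure": (0.6, 1.0),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """A fully specified generating process for one synthetic experiment.

    ``params`` maps condition -> parameter dict (2HTM names Do..a_n, or the
    UVSDT layout of :data:`BASELINE_UVSDT`).  ``heterogeneity`` is a beta
    concentration kappa: participant parameters are drawn from
    Beta(p*kappa, (1-p)*kappa); ``None`` (default) disables it.
    """

    model: str
    params: Mapping[str, Mapping]
    design: ExperimentDesign = DEFAULT_DESIGN
    n_replicates: int = 1
    seed: int = 0
    heterogeneity: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("2htm", "uvsdt"):
            raise ValueError(f"unknown generating model {self.model!r}")
        missing = set(self.design.conditions) - set(self.params)
        if missing:
            raise ValueError(f"no parameters for conditions: {sorted(missing)}")
        if self.model == "2htm":
            for cond, p in self.params.items():
                for name in CONDITION_PARAMETERS + GUESSING_PARAMETERS:
                    v = p[name]
                    if not 0.0 <= v <= 1.0:  # degenerate boundary processes are allowed
                        raise ValueError(f"{cond}/{name} outside [0, 1]: {v}")


@dataclass(frozen=True)
class SimulatedData:
    """Trial-level table plus the pooled counts ready for fitting."""

    trials: pd.DataFrame  # columns: participant, condition, item_class, rating
    counts: tuple[RatingCounts, ...]
    replicate: int


def _rng_for(spec: GeneratorSpec, replicate: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, replicate])


def _participant_params(
    base: Mapping[str, float], kappa: float | None, rng: np.random.Generator
) -> dict[str, float]:
    if kappa is None:
        return dict(base)
    return {
        k: float(np.clip(rng.beta(v * kappa, (1.0 - v) * kappa), 1e-6, 1 - 1e-6))
        for k, v in base.items()
    }


def simulate_2htm(spec: GeneratorSpec, replicate: int = 0) -> SimulatedData:
    """One replicate of confidence-rating data from the 2HTM branch process.

    Each trial's rating is drawn from the exact branch-probability multinomial
    of its item-class tree (equivalent to sampling every detect/guess split
    independently).  Pooled counts aggregate the trial table exactly.
    """
    if spec.model != "2htm":
        raise ValueError("spec.model must be '2htm'")
    rng = _rng_for(spec, replicate)
    return _simulate(spec, rng, replicate, _rate_probs_2htm)


def simulate_uvsdt(spec: GeneratorSpec, replicate: int = 0) -> SimulatedData:
    """One replicate from the UVSDT strength process (strengths binned by criteria)."""
    if spec.model != "uvsdt":
        raise ValueError("spec.model must be 'uvsdt'")
    rng = _rng_for(spec, replicate)
    return _simulate(spec, rng, replicate, _rate_probs_uvsdt)


def _rate_probs_2htm(params: Mapping, item_class: str) -> np.ndarray:
    return class_probabilities(params, item_class)


def _rate_probs_uvsdt(params: Mapping, item_class: str) -> np.ndarray:
    mu, sigma = params[item_class]
    criteria = np.asarray(params["criteria"], dtype=float)
    from scipy.stats import norm

    cdf = norm.cdf((criteria - mu) / sigma)
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def _simulate(spec, rng, replicate, prob_fn) -> SimulatedData:
    pids: list[np.ndarray] = []
    conds: list[str] = []
    classes: list[str] = []
    ratings_all: list[np.ndarray] = []
    lengths: list[int] = []
    pooled: dict[tuple[str, str], np.ndarray] = {}
    pid = 0
    for cond in spec.design.conditions:
        base = spec.params[cond]
        for _ in range(spec.design.n_participants[cond]):
            pid += 1
            if spec.model == "2htm":
                p_params = _participant_params(base, spec.heterogeneity, rng)
            else:
                p_params = base  # heterogeneity knob applies to unit-interval parameters only
            for cls in spec.design.item_classes:
                n_trials = spec.design.trials_per_item_class[cls]
                probs = prob_fn(p_params, cls)
                ratings = rng.choice(4, size=n_trials, p=probs / probs.sum()) + 1
                pids.append(np.full(n_trials, pid))
                conds.append(cond)
                classes.append(cls)
                lengths.append(n_trials)
                ratings_all.append(ratings)
                key = (cond, cls)
                pooled.setdefault(key, np.zeros(4, dtype=int))
                pooled[key] += np.bincount(ratings - 1, minlength=4)
    trials = pd.DataFrame(
        {
            "participant": np.concatenate(pids),
            "condition": np.repeat(conds, lengths),
            "item_class": np.repeat(classes, lengths),
            "rating": np.concatenate(ratings_all),
        }
    )
    counts = tuple(
        RatingCounts(
            condition=cond,
            item_class=cls,
            counts=tuple(int(c) for c in pooled[(cond, cls)]),
            experiment=spec.design.label,
        )
        for cond in spec.design.conditions
        for cls in spec.design.item_classes
    )
    return SimulatedData(trials=trials, counts=counts, replicate=replicate)


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------


def scenario_null_interaction(
    *, design: ExperimentDesign = DEFAULT_DESIGN, n_replicates: int = 1, seed: int = 0
) -> GeneratorSpec:
    """No condition differences: both conditions at the 2HTM baseline values."""
    return GeneratorSpec(
        model="2htm",
        params={cond: dict(BASELINE_2HTM) for cond in design.conditions},
        design=design,
        n_replicates=n_replicates,
        seed=seed,
    )


def scenario_word_like(
    *,
    dn_col: tuple[float, float] = (0.35, 0.75),
    design: ExperimentDesign = DEFAULT_DESIGN,
    n_replicates: int = 1,
    seed: int = 0,
) -> GeneratorSpec:
    """Word-material pattern: colour-lure detection higher under category encoding.

    ``dn_col`` gives (colour-condition, category-condition) values of Dn_col.
    """
    params = {cond: dict(BASELINE_2HTM) for cond in design.conditions}
    params["colour"]["Dn_col"], params["category"]["Dn_col"] = dn_col
    return GeneratorSpec(model="2htm", params=params, design=design,
                         n_replicates=n_replicates, seed=seed)


def scenario_picture_like(
    *,
    dn_cat: tuple[float, float] = (0.75, 0.45),
    design: ExperimentDesign = DEFAULT_DESIGN,
    n_replicates: int = 1,
    seed: int = 0,
) -> GeneratorSpec:
    """Picture-material pattern: category-lure detection higher under colour encoding."""
    params = {cond: dict(BASELINE_2HTM) for cond in design.conditions}
    params["colour"]["Dn_cat"], params["category"]["Dn_cat"] = dn_cat
    return GeneratorSpec(model="2htm", params=params, design=design,
                         n_replicates=n_replicates, seed=seed)


_SCENARIOS = {
    "null-interaction": scenario_null_interaction,
    "word-like": scenario_word_like,
    "picture-like": scenario_picture_like,
}


def scenario(name: str, **kwargs) -> GeneratorSpec:
    """Look up a named preset scenario."""
    try:
        factory = _SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_SCENARIOS)}") from None
    return factory(**kwargs)
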