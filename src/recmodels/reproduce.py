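"""End-to-end reproduction pipeline on the bundled study tables.

Runs count reconstruction, the pooled UVSDT fits, the joint and combined
2HTM fits, the Delta G^2 battery, and the cross-experiment ratio-invariance
interaction test, then compares each computed quantity with the bundled
published estimate at a fixed tolerance:

* G^2 goodness of fit: ±0.3 (count-reconstruction rounding + optimiser),
* Delta G^2: ±0.5,
* d_a and x_c: ±0.03,
* Wald z: ±0.02,
* descriptives: printed precision.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

from . import __version__
from .datasets import reference_values, study_counts
from .design import descriptives
from .htm import (
    build_combined_model,
    build_joint_experiment_model,
    data_for_model,
    interaction_test,
    test_parameter_across_conditions,
)
from .mpt import bootstrap_parameters, fit_mpt
from .uvsdt import fit_uvsdt, wald_z

__all__ = ["Comparison", "ReproductionReport", "reproduce_paper"]

log = logging.getLogger(__name__)

TOL_G2 = 0.3
TOL_DELTA_G2 = 0.5
TOL_SDT = 0.03
TOL_Z = 0.02
TOL_MEAN_RATING = 0.0005  # printed to 3 dp
TOL_RATE = 0.005  # printed to 2 dp


@dataclass(frozen=True)
class Comparison:
    name: str
    computed: float
    reference: float
    tolerance: float

    @property
    def abs_diff(self) -> float:
        return abs(self.computed - self.reference)

    @property
    def passed(self) -> bool:
        return self.abs_diff <= self.tolerance

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "computed": round(self.computed, 6),
            "reference": self.reference,
            "abs_diff": round(self.abs_diff, 6),
            "tolerance": self.tolerance,
            "passed": self.passed,
        }


@dataclass(frozen=True)
class ReproductionReport:
    comparisons: tuple[Comparison, ...]
    seed: int
    runtime_s: float
    bootstrap_sd: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.comparisons)

    def __getitem__(self, name: str) -> Comparison:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_json(self, *, include_runtime: bool = False) -> str:
        payload: dict = {
            "version": __version__,
            "seed": self.seed,
            "comparisons": [c.as_dict() for c in self.comparisons],
        }
        if self.bootstrap_sd:
            payload["bootstrap_sd"] = {
                exp: {k: round(v, 6) for k, v in sd.items()}
                for exp, sd in self.bootstrap_sd.items()
            }
        if include_runtime:
            payload["runtime_s"] = round(self.runtime_s, 3)
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        width = max(len(c.name) for c in self.comparisons)
        lines = [f"{'comparison':<{width}}  computed  reference   |diff|  tol    ok"]
        for c in self.comparisons:
            lines.append(
                f"{c.name:<{width}}  {c.computed:8.3f}  {c.reference:9.3f}  "
                f"{c.abs_diff:7.3f}  {c.tolerance:<5g}  {'yes' if c.passed else 'NO'}"
            )
        return "\n".join(lines)


def reproduce_paper(
    *, seed: int = 0, n_starts: int = 20, bootstrap_B: int = 0
) -> ReproductionReport:
    """Recompute the study's headline model results and compare with the bundled values.

    Every stage starts from counts reconstructed out of the bundled
    proportion tables; nothing is read from the reference block except for
    the final comparison.  Deterministic for a fixed (seed, n_starts);
    ``bootstrap_B > 0`` additionally runs a parametric bootstrap of each
    joint model and attaches parameter SDs (not compared - the study's
    bootstrap bar values are not published numerically).
    """
    t0 = time.perf_counter()
    ref = reference_values()
    counts = study_counts()
    rows = list(counts.values())
    comparisons: list[Comparison] = []

    # --- descriptives -----------------------------------------------------
    log.info("stage: descriptives")
    mr = descriptives(counts[("exp1", "colour", "target")]).mean_rating
    comparisons.append(Comparison(
        "mean_rating.exp1.colour.target", mr,
        ref["descriptives"]["exp1_colour_target_mean_rating"], TOL_MEAN_RATING,
    ))
    crit = [counts[("exp2", cond, "critical_lure")] for cond in ("colour", "category")]
    fa = sum(descriptives(c).old_rate * c.total for c in crit) / sum(c.total for c in crit)
    comparisons.append(Comparison(
        "false_alarm_rate.exp2.critical_lure", fa,
        ref["descriptives"]["exp2_critical_lure_false_alarm_rate"], TOL_RATE,
    ))

    # --- UVSDT ------------------------------------------------------------
    log.info("stage: UVSDT fits")
    sdt = {}
    for cond in ("colour", "category"):
        sdt[cond] = fit_uvsdt(
            counts[("exp1", cond, "target")], counts[("exp1", cond, "colour_lure")]
        )
    comparisons.append(Comparison(
        "uvsdt_d_a.exp1.category.colour_lure", sdt["category"].d_a,
        ref["uvsdt"]["exp1"]["category"]["colour_lure"]["d_a"], TOL_SDT,
    ))
    comparisons.append(Comparison(
        "uvsdt_x_c.exp1.category.colour_lure", sdt["category"].x_c,
        ref["uvsdt"]["exp1"]["category"]["colour_lure"]["x_c"], TOL_SDT,
    ))
    z = wald_z(sdt["category"].d_a, sdt["category"].se_d_a,
               sdt["colour"].d_a, sdt["colour"].se_d_a)
    comparisons.append(Comparison(
        "wald_z.exp1.d_a.colour_lure", abs(z.z),
        ref["wald_z"]["exp1"]["d_a_colour_lure"], TOL_Z,
    ))

    # --- joint 2HTM fits ---------------------------------------------------
    fits = {}
    for i, exp in enumerate(("exp1", "exp2")):
        log.info("stage: joint 2HTM fit %s", exp)
        model = build_joint_experiment_model(exp)
        fits[exp] = fit_mpt(model, data_for_model(model, rows), n_starts=n_starts, seed=seed + i)
        comparisons.append(Comparison(
            f"g2.{exp}", fits[exp].g2, ref["g2"][exp]["value"], TOL_G2,
        ))

    log.info("stage: combined 2HTM fit")
    combined_model = build_combined_model()
    combined = fit_mpt(combined_model, data_for_model(combined_model, rows),
                       n_starts=n_starts, seed=seed + 2)
    comparisons.append(Comparison(
        "g2.combined", combined.g2, ref["g2"]["combined"]["value"], TOL_G2,
    ))

    # --- Delta G^2 battery --------------------------------------------------
    log.info("stage: condition-equality tests")
    for exp, param in (("exp1", "Do"), ("exp1", "Dn_col"), ("exp2", "Dn_cat")):
        t = test_parameter_across_conditions(fits[exp], param, n_starts=n_starts, seed=seed + 3)
        comparisons.append(Comparison(
            f"delta_g2.{exp}.{param}", t.delta_g2,
            ref["delta_g2"][exp][f"{param}_condition"], TOL_DELTA_G2,
        ))

    log.info("stage: ratio-invariance interaction test")
    it = interaction_test(combined, "Dn_col", n_starts=n_starts, seed=seed + 4)
    comparisons.append(Comparison(
        "delta_g2.interaction.Dn_col", it.delta_g2,
        ref["delta_g2"]["interaction"]["Dn_col"], TOL_DELTA_G2,
    ))

    bootstrap_sd = {}
    if bootstrap_B > 0:
        for exp in ("exp1", "exp2"):
            log.info("stage: bootstrap %s (B=%d)", exp, bootstrap_B)
            boot = bootstrap_parameters(
                fits[exp].model, fits[exp].data, B=bootstrap_B, seed=seed + 5, fit=fits[exp]
            )
            bootstrap_sd[exp] = {k: float(v) for k, v in boot.sd.items()}

    return ReproductionReport(
        comparisons=tuple(comparisons),
        seed=seed,
        runtime_s=time.perf_counter() - t0,
        bootstrap_sd=bootstrap_sd,
    )
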