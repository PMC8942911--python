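"""Generic multinomial processing tree (MPT) machinery.

An MPT model expresses the category probabilities of one or more independent
multinomial "trees" as sums over branches of products of parameters theta and
complements (1 - theta).  This module provides the model representation,
category-probability evaluation, product-multinomial maximum-likelihood
fitting with equality and ratio constraints, the G^2 goodness-of-fit
statistic and nested-model Delta G^2 tests, a parametric bootstrap, a
numeric identifiability check, and a plain-text model-file format in the
spirit of the conventional MPT ".eqn" layout.

Parameter binding
-----------------
Every parameter *slot* named in a branch is, by default, its own free
parameter in (0, 1); slots sharing a name share the parameter.  Bindings can
redirect a slot to a differently named free parameter (equality
constraints), pin it to a constant, or express it as ``scale * base`` where
``scale`` is a free positive factor and ``base`` another free unit-interval
parameter (the ratio reparametrization used for interaction tests).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

__all__ = [
    "Branch",
    "Tree",
    "Free",
    "Fixed",
    "Scaled",
    "MPTModel",
    "MPTFit",
    "TestResult",
    "BootstrapResult",
    "IdentifiabilityReport",
    "category_probabilities",
    "fit_mpt",
    "delta_g2",
    "bootstrap_parameters",
    "check_identifiability",
    "read_eqn",
    "write_eqn",
]

log = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12
_BOUND = 1e-6  # clamp for boundary reporting of unit parameters


@dataclass(frozen=True)
class Branch:
    """One root-to-leaf path: ordered (slot, complement?) factors and a category."""

    category: str
    factors: tuple[tuple[str, bool], ...]


@dataclass(frozen=True)
class Tree:
    """One independent multinomial: named categories and the branches feeding them."""

    name: str
    categories: tuple[str, ...]
    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        unknown = {b.category for b in self.branches} - set(self.categories)
        if unknown:
            raise ValueError(f"tree {self.name!r}: branch categories {unknown} not declared")


@dataclass(frozen=True)
class Free:
    """Slot bound to the free unit-interval parameter ``name``."""

    name: str


@dataclass(frozen=True)
class Fixed:
    """Slot pinned to a constant in [0, 1]."""

    value: float


@dataclass(frozen=True)
class Scaled:
    """Slot equal to ``scale * base``: a positive free factor times a free unit parameter."""

    scale: str
    base: str


Binding = Union[Free, Fixed, Scaled]


class MPTModel:
    """A set of trees plus the binding of parameter slots to free parameters."""

    def __init__(self, trees: Sequence[Tree], bindings: Mapping[str, Binding] | None = None):
        self.trees: tuple[Tree, ...] = tuple(trees)
        if len({t.name for t in self.trees}) != len(self.trees):
            raise ValueError("tree names must be unique")
        self.bindings: dict[str, Binding] = dict(bindings or {})
        unknown = set(self.bindings) - set(self.slots)
        if unknown:
            raise ValueError(f"bindings for unknown slots: {sorted(unknown)}")
        self._compiled: _Compiled | None = None

    # -- structure ----------------------------------------------------------

    @property
    def slots(self) -> tuple[str, ...]:
        """Parameter slots in first-appearance order across trees and branches."""
        seen: dict[str, None] = {}
        for tree in self.trees:
            for branch in tree.branches:
                for slot, _ in branch.factors:
                    seen.setdefault(slot)
        return tuple(seen)

    def binding(self, slot: str) -> Binding:
        return self.bindings.get(slot, Free(slot))

    @property
    def unit_parameters(self) -> tuple[str, ...]:
        """Free unit-interval parameter names, in slot order."""
        seen: dict[str, None] = {}
        for slot in self.slots:
            b = self.binding(slot)
            if isinstance(b, Free):
                seen.setdefault(b.name)
            elif isinstance(b, Scaled):
                seen.setdefault(b.base)
        return tuple(seen)

    @property
    def scale_parameters(self) -> tuple[str, ...]:
        """Free positive scale-factor names, in slot order."""
        seen: dict[str, None] = {}
        for slot in self.slots:
            b = self.binding(slot)
            if isinstance(b, Scaled):
                seen.setdefault(b.scale)
        return tuple(seen)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return self.unit_parameters + self.scale_parameters

    @property
    def n_free_categories(self) -> int:
        return sum(len(t.categories) - 1 for t in self.trees)

    # -- derived models -----------------------------------------------------

    def equate(self, slots: Sequence[str], name: str | None = None) -> "MPTModel":
        """Bind several slots to one shared free parameter (equality constraint)."""
        missing = set(slots) - set(self.slots)
        if missing:
            raise KeyError(f"unknown slots: {sorted(missing)}")
        shared = name or "=".join(slots)
        new = dict(self.bindings)
        new.update({s: Free(shared) for s in slots})
        return MPTModel(self.trees, new)

    def fix(self, slot: str, value: float) -> "MPTModel":
        """Pin a slot to a constant."""
        if slot not in self.slots:
            raise KeyError(f"unknown slot: {slot}")
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"fixed value outside [0, 1]: {value}")
        return MPTModel(self.trees, {**self.bindings, slot: Fixed(value)})

    def rebind_ratio(self, slot: str, scale: str, base_slot: str) -> "MPTModel":
        """Express ``slot`` as ``scale * base_slot`` (ratio reparametrization).

        ``base_slot`` must itself be bound to a free parameter; ``scale`` is a
        new free positive factor, unbounded above (the product is kept inside
        (0, 1) during optimisation).
        """
        for s in (slot, base_slot):
            if s not in self.slots:
                raise KeyError(f"unknown slot: {s}")
        base = self.binding(base_slot)
        if not isinstance(base, Free):
            raise ValueError(f"base slot {base_slot!r} must be bound to a free parameter")
        return MPTModel(self.trees, {**self.bindings, slot: Scaled(scale, base.name)})

    # -- evaluation ---------------------------------------------------------

    def slot_values(self, free: Mapping[str, float]) -> dict[str, float]:
        """Resolve every slot to its numeric value under ``free``."""
        out: dict[str, float] = {}
        for slot in self.slots:
            b = self.binding(slot)
            if isinstance(b, Fixed):
                out[slot] = b.value
            elif isinstance(b, Free):
                out[slot] = float(free[b.name])
            else:
                out[slot] = float(free[b.scale]) * float(free[b.base])
        return out

    def _compile(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled


class _Compiled:
    """Vectorised evaluator: free vector -> per-tree category probabilities."""

    def __init__(self, model: MPTModel):
        self.model = model
        self.slots = model.slots
        self.units = model.unit_parameters
        self.scales = model.scale_parameters
        unit_pos = {n: i for i, n in enumerate(self.units)}
        scale_pos = {n: i for i, n in enumerate(self.scales)}
        slot_pos = {s: i for i, s in enumerate(self.slots)}

        n_slots = len(self.slots)
        self.fixed = np.zeros(n_slots)
        self.unit_idx: list[tuple[int, int]] = []  # (slot index, unit param index)
        self.scaled_idx: list[tuple[int, int, int]] = []  # (slot, scale, base-unit)
        for s, slot in enumerate(self.slots):
            b = model.binding(slot)
            if isinstance(b, Fixed):
                self.fixed[s] = b.value
            elif isinstance(b, Free):
                self.unit_idx.append((s, unit_pos[b.name]))
            else:
                self.scaled_idx.append((s, scale_pos[b.scale], unit_pos[b.base]))

        # branch factor matrix padded with a sentinel slot of value 1
        max_f = max((len(b.factors) for t in model.trees for b in t.branches), default=1)
        rows: list[list[int]] = []
        comps: list[list[bool]] = []
        self.branch_cat: list[int] = []  # global category index
        self.tree_slices: list[tuple[str, slice, int]] = []  # (tree, cat slice, n_cat)
        cat_offset = 0
        branch_tree_cat: list[int] = []
        for tree in model.trees:
            cat_pos = {c: cat_offset + j for j, c in enumerate(tree.categories)}
            for b in tree.branches:
                idx = [slot_pos[s] for s, _ in b.factors] + [n_slots] * (max_f - len(b.factors))
                comp = [c for _, c in b.factors] + [False] * (max_f - len(b.factors))
                rows.append(idx)
                comps.append(comp)
                branch_tree_cat.append(cat_pos[b.category])
            self.tree_slices.append(
                (tree.name, slice(cat_offset, cat_offset + len(tree.categories)), len(tree.categories))
            )
            cat_offset += len(tree.categories)
        self.n_categories = cat_offset
        self.factor_idx = np.asarray(rows, dtype=np.intp)
        self.factor_comp = np.asarray(comps, dtype=bool)
        self.branch_cat_idx = np.asarray(branch_tree_cat, dtype=np.intp)

    def slot_vector(self, x: np.ndarray) -> np.ndarray:
        """Natural-space free vector (units then scales) -> slot values + sentinel 1."""
        u = x[: len(self.units)]
        s = x[len(self.units) :]
        vals = self.fixed.copy()
        for slot_i, unit_i in self.unit_idx:
            vals[slot_i] = u[unit_i]
        for slot_i, scale_i, base_i in self.scaled_idx:
            vals[slot_i] = s[scale_i] * u[base_i]
        return np.concatenate([vals, [1.0]])

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        """Stacked category probabilities over all trees."""
        vals = self.slot_vector(x)
        f = vals[self.factor_idx]
        f = np.where(self.factor_comp, 1.0 - f, f)
        branch_p = f.prod(axis=1)
        return np.bincount(self.branch_cat_idx, weights=branch_p, minlength=self.n_categories)


# ---------------------------------------------------------------------------
# probabilities and likelihood
# ---------------------------------------------------------------------------


def category_probabilities(model: MPTModel, params: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Category probabilities per tree for free-parameter values ``params``."""
    for name in model.unit_parameters:
        if name not in params:
            raise KeyError(f"unbound parameter: {name}")
        if not 0.0 <= params[name] <= 1.0:
            raise ValueError(f"parameter {name} outside [0, 1]: {params[name]}")
    comp = model._compile()
    x = np.array(
        [params[n] for n in comp.units] + [params[n] for n in comp.scales], dtype=float
    )
    stacked = comp.probabilities(x)
    return {name: stacked[sl] for name, sl, _ in comp.tree_slices}


def _align_data(model: MPTModel, data: Mapping[str, Sequence[float]]) -> np.ndarray:
    comp = model._compile()
    missing = [name for name, _, _ in comp.tree_slices if name not in data]
    if missing:
        raise ValueError(f"no counts supplied for trees: {missing}")
    stacked = np.zeros(comp.n_categories)
    for name, sl, n_cat in comp.tree_slices:
        counts = np.asarray(data[name], dtype=float)
        if counts.shape != (n_cat,) or (counts < 0).any():
            raise ValueError(f"tree {name!r}: expected {n_cat} non-negative counts, got {counts}")
        stacked[sl] = counts
    return stacked


def _saturated_loglik(counts: np.ndarray, comp: _Compiled) -> float:
    ll = 0.0
    for _, sl, _ in comp.tree_slices:
        c = counts[sl]
        tot = c.sum()
        nz = c > 0
        ll += float((c[nz] * np.log(c[nz] / tot)).sum())
    return ll


@dataclass(frozen=True)
class MPTFit:
    """Maximum-likelihood MPT fit with G^2 goodness of fit."""

    model: MPTModel = field(repr=False)
    data: dict[str, np.ndarray] = field(repr=False)
    estimates: dict[str, float]
    loglik: float
    g2: float
    df: int
    p_value: float
    converged: bool
    boundary: tuple[str, ...]
    expected: dict[str, np.ndarray] = field(repr=False)

    @property
    def slot_estimates(self) -> dict[str, float]:
        return self.model.slot_values(self.estimates)


@dataclass(frozen=True)
class TestResult:
    """Nested-model likelihood-ratio test."""

    delta_g2: float
    df: int
    p_value: float
    constrained: tuple[str, ...] = ()


@dataclass(frozen=True)
class BootstrapResult:
    """Parametric-bootstrap variability of the free parameters."""

    sd: pd.Series
    ci: pd.DataFrame  # columns lo, hi (2.5 / 97.5 percentiles)
    samples: pd.DataFrame
    n_failed: int


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Numeric-Jacobian rank check at random interior points."""

    n_free: int
    ranks: tuple[int, ...]
    identified: bool


def _transform(x_nat: np.ndarray, n_units: int) -> np.ndarray:
    z = np.empty_like(x_nat)
    z[:n_units] = logit(np.clip(x_nat[:n_units], 1e-9, 1 - 1e-9))
    z[n_units:] = np.log(x_nat[n_units:])
    return z


def _untransform(z: np.ndarray, n_units: int) -> np.ndarray:
    x = np.empty_like(z)
    x[:n_units] = expit(z[:n_units])
    x[n_units:] = np.exp(np.clip(z[n_units:], -30.0, 30.0))
    return x


def fit_mpt(
    model: MPTModel,
    data: Mapping[str, Sequence[float]],
    *,
    n_starts: int = 20,
    seed: int = 0,
    extra_starts: Iterable[Mapping[str, float]] = (),
) -> MPTFit:
    """Fit an MPT model to per-tree counts by product-multinomial ML.

    Optimisation runs on logit-transformed unit parameters (log-transformed
    scale factors) with L-BFGS-B from one neutral start (all probabilities
    0.5, scales 1.0), ``n_starts - 1`` seeded random interior points, and any
    ``extra_starts`` (dicts of natural-space values, e.g. a previous fit's
    estimates).  Among likelihood ties the lexicographically smallest
    parameter vector wins, for determinism.
    """
    comp = model._compile()
    counts = _align_data(model, data)
    n_units, n_scales = len(comp.units), len(comp.scales)
    n_free = n_units + n_scales
    if n_free == 0:
        raise ValueError("model has no free parameters")

    def objective(z: np.ndarray) -> float:
        p = comp.probabilities(_untransform(z, n_units))
        val = -float(counts @ np.log(np.clip(p, _PROB_FLOOR, 1.0)))
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_free)]
    for _ in range(max(0, n_starts - 1)):
        z0 = np.concatenate([rng.normal(0.0, 1.5, n_units), rng.normal(0.0, 0.3, n_scales)])
        starts.append(z0)
    for nat in extra_starts:
        x_nat = np.array([nat[n] for n in comp.units] + [nat[n] for n in comp.scales], dtype=float)
        starts.append(_transform(x_nat, n_units))

    best_res = None
    best_x: np.ndarray | None = None
    any_success = False
    for i, z0 in enumerate(starts):
        res = minimize(
            objective,
            z0,
            method="L-BFGS-B",
            options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-14, "gtol": 1e-10},
        )
        any_success = any_success or res.success
        x_nat = _untransform(res.x, n_units)
        log.debug("mpt start %d/%d: nll=%.8f success=%s", i + 1, len(starts), res.fun, res.success)
        if (
            best_res is None
            or res.fun < best_res.fun - 1e-9
            or (abs(res.fun - best_res.fun) <= 1e-9 and tuple(x_nat) < tuple(best_x))
        ):
            best_res, best_x = res, x_nat
    if best_res is None or not np.isfinite(best_res.fun):
        raise RuntimeError("MPT fit failed: non-finite likelihood from every start")

    estimates = {n: float(v) for n, v in zip(comp.units, best_x[:n_units])}
    estimates.update({n: float(v) for n, v in zip(comp.scales, best_x[n_units:])})
    boundary = tuple(
        n for n in comp.units if estimates[n] < _BOUND or estimates[n] > 1 - _BOUND
    )
    for n in boundary:
        estimates[n] = float(np.clip(estimates[n], _BOUND, 1 - _BOUND))
        log.info("parameter %s at boundary, clamped to %g", n, estimates[n])

    stacked_p = comp.probabilities(best_x)
    loglik = float(counts @ np.log(np.clip(stacked_p, _PROB_FLOOR, 1.0)))
    g2 = 2.0 * (_saturated_loglik(counts, comp) - loglik)
    g2 = max(g2, 0.0)
    df = model.n_free_categories - n_free
    if df < 0:
        raise ValueError(f"over-parameterised model: {n_free} free parameters, "
                         f"{model.n_free_categories} free categories")
    expected = {}
    aligned = {}
    for name, sl, _ in comp.tree_slices:
        aligned[name] = counts[sl].copy()
        expected[name] = counts[sl].sum() * stacked_p[sl]
    return MPTFit(
        model=model,
        data=aligned,
        estimates=estimates,
        loglik=loglik,
        g2=float(g2),
        df=int(df),
        p_value=float(chi2.sf(g2, df)) if df > 0 else float("nan"),
        converged=bool(any_success),
        boundary=boundary,
        expected=expected,
    )


def delta_g2(fit_general: MPTFit, fit_constrained: MPTFit, *, tol: float = 1e-3) -> TestResult:
    """Likelihood-ratio Delta G^2 test of a constrained (nested) model.

    A Delta G^2 below ``-tol`` means the "constrained" optimum beat the
    general one, i.e. the general fit is not at its maximum; the caller
    should refit with more starts.
    """
    d_df = fit_constrained.df - fit_general.df
    if d_df < 1:
        raise ValueError(f"constrained model must lose at least 1 df (got {d_df})")
    dg = fit_constrained.g2 - fit_general.g2
    if dg < -tol:
        raise RuntimeError(
            f"Delta G^2 = {dg:.6f} < 0: general model under-optimised; refit with more starts"
        )
    dg = max(dg, 0.0)
    gen = set(fit_general.model.free_parameters)
    con = set(fit_constrained.model.free_parameters)
    return TestResult(
        delta_g2=float(dg),
        df=int(d_df),
        p_value=float(chi2.sf(dg, d_df)),
        constrained=tuple(sorted(gen - con)),
    )


def bootstrap_parameters(
    model: MPTModel,
    data: Mapping[str, Sequence[float]],
    *,
    B: int = 1000,
    seed: int = 0,
    n_starts: int = 2,
    fit: MPTFit | None = None,
) -> BootstrapResult:
    """Parametric bootstrap: resample counts at the fitted probabilities, refit.

    Each of the ``B`` replicates draws per-tree multinomial counts from the
    fitted category probabilities and refits the model (warm-started at the
    point estimates plus ``n_starts - 1`` random starts).  Returns the
    per-parameter SD and 2.5/97.5 percentile intervals.  Replicates whose
    refit fails to converge are dropped and counted; more than 5% failures
    raises a warning.
    """
    if B <= 0:
        raise ValueError(f"B must be positive, got {B}")
    if fit is None:
        fit = fit_mpt(model, data, seed=seed)
    probs = category_probabilities(model, fit.estimates)
    totals = {name: int(np.asarray(data[name]).sum()) for name in probs}
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for b in range(B):
        resample = {name: rng.multinomial(totals[name], probs[name]) for name in probs}
        try:
            refit = fit_mpt(
                model,
                resample,
                n_starts=n_starts - 1,
                seed=int(rng.integers(2**31 - 1)),
                extra_starts=[fit.estimates],
            )
        except RuntimeError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        rows.append(refit.estimates)
    if n_failed > 0.05 * B:
        warnings.warn(f"bootstrap: {n_failed}/{B} resamples failed to converge", stacklevel=2)
    samples = pd.DataFrame(rows, columns=list(fit.estimates))
    return BootstrapResult(
        sd=samples.std(ddof=1),
        ci=pd.DataFrame({"lo": samples.quantile(0.025), "hi": samples.quantile(0.975)}),
        samples=samples,
        n_failed=n_failed,
    )


def check_identifiability(
    model: MPTModel, *, n_points: int = 5, seed: int = 0, eps: float = 1e-6
) -> IdentifiabilityReport:
    """Local identifiability via the rank of the probability Jacobian.

    Evaluates the Jacobian of the stacked category probabilities with respect
    to the free parameters (central differences) at ``n_points`` random
    interior points; full column rank everywhere indicates local
    identifiability, so the G^2 degrees of freedom are trustworthy.
    """
    comp = model._compile()
    n_units, n_scales = len(comp.units), len(comp.scales)
    n_free = n_units + n_scales
    rng = np.random.default_rng(seed)
    ranks = []
    for _ in range(n_points):
        x = np.concatenate([rng.uniform(0.2, 0.8, n_units), rng.uniform(0.8, 1.2, n_scales)])
        J = np.empty((comp.n_categories, n_free))
        for j in range(n_free):
            hi, lo = x.copy(), x.copy()
            hi[j] += eps
            lo[j] -= eps
            J[:, j] = (comp.probabilities(hi) - comp.probabilities(lo)) / (2 * eps)
        # tolerance well above the finite-difference noise floor (~1e-10)
        s = np.linalg.svd(J, compute_uv=False)
        ranks.append(int((s > s[0] * 1e-6).sum()) if s[0] > 0 else 0)
    return IdentifiabilityReport(
        n_free=n_free, ranks=tuple(ranks), identified=all(r == n_free for r in ranks)
    )


# ---------------------------------------------------------------------------
# .eqn-style model files
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"^(?:\((?:1\s*-\s*)([\w.]+)\)|([\w.]+))$")


def write_eqn(model: MPTModel, path) -> None:
    """Write the tree structure as an .eqn-style text file (one line per branch)."""
    lines = []
    for tree in model.trees:
        for b in tree.branches:
            term = "*".join(f"(1-{s})" if comp else s for s, comp in b.factors)
            lines.append(f"{tree.name} {b.category} {term}")
    with open(path, "w") as fh:
        fh.write(f"{len(lines)}\n")
        fh.write("\n".join(lines) + "\n")


def read_eqn(path) -> MPTModel:
    """Read an .eqn-style file; slots sharing a name share a parameter."""
    with open(path) as fh:
        raw = [ln.strip() for ln in fh if ln.strip()]
    if not raw:
        raise ValueError("empty model file")
    try:
        n = int(raw[0])
        body = raw[1 : 1 + n]
    except ValueError:
        body = raw  # header line optional
    trees: dict[str, list[Branch]] = {}
    cats: dict[str, dict[str, None]] = {}
    for ln in body:
        parts = ln.split(maxsplit=2)
        if len(parts) != 3:
            raise ValueError(f"malformed branch line: {ln!r}")
        tree_name, category, term = parts
        factors = []
        for tok in term.split("*"):
            m = _TOKEN.match(tok.strip())
            if not m:
                raise ValueError(f"malformed factor {tok!r} in line {ln!r}")
            comp_name, plain = m.groups()
            factors.append((comp_name or plain, comp_name is not None))
        trees.setdefault(tree_name, []).append(Branch(category=category, factors=tuple(factors)))
        cats.setdefault(tree_name, {}).setdefault(category)
    return MPTModel(
        [
            Tree(name=name, categories=tuple(cats[name]), branches=tuple(branches))
            for name, branches in trees.items()
        ]
    )
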