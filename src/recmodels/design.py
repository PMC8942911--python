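"""Study designs, pooled rating-count tables, and descriptive statistics.

Recognition-memory experiments of the kind modelled here present each
participant with a fixed number of test items per item class (targets and
several lure types) and collect responses on a 4-point confidence scale,
1 = "definitely new" ... 4 = "definitely old".  Because every participant
contributes the same number of trials per item class, the participant-mean
response proportions published in summary tables equal the pooled response
proportions, and pooled integer counts can be recovered exactly from a
printed proportion table by largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical item classes, in display order
ITEM_CLASSES = ("target", "category_lure", "colour_lure", "critical_lure")

#: number of confidence-rating levels
N_RATING_LEVELS = 4

#: confidence-scale values used for mean ratings
RATING_VALUES = np.arange(1, N_RATING_LEVELS + 1)


@dataclass(frozen=True)
class ExperimentDesign:
    """Between-subject design: group sizes and per-participant trial counts.

    Parameters
    ----------
    label
        Short experiment identifier (e.g. ``"exp1"``).
    n_participants
        Mapping of encoding-condition label ("colour", "category") to the
        number of participants in that group.
    trials_per_item_class
        Mapping of item class to the number of test trials each participant
        contributes for that class.
    """

    label: str
    n_participants: Mapping[str, int]
    trials_per_item_class: Mapping[str, int]

    def __post_init__(self) -> None:
        for cond, n in self.n_participants.items():
            if int(n) != n or n <= 0:
                raise ValueError(f"group size for {cond!r} must be a positive integer, got {n}")
        for cls, t in self.trials_per_item_class.items():
            if int(t) != t or t <= 0:
                raise ValueError(f"trial count for {cls!r} must be a positive integer, got {t}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.n_participants)

    @property
    def item_classes(self) -> tuple[str, ...]:
        return tuple(self.trials_per_item_class)

    def pooled_trials(self, condition: str, item_class: str) -> int:
        """Total pooled trials for one (condition, item class) cell."""
        return int(self.n_participants[condition]) * int(self.trials_per_item_class[item_class])


@dataclass(frozen=True)
class RatingCounts:
    """Pooled integer response counts over ratings 1-4 for one cell.

    ``counts[0]`` is the number of rating-1 ("definitely new") responses and
    ``counts[3]`` the number of rating-4 ("definitely old") responses.
    """

    condition: str
    item_class: str
    counts: tuple[int, int, int, int]
    experiment: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) != N_RATING_LEVELS:
            raise ValueError(f"expected {N_RATING_LEVELS} rating counts, got {len(self.counts)}")
        for c in self.counts:
            if int(c) != c or c < 0:
                raise ValueError(f"counts must be non-negative integers, got {self.counts}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def total(self) -> int:
        return sum(self.counts)

    def proportions(self) -> np.ndarray:
        """Counts normalised to proportions over the four rating levels."""
        return np.asarray(self.counts, dtype=float) / self.total

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class ProportionRow:
    """One row of a published proportion table: P(rating = r) for one cell."""

    condition: str
    item_class: str
    proportions: tuple[float, float, float, float]
    mean_rating: float | None = None
    #: slack allowed on the sum of proportions; printed 3/4-dp tables carry
    #: up to one rounding unit per cell
    tol: float = field(default=0.003, repr=False, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != N_RATING_LEVELS:
            raise ValueError(f"expected {N_RATING_LEVELS} proportions, got {len(p)}")
        if (p < 0).any() or (p > 1).any():
            raise ValueError(f"proportions must lie in [0, 1]: {self.proportions}")
        if abs(p.sum() - 1.0) > self.tol:
            raise ValueError(
                f"proportions sum to {p.sum():.4f}, outside 1 ± {self.tol}: {self.proportions}"
            )


@dataclass(frozen=True)
class Descriptives:
    """Summary statistics for one cell of the design.

    ``old_rate`` is the proportion of "old" responses (ratings 3 and 4);
    for targets it is the hit rate and for lures the false-alarm rate.
    ``mean_rating`` is the confidence-weighted mean on the 1-4 scale.
    """

    old_rate: float
    mean_rating: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.old_rate <= 1.0:
            raise ValueError(f"old_rate outside [0, 1]: {self.old_rate}")
        if not 1.0 <= self.mean_rating <= 4.0:
            raise ValueError(f"mean_rating outside [1, 4]: {self.mean_rating}")


def reconstruct_counts(
    row: ProportionRow, design: ExperimentDesign, experiment: str | None = None
) -> RatingCounts:
    """Invert a proportion-table row into pooled integer counts.

    Multiplies each proportion by the pooled trial total and rounds by the
    largest-remainder method, which guarantees the counts sum to the total
    exactly; ties between remainders go to the lower rating index.  A
    printed table that is consistent with integer counts never requires an
    adjustment of one whole count or more in any cell; a larger adjustment
    indicates a mismatch between the table and the stated design and raises
    :class:`ValueError`.
    """
    total = design.pooled_trials(row.condition, row.item_class)
    counts = _largest_remainder(np.asarray(row.proportions, dtype=float), total)
    raw = np.asarray(row.proportions, dtype=float) * total
    off = np.abs(counts - raw)
    if off.max() >= 1.0:
        raise ValueError(
            f"proportions {row.proportions} inconsistent with pooled total {total} "
            f"({row.condition}/{row.item_class}): cell adjustment {off.max():.3f} >= 1"
        )
    return RatingCounts(
        condition=row.condition,
        item_class=row.item_class,
        counts=tuple(int(c) for c in counts),
        experiment=experiment or design.label,
    )


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    raw = proportions * total
    base = np.floor(raw).astype(int)
    remainders = raw - base
    shortfall = int(round(total - base.sum()))
    # stable sort on descending remainder -> ties broken by lower rating index
    order = np.argsort(-remainders, kind="stable")
    base[order[:shortfall]] += 1
    return base


def descriptives(cell: ProportionRow | RatingCounts) -> Descriptives:
    """Hit/false-alarm rate (ratings 3+4) and mean confidence rating."""
    if isinstance(cell, RatingCounts):
        p = cell.proportions()
    else:
        p = np.asarray(cell.proportions, dtype=float)
        p = p / p.sum()  # renormalise away printing slack
    return Descriptives(old_rate=float(p[2] + p[3]), mean_rating=float(RATING_VALUES @ p))


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["experiment", "condition", "item_class", "r1", "r2", "r3", "r4"]


def write_counts_csv(rows: Iterable[RatingCounts], path) -> None:
    """Write rating-count rows to CSV (header: experiment,condition,item_class,r1..r4)."""
    records = [
        {
            "experiment": r.experiment,
            "condition": r.condition,
            "item_class": r.item_class,
            **{f"r{i + 1}": r.counts[i] for i in range(N_RATING_LEVELS)},
        }
        for r in rows
    ]
    pd.DataFrame(records, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_counts_csv(path) -> list[RatingCounts]:
    """Read rating-count rows from CSV, validating header and cell values."""
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_COLUMNS:
        raise ValueError(f"malformed header {list(df.columns)}; expected {_CSV_COLUMNS}")
    rows = []
    for _, rec in df.iterrows():
        counts = [rec[f"r{i + 1}"] for i in range(N_RATING_LEVELS)]
        for c in counts:
            if pd.isna(c) or float(c) != int(c) or int(c) < 0:
                raise ValueError(f"counts must be non-negative integers, got {counts}")
        rows.append(
            RatingCounts(
                condition=str(rec["condition"]),
                item_class=str(rec["item_class"]),
                counts=tuple(int(c) for c in counts),
                experiment="" if pd.isna(rec["experiment"]) else str(rec["experiment"]),
            )
        )
    return rows


def counts_index(rows: Sequence[RatingCounts]) -> dict[tuple[str, str, str], RatingCounts]:
    """Index rows by (experiment, condition, item_class)."""
    out: dict[tuple[str, str, str], RatingCounts] = {}
    for r in rows:
        key = (r.experiment, r.condition, r.item_class)
        if key in out:
            raise ValueError(f"duplicate counts row for {key}")
        out[key] = r
    return out
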