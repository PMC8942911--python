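"""Bundled study tables: designs, proportion tables, and published estimates.

The package ships the summary tables of a two-experiment recognition-memory
study (words in coloured fonts / door-scene photographs, colour vs. category
encoding, three lure types, 4-point confidence ratings) so the full analysis
pipeline can be exercised without any download.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml

from .design import ExperimentDesign, ProportionRow, RatingCounts, counts_index, reconstruct_counts

EXPERIMENTS = ("exp1", "exp2")


@lru_cache(maxsize=1)
def _tables() -> dict[str, Any]:
    with resources.files("recmodels.data").joinpath("study_tables.yaml").open() as fh:
        return yaml.safe_load(fh)


def study_designs() -> dict[str, ExperimentDesign]:
    """Experiment designs keyed by experiment label."""
    return {
        name: ExperimentDesign(
            label=spec["label"],
            n_participants=dict(spec["n_participants"]),
            trials_per_item_class=dict(spec["trials_per_item_class"]),
        )
        for name, spec in _tables()["designs"].items()
    }


def study_proportions() -> list[tuple[str, ProportionRow]]:
    """(experiment, ProportionRow) pairs for every cell of both experiments."""
    return [
        (
            rec["experiment"],
            ProportionRow(
                condition=rec["condition"],
                item_class=rec["item_class"],
                proportions=tuple(rec["p"]),
                mean_rating=rec.get("mean_rating"),
            ),
        )
        for rec in _tables()["proportions"]
    ]


def study_counts() -> dict[tuple[str, str, str], RatingCounts]:
    """Pooled integer counts reconstructed from the bundled proportion tables.

    Keyed by (experiment, condition, item_class).
    """
    designs = study_designs()
    rows = [reconstruct_counts(row, designs[exp], experiment=exp) for exp, row in study_proportions()]
    return counts_index(rows)


def reference_values() -> dict[str, Any]:
    """Published model-based estimates, for comparison reports only.

    These numbers are never used in any computation; fits always start from
    the reconstructed counts.
    """
    return _tables()["reference"]
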