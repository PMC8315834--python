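"""Lift: synergy and redundancy of higher-order features, in decibans.

The lift of a feature f for target t is the difference between its
coefficient and the value expected from its lower-order decomposition:

    L(f,t) = C(f,t) − C̄(f,t),     C̄(f,t) = Σ_{g∈G} C^{|g|}(g,t),

where G partitions f's code set into features found by walking down the
ordered feature set (toward lower cardinality) starting just after f, and
each constituent's coefficient comes from the model of *its own* order.
Positive lift means the codes act synergistically on the target — the
higher-order combination carries more evidence than its parts — and
negative lift means redundancy.  Singletons have no lower-order
decomposition; their lift is 0 by convention and they are excluded from
ranked reports, as are trivial records (target code contained in the
feature itself, which are guaranteed hits under monotone accumulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import Feature, OrderedFeatureSet
from .pipeline import OrderFit

__all__ = [
    "LiftRecord",
    "PartitionError",
    "build_partition",
    "lift",
    "compute_lifts",
    "rank_lifts",
]


class PartitionError(ValueError):
    """The feature's code set cannot be partitioned from the feature set."""


@dataclass(frozen=True)
class LiftRecord:
    feature: Feature
    target: str
    C_db: float
    C_expected_db: float
    lift_db: float
    partition: tuple[Feature, ...]
    n_joint: int
    trivial: bool

    def __post_init__(self) -> None:
        if not np.isclose(self.lift_db, self.C_db - self.C_expected_db):
            raise ValueError("lift must equal C − C_expected exactly")


def build_partition(f: Feature, F: OrderedFeatureSet) -> list[Feature]:
    """Disjoint lower-order features covering f's code set.

    Walk F in order starting at the entry after f, collecting every feature
    whose codes fit inside the not-yet-covered remainder of f; stop when
    the union reaches f's code set.  The ordering (cardinality descending)
    guarantees the collected sets are pairwise disjoint.  Raises
    :class:`PartitionError` when the remainder cannot be covered.
    """
    if f.cardinality < 2:
        raise PartitionError("singletons have no lower-order decomposition")
    start = F.index_of(f.codes) + 1
    remaining = set(f.codes)
    parts: list[Feature] = []
    for g in list(F)[start:]:
        if g.codes <= remaining:
            parts.append(g)
            remaining -= g.codes
            if not remaining:
                return parts
    raise PartitionError(
        f"no supported features cover {sorted(remaining)} of {f.label}"
    )


def lift(
    f: Feature,
    target: str,
    models: Mapping[int, OrderFit],
    F: OrderedFeatureSet,
) -> LiftRecord:
    """Lift of feature f for one target, from the per-order model family."""
    top = models[f.cardinality] if f.cardinality in models else None
    if top is None:
        raise KeyError(f"no model of order {f.cardinality}")
    C = float(top.results.coef_db.loc[f.label, target])
    trivial = target in f.codes
    x_col = top.X.column(f.codes)
    y_col = top.results.model.Y.column(target)
    n_joint = int((x_col & y_col).sum())
    if f.cardinality == 1:
        return LiftRecord(
            feature=f, target=target, C_db=C, C_expected_db=C, lift_db=0.0,
            partition=(), n_joint=n_joint, trivial=trivial,
        )
    parts = build_partition(f, F)
    expected = 0.0
    for g in parts:
        fit = models.get(g.cardinality)
        if fit is None:
            raise KeyError(f"no model of order {g.cardinality} for constituent {g.label}")
        if g.codes not in fit.feature_set:
            raise PartitionError(
                f"constituent {g.label} missing from the order-{g.cardinality} model"
            )
        expected += float(fit.results.coef_db.loc[g.label, target])
    return LiftRecord(
        feature=f,
        target=target,
        C_db=C,
        C_expected_db=expected,
        lift_db=C - expected,
        partition=tuple(parts),
        n_joint=n_joint,
        trivial=trivial,
    )


def compute_lifts(
    models: Mapping[int, OrderFit],
    targets: Sequence[str] | None = None,
    min_cardinality: int = 2,
) -> list[LiftRecord]:
    """Lift records for every feature of the top-order model × every target.

    Features whose partition is incomplete are skipped (their lift is
    missing, not imputed).
    """
    top_order = max(models)
    F = models[top_order].feature_set
    targets = list(targets) if targets is not None else models[top_order].results.targets
    records: list[LiftRecord] = []
    for f in F:
        if f.cardinality < min_cardinality:
            continue
        for t in targets:
            try:
                records.append(lift(f, t, models, F))
            except (PartitionError, KeyError):
                break  # partition/model availability is target-independent
    return records


def rank_lifts(
    records: Iterable[LiftRecord],
    min_joint: int = 50,
    min_C_db: float = 8.0,
) -> pd.DataFrame:
    """Ranked synergy table: median lift per feature over qualifying targets.

    Filters: feature–target co-occurrence in at least ``min_joint``
    patients, coefficient at least ``min_C_db`` db, non-trivial, feature
    cardinality ≥ 2.  One row per feature: the median lift over its
    qualifying targets (the value itself when there is only one), the
    vertical-bar-joined constituent split, and the target list; sorted by
    median lift descending.
    """
    rows: dict[str, dict] = {}
    for r in records:
        if r.trivial or r.feature.cardinality < 2:
            continue
        if r.n_joint < min_joint or r.C_db < min_C_db:
            continue
        entry = rows.setdefault(
            r.feature.label,
            {
                "feature": r.feature.label,
                "constituents": " | ".join(g.label for g in r.partition),
                "lifts": [],
                "targets": [],
            },
        )
        entry["lifts"].append(r.lift_db)
        entry["targets"].append(r.target)
    table = pd.DataFrame(
        [
            {
                "feature": e["feature"],
                "constituents": e["constituents"],
                "median_lift_db": float(np.median(e["lifts"])),
                "n_targets": len(e["targets"]),
                "targets": ", ".join(sorted(e["targets"])),
            }
            for e in rows.values()
        ],
        columns=["feature", "constituents", "median_lift_db", "n_targets", "targets"],
    )
    if len(table):
        table = table.sort_values(
            "median_lift_db", ascending=False, ignore_index=True
        )
    return table
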