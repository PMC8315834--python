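"""Convenience glue: mine, prune and fit one model per model order.

Lift computations contrast a feature's coefficient at its own order with
the coefficients of its constituents, each taken from the model whose
order equals that constituent's cardinality — so the pipeline routinely
fits a family of models at orders 1..m on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .claims import DiagnosisMatrix
from .features import FeatureMatrix, OrderedFeatureSet, mine_candidates, prune_to_final
from .mnb import MNBResults, MultiTargetNaiveBayes

__all__ = ["OrderFit", "fit_order_models"]


@dataclass
class OrderFit:
    """Final feature set, assignment matrix and fitted model at one order."""

    order: int
    feature_set: OrderedFeatureSet
    X: FeatureMatrix
    results: MNBResults


def fit_order_models(
    X0: DiagnosisMatrix,
    Y: DiagnosisMatrix,
    orders: Sequence[int],
    alpha: float = 1.0,
    support_min: int = 30,
    minidp_min: float = 1.0,
    targets: Sequence[str] | None = None,
    variant: str = "conditional",
) -> dict[int, OrderFit]:
    """Fit the all-data model at each requested order on the same matrices."""
    fits: dict[int, OrderFit] = {}
    for order in sorted(set(orders)):
        cands = mine_candidates(X0, order, support_min, minidp_min)
        F, X = prune_to_final(X0, cands, support_min)
        res = MultiTargetNaiveBayes(
            X, Y, targets=targets, alpha=alpha, variant=variant
        ).fit()
        fits[order] = OrderFit(order=order, feature_set=F, X=X, results=res)
    return fits
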