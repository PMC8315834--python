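"""Higher-order diagnosis features: mining, ordering, assignment, pruning.

A *feature* is a set of role-suffixed diagnosis codes treated as a single
predictor.  Candidates are frequent itemsets (support ≥ support_min) of
size up to the model order; sets of size ≥ 2 must additionally pass the
minimum-information-difference-to-prior (minIDP) filter, which requires
every member code to be more likely given the rest of the set than a
priori:

    minIDP(S) = min_{d∈S} 10·log10( P̂(d | S∖{d}) / P̂(d) )   [db]

with Laplace smoothing (+1 on the numerator count, +2 on the denominator
count) in both estimates.  Candidates are ordered by cardinality (desc),
minIDP (desc), support (desc) and code string (asc), then greedily
assigned to patients so that each patient's assigned features have
pairwise-disjoint code sets.  Features whose assigned support drops below
support_min are pruned one at a time (front of the order first) and the
assignment repeated, because removing one feature can re-support features
further down the order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .claims import DiagnosisMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "OrderedFeatureSet",
    "FeatureMatrix",
    "mine_candidates",
    "min_idp",
    "assign_features",
    "prune_to_final",
]


@dataclass(frozen=True)
class Feature:
    """A set of role-suffixed diagnosis codes with mining metadata.

    ``raw_support`` is the plain co-occurrence count used in the ordering;
    ``support`` is the number of patients carrying the feature *after*
    greedy assignment (None until assigned).  Singletons carry minIDP 0 by
    convention (their prior ratio is 1).
    """

    codes: frozenset[str]
    minidp: float
    raw_support: int
    support: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))
        if not self.codes:
            raise ValueError("feature must contain at least one code")
        if self.raw_support < 0:
            raise ValueError("support must be non-negative")

    @property
    def cardinality(self) -> int:
        return len(self.codes)

    @property
    def label(self) -> str:
        return " ".join(sorted(self.codes))

    @property
    def order_key(self) -> tuple:
        return (-self.cardinality, -self.minidp, -self.raw_support, self.label)


class OrderedFeatureSet:
    """Strictly ordered, duplicate-free list of features."""

    def __init__(self, features: Iterable[Feature]):
        self.features: list[Feature] = list(features)
        keys = [f.order_key for f in self.features]
        if any(a >= b for a, b in zip(keys, keys[1:])):
            raise ValueError("features are not strictly sorted by the order key")
        if len({f.codes for f in self.features}) != len(self.features):
            raise ValueError("duplicate code sets")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i: int) -> Feature:
        return self.features[i]

    def index_of(self, codes: frozenset[str]) -> int:
        for i, f in enumerate(self.features):
            if f.codes == codes:
                return i
        raise KeyError(f"feature {sorted(codes)} not in set")

    def __contains__(self, codes) -> bool:
        codes = frozenset(codes)
        return any(f.codes == codes for f in self.features)

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tcodes\tcardinality\tminidp_db\tsupport\n")
            for rank, f in enumerate(self.features, start=1):
                support = f.support if f.support is not None else f.raw_support
                fh.write(
                    f"{rank}\t{f.label}\t{f.cardinality}\t{f.minidp:.4f}\t{support}\n"
                )


@dataclass
class FeatureMatrix:
    """Binary patients × features assignment indicator."""

    patients: list[str]
    feature_set: OrderedFeatureSet
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.int8)
        if self.values.shape != (len(self.patients), len(self.feature_set)):
            raise ValueError("matrix shape does not match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def labels(self) -> list[str]:
        return self.feature_set.labels

    def to_dense_bool(self) -> np.ndarray:
        return self.values.toarray().astype(bool)

    def assigned_supports(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def column(self, codes) -> np.ndarray:
        j = self.feature_set.index_of(frozenset(codes))
        return np.asarray(self.values[:, j].todense(), dtype=bool).ravel()


def _smoothed_ratio(joint: int, given: int, marginal: int, n: int) -> float:
    """10·log10(P̂(d|rest)/P̂(d)) with +1/+2 Laplace smoothing in both."""
    p_cond = (joint + 1.0) / (given + 2.0)
    p_marg = (marginal + 1.0) / (n + 2.0)
    return 10.0 * np.log10(p_cond / p_marg)


def min_idp(codes: Iterable[str], X0: DiagnosisMatrix) -> float:
    """Minimum information difference to prior of a code set, in decibans.

    The minimum over member codes d of the smoothed log-ratio between
    P(d | all other members present) and the marginal P(d).  Positive values
    mean every member is informative about the rest of the set.
    """
    codes = sorted(set(codes))
    if len(codes) < 2:
        raise ValueError("minIDP needs at least two codes")
    cols = np.column_stack([X0.column(c) for c in codes])
    n = len(X0.patients)
    joint = int(cols.all(axis=1).sum())
    worst = np.inf
    for k in range(len(codes)):
        rest = np.delete(cols, k, axis=1).all(axis=1)
        marginal = int(cols[:, k].sum())
        worst = min(worst, _smoothed_ratio(joint, int(rest.sum()), marginal, n))
    return float(worst)


def mine_candidates(
    X0: DiagnosisMatrix,
    model_order: int,
    support_min: int = 30,
    minidp_min: float = 1.0,
) -> OrderedFeatureSet:
    """Level-wise frequent-itemset mining with the minIDP filter.

    Returns every code set of size 1..model_order with co-occurrence
    support ≥ support_min; sets of size ≥ 2 must also reach minidp_min.
    Singletons bypass the minIDP filter (their prior ratio is identically 1).
    The support lattice is expanded before minIDP filtering because support
    is anti-monotone over supersets but minIDP is not.
    """
    if model_order < 1:
        raise ValueError("model_order must be at least 1")
    if support_min < 1:
        raise ValueError("support_min must be at least 1")
    if model_order > 4:
        warnings.warn(
            f"model_order={model_order}: orders above four are unexplored territory",
            stacklevel=2,
        )
    B = X0.to_dense_bool()
    n = B.shape[0]
    counts: dict[frozenset[int], int] = {}
    col_counts = B.sum(axis=0)
    frequent: list[list[tuple[int, ...]]] = []  # per level, sorted index tuples
    level1 = [
        (j,) for j in range(B.shape[1]) if col_counts[j] >= support_min
    ]
    for (j,) in level1:
        counts[frozenset((j,))] = int(col_counts[j])
    frequent.append(level1)
    level_vectors = {(j,): B[:, j] for (j,) in level1}
    for _size in range(2, model_order + 1):
        prev = frequent[-1]
        prev_set = {frozenset(t) for t in prev}
        nxt: list[tuple[int, ...]] = []
        nxt_vectors: dict[tuple[int, ...], np.ndarray] = {}
        for a_i in range(len(prev)):
            a = prev[a_i]
            for b_i in range(a_i + 1, len(prev)):
                b = prev[b_i]
                if a[:-1] != b[:-1]:
                    continue
                cand = a + (b[-1],)
                # all (k-1)-subsets must be frequent
                if any(
                    frozenset(cand[:k] + cand[k + 1 :]) not in prev_set
                    for k in range(len(cand))
                ):
                    continue
                vec = level_vectors[a] & B[:, b[-1]]
                support = int(vec.sum())
                if support >= support_min:
                    counts[frozenset(cand)] = support
                    nxt.append(cand)
                    nxt_vectors[cand] = vec
        frequent.append(nxt)
        level_vectors = nxt_vectors

    features: list[Feature] = []
    for (j,) in frequent[0]:
        features.append(
            Feature(
                codes=frozenset((X0.codes[j],)),
                minidp=0.0,
                raw_support=counts[frozenset((j,))],
            )
        )
    for level in frequent[1:]:
        for cand in level:
            fs = frozenset(cand)
            joint = counts[fs]
            worst = np.inf
            for k in range(len(cand)):
                rest = frozenset(cand[:k] + cand[k + 1 :])
                worst = min(
                    worst,
                    _smoothed_ratio(
                        joint, counts[rest], int(col_counts[cand[k]]), n
                    ),
                )
            if worst >= minidp_min:
                features.append(
                    Feature(
                        codes=frozenset(X0.codes[j] for j in cand),
                        minidp=float(worst),
                        raw_support=joint,
                    )
                )
    features.sort(key=lambda f: f.order_key)
    return OrderedFeatureSet(features)


def assign_features(X0: DiagnosisMatrix, F: OrderedFeatureSet) -> FeatureMatrix:
    """Greedy subset-cover assignment of features to patients.

    Walking F in order, a feature is assigned to a patient iff its codes are
    all present and none of them is already covered by an earlier assigned
    feature; assigned codes become covered.  Each code of a patient is
    therefore covered at most once, and a patient's assigned features have
    pairwise-disjoint code sets.
    """
    B = X0.to_dense_bool()
    covered = np.zeros_like(B)
    n = B.shape[0]
    cols_out: list[np.ndarray] = []
    for f in F:
        try:
            idx = [X0.code_index(c) for c in sorted(f.codes)]
        except KeyError:
            cols_out.append(np.zeros(n, dtype=bool))
            continue
        eligible = B[:, idx].all(axis=1) & ~covered[:, idx].any(axis=1)
        covered[np.ix_(eligible, idx)] = True
        cols_out.append(eligible)
    values = sp.csr_matrix(
        np.column_stack(cols_out) if cols_out else np.zeros((n, 0), dtype=bool),
        dtype=np.int8,
    )
    return FeatureMatrix(list(X0.patients), F, values)


def prune_to_final(
    X0: DiagnosisMatrix,
    F: OrderedFeatureSet,
    support_min: int = 30,
) -> tuple[OrderedFeatureSet, FeatureMatrix]:
    """Iteratively drop the first under-supported feature and re-assign.

    Only the *first* weakly supported feature (in F order) is removed per
    iteration: re-assignment of its patients can push later weak features
    back over the support threshold.  Terminates because each iteration
    shrinks F by one.  The returned features carry their final assigned
    supports.
    """
    current = list(F)
    X = assign_features(X0, OrderedFeatureSet(current))
    dense = X.to_dense_bool()
    while True:
        supports = dense.sum(axis=0)
        weak = np.flatnonzero(supports < support_min)
        if weak.size == 0:
            break
        drop = int(weak[0])
        affected = dense[:, drop]
        current.pop(drop)
        dense = np.delete(dense, drop, axis=1)
        if affected.any():
            sub_ids = [X0.patients[i] for i in np.flatnonzero(affected)]
            sub = assign_features(X0.subset_patients(sub_ids), OrderedFeatureSet(current))
            dense[np.flatnonzero(affected)] = sub.to_dense_bool()
    final_supports = dense.sum(axis=0)
    final = OrderedFeatureSet(
        replace(f, support=int(s)) for f, s in zip(current, final_supports)
    )
    return final, FeatureMatrix(list(X0.patients), final, sp.csr_matrix(dense, dtype=np.int8))
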