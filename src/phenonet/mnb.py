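"""Multi-target naive Bayes with coefficients in decibans.

For every target diagnosis t the model contrasts the target-positive and
target-negative patient classes.  The coefficient

    C(f,t) = 10·log10( Pr(X_f=1 | Y_t=1) / Pr(X_f=1 | Y_t=0) )   [db]

is the weight of evidence that the presence of feature f lends to target t:
it equals the change in the modelled log-odds of t due to f.  The prior
log-odds are π(t) = 10·log10(n_{t=1}/n_{t=0}).  The linear decision
function is Δ(p,t) = Σ_{f assigned to p} C(f,t) + π(t), and t is predicted
present exactly when Δ(p,t) > 0.

Two smoothing conventions are available:

* ``variant="conditional"`` (default): per-feature Bernoulli conditionals,
  θ_{c,f} = (N_{c,f} + α)/(n_c + 2α) with n_c the number of class-c
  patients — the printed weight-of-evidence formula.  For independent
  feature–target pairs C → 0 as n grows.
* ``variant="multinomial"``: multinomial event model,
  θ_{c,f} = (N_{c,f} + α)/(N_c + α·N_F) with N_c the total number of
  feature occurrences in class c (Σ_f θ_{c,f} = 1).  This matches
  scikit-learn's MultinomialNB fitted on binary indicators.

Scoring: per-target precision, recall and F1; a target's support is its
number of true positives, and the total F1 is the support-weighted mean —
emphasising prevalent targets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .claims import DiagnosisMatrix
from .features import FeatureMatrix, assign_features, mine_candidates, prune_to_final

logger = logging.getLogger(__name__)

__all__ = [
    "MultiTargetNaiveBayes",
    "MNBResults",
    "ScoreReport",
    "score_predictions",
    "select_targets",
    "make_folds",
    "cross_validate",
    "CVResult",
]


class MultiTargetNaiveBayes:
    """Model object: binary feature matrix X, accumulated diagnosis matrix Y.

    Parameters
    ----------
    X : FeatureMatrix
        Greedily assigned higher-order feature indicators.
    Y : DiagnosisMatrix
        Accumulated (monotone) target indicators, same patient order as X.
    targets : sequence of str, optional
        Target codes to model; defaults to every Y column with at least one
        positive and one negative patient.  Targets violating that
        requirement are dropped with a warning.
    alpha : float
        Additive smoothing parameter (> 0).
    variant : {"conditional", "multinomial"}
        Smoothing convention, see module docstring.
    """

    def __init__(
        self,
        X: FeatureMatrix,
        Y: DiagnosisMatrix,
        targets: Sequence[str] | None = None,
        alpha: float = 1.0,
        variant: str = "conditional",
    ):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        if variant not in ("conditional", "multinomial"):
            raise ValueError(f"unknown variant {variant!r}")
        if X.patients != Y.patients:
            raise ValueError("X and Y must share the same patient ordering")
        self.X = X
        self.Y = Y
        self.alpha = float(alpha)
        self.variant = variant
        requested = list(targets) if targets is not None else list(Y.codes)
        missing = [t for t in requested if t not in Y.codes]
        if missing:
            raise ValueError(f"targets not in Y: {missing}")
        self.targets = requested

    def fit(self) -> "MNBResults":
        Xb = self.X.to_dense_bool()
        n_patients, n_features = Xb.shape
        Yb = np.column_stack([self.Y.column(t) for t in self.targets])
        n1 = Yb.sum(axis=0)
        n0 = n_patients - n1
        usable = (n1 > 0) & (n0 > 0)
        dropped = [t for t, u in zip(self.targets, usable) if not u]
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} target(s) with a one-sided class: "
                f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                stacklevel=2,
            )
        kept = [t for t, u in zip(self.targets, usable) if u]
        Yb = Yb[:, usable]
        n1 = n1[usable]
        n0 = n0[usable]

        N1f = Xb.T.astype(np.float64) @ Yb.astype(np.float64)  # features × targets
        N0f = Xb.sum(axis=0, dtype=np.float64)[:, None] - N1f
        a = self.alpha
        if self.variant == "conditional":
            theta1 = (N1f + a) / (n1 + 2 * a)
            theta0 = (N0f + a) / (n0 + 2 * a)
        else:
            tot1 = N1f.sum(axis=0)
            tot0 = N0f.sum(axis=0)
            theta1 = (N1f + a) / (tot1 + a * n_features)
            theta0 = (N0f + a) / (tot0 + a * n_features)
        C = 10.0 * np.log10(theta1 / theta0)
        prior = 10.0 * np.log10(n1 / n0)

        coef = pd.DataFrame(C, index=self.X.labels, columns=kept)
        prior = pd.Series(prior, index=kept, name="pi_db")
        return MNBResults(
            model=self,
            coef_db=coef,
            prior_db=prior,
            _theta1=theta1,
            _theta0=theta0,
        )


@dataclass
class ScoreReport:
    """Per-target precision/recall/F1 and the support-weighted total F1."""

    per_target: pd.DataFrame  # columns: precision, recall, f1, support
    total_f1: float

    @property
    def n_targets_scored(self) -> int:
        return len(self.per_target)

    def to_json(self, path) -> None:
        payload = {
            "total_f1": self.total_f1,
            "n_targets_scored": self.n_targets_scored,
            "per_target": self.per_target.to_dict(orient="index"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def score_predictions(
    Y_true: np.ndarray, Y_pred: np.ndarray, targets: Sequence[str]
) -> ScoreReport:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1; zero when a denominator is 0.

    Support = TP count; total F1 = Σ support·F1 / Σ support (0 if no true
    positives at all).
    """
    Y_true = np.asarray(Y_true, dtype=bool)
    Y_pred = np.asarray(Y_pred, dtype=bool)
    if Y_true.shape != Y_pred.shape or Y_true.shape[1] != len(targets):
        raise ValueError("shape mismatch between truth, prediction and target list")
    tp = (Y_true & Y_pred).sum(axis=0).astype(float)
    fp = (~Y_true & Y_pred).sum(axis=0).astype(float)
    fn = (Y_true & ~Y_pred).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    support = tp
    total = float((support * f1).sum() / support.sum()) if support.sum() > 0 else 0.0
    per_target = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support.astype(int),
        },
        index=list(targets),
    )
    return ScoreReport(per_target=per_target, total_f1=total)


@dataclass
class MNBResults:
    """Fitted coefficients (decibans), prior log-odds, prediction and scoring."""

    model: MultiTargetNaiveBayes
    coef_db: pd.DataFrame  # features × targets
    prior_db: pd.Series
    _theta1: np.ndarray = field(repr=False, default=None)
    _theta0: np.ndarray = field(repr=False, default=None)

    @property
    def targets(self) -> list[str]:
        return list(self.coef_db.columns)

    def decision_function(self, X: FeatureMatrix | None = None) -> pd.DataFrame:
        """Δ(p,t) = Σ_{f: X(p,f)=1} C(f,t) + π(t)."""
        X = X if X is not None else self.model.X
        if X.labels != list(self.coef_db.index):
            raise ValueError("feature columns do not align with the fitted model")
        delta = X.to_dense_bool() @ self.coef_db.to_numpy() + self.prior_db.to_numpy()
        return pd.DataFrame(delta, index=X.patients, columns=self.targets)

    def predict(self, X: FeatureMatrix | None = None) -> pd.DataFrame:
        """Present iff Δ(p,t) > 0 (strict: an exact tie predicts absent)."""
        return self.decision_function(X) > 0.0

    def score(
        self, Y: DiagnosisMatrix | None = None, X: FeatureMatrix | None = None,
        targets: Sequence[str] | None = None,
    ) -> ScoreReport:
        Y = Y if Y is not None else self.model.Y
        targets = list(targets) if targets is not None else self.targets
        pred = self.predict(X)[targets].to_numpy()
        truth = np.column_stack([Y.column(t) for t in targets])
        return score_predictions(truth, pred, targets)

    def to_tsv(self, coef_path, prior_path) -> None:
        order = max(f.cardinality for f in self.model.X.feature_set)
        with open(coef_path, "w", encoding="utf-8") as fh:
            fh.write("feature\ttarget\tC_db\torder\n")
            stacked = self.coef_db.stack()
            for (feat, tgt), c in stacked.items():
                fh.write(f"{feat}\t{tgt}\t{c:.4f}\t{order}\n")
        with open(prior_path, "w", encoding="utf-8") as fh:
            fh.write("target\tpi_db\n")
            for tgt, p in self.prior_db.items():
                fh.write(f"{tgt}\t{p:.4f}\n")

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the strongest coefficients."""
        from .units import evidence_grade

        lines = [
            "Multi-target naive Bayes (decibans)",
            f"  patients: {len(self.model.X.patients)}",
            f"  features: {len(self.model.X.feature_set)}",
            f"  targets:  {len(self.targets)}",
            f"  alpha:    {self.model.alpha}   variant: {self.model.variant}",
            "",
            f"  top {top} coefficients by |C|:",
        ]
        stacked = self.coef_db.stack()
        for (feat, tgt), c in stacked.reindex(
            stacked.abs().sort_values(ascending=False).index
        )[:top].items():
            lines.append(
                f"    C({feat} -> {tgt}) = {c:+7.2f} db  [{evidence_grade(abs(c))}]"
            )
        return "\n".join(lines)


def make_folds(n_patients: int, k: int, seed: int) -> np.ndarray:
    """Seeded uniform unstratified fold labels in {0..k-1}, sizes within 1."""
    if k < 2:
        raise ValueError("need at least two folds")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_patients) % k
    return labels[rng.permutation(n_patients)]


def select_targets(
    Y: DiagnosisMatrix,
    folds: np.ndarray,
    min_per_fold: int = 200,
    cap: int = 1000,
) -> list[str]:
    """Targets with ≥ min_per_fold positives in every fold, top-``cap`` by support.

    Ranking is by total positive count descending, ties broken
    lexicographically, truncated to the cap so that fold-to-fold chance
    fluctuations cannot change the number of scored targets.
    """
    Yb = Y.to_dense_bool()
    k = int(folds.max()) + 1
    keep: list[tuple[int, str]] = []
    for j, code in enumerate(Y.codes):
        per_fold = np.array([Yb[folds == f, j].sum() for f in range(k)])
        if per_fold.min() >= min_per_fold:
            keep.append((int(per_fold.sum()), code))
    keep.sort(key=lambda t: (-t[0], t[1]))
    return [code for _, code in keep[:cap]]


@dataclass
class CVResult:
    """Cross-validation outcome: held-out and training scores per fold."""

    mean_total_f1: float
    fold_total_f1: list[float]
    train_total_f1: list[float]
    n_features_per_fold: list[int]
    targets: list[str]


def cross_validate(
    X0: DiagnosisMatrix,
    Y: DiagnosisMatrix,
    model_order: int,
    alpha: float = 1.0,
    support_min: int = 30,
    minidp_min: float = 1.0,
    k: int = 5,
    seed: int = 0,
    min_per_fold: int = 200,
    cap: int = 1000,
    variant: str = "conditional",
) -> CVResult:
    """Fivefold (by default) cross-validation of the full mining+fit pipeline.

    Per fold the candidate features are mined, pruned and fitted on the
    training patients only, then assigned to the held-out patients and
    scored over the globally selected targets.  Returns held-out scores
    (the headline number) and training scores.
    """
    folds = make_folds(len(X0.patients), k, seed)
    targets = select_targets(Y, folds, min_per_fold=min_per_fold, cap=cap)
    if not targets:
        raise ValueError(
            "no target reaches the per-fold support threshold; "
            "lower min_per_fold or increase the cohort"
        )
    fold_scores: list[float] = []
    train_scores: list[float] = []
    n_feats: list[int] = []
    for f in range(k):
        train_ids = [p for p, lab in zip(X0.patients, folds) if lab != f]
        test_ids = [p for p, lab in zip(X0.patients, folds) if lab == f]
        X0_tr = X0.subset_patients(train_ids)
        Y_tr = Y.subset_patients(train_ids)
        cands = mine_candidates(X0_tr, model_order, support_min, minidp_min)
        F, X_tr = prune_to_final(X0_tr, cands, support_min)
        usable_targets = [t for t in targets if t in Y_tr.codes]
        res = MultiTargetNaiveBayes(
            X_tr, Y_tr, targets=usable_targets, alpha=alpha, variant=variant
        ).fit()
        X_te = assign_features(X0.subset_patients(test_ids), F)
        rep = res.score(Y.subset_patients(test_ids), X_te)
        fold_scores.append(rep.total_f1)
        train_scores.append(res.score().total_f1)
        n_feats.append(len(F))
    return CVResult(
        mean_total_f1=float(np.mean(fold_scores)),
        fold_total_f1=fold_scores,
        train_total_f1=train_scores,
        n_features_per_fold=n_feats,
        targets=targets,
    )
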