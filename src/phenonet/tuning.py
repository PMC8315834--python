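"""Hyperparameter search over the smoothing α and the minIDP threshold.

The two free hyperparameters of the pipeline are the naive-Bayes smoothing
parameter α (log-scaled) and the candidate filter threshold minIDP_min in
decibans; the minimum feature support stays fixed.  Each evaluation runs
the full cross-validated pipeline and scores it by mean held-out total F1.
Grid search is the reference strategy; a sequential model-based strategy
(Gaussian-process surrogate with expected improvement) is available for
budgets too small to cover a grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import DiagnosisMatrix
from .mnb import cross_validate

__all__ = ["SearchSpace", "TuneResult", "tune"]


@dataclass(frozen=True)
class SearchSpace:
    alpha_bounds: tuple[float, float] = (1e-3, 10.0)
    minidp_bounds: tuple[float, float] = (0.0, 5.0)
    budget: int = 16
    strategy: str = "grid"  # or "bayesian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_bounds[0] <= 0 or self.alpha_bounds[0] >= self.alpha_bounds[1]:
            raise ValueError("alpha bounds must be positive and non-degenerate")
        if self.minidp_bounds[0] > self.minidp_bounds[1]:
            raise ValueError("minidp bounds out of order")
        if self.budget < 1:
            raise ValueError("budget must be at least 1")
        if self.strategy not in ("grid", "bayesian"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class TuneResult:
    alpha: float
    minidp_min: float
    best_score: float
    history: pd.DataFrame  # iteration, alpha, minidp_min, mean_f1, fold_f1

    def to_csv(self, path) -> None:
        self.history.to_csv(path, index=False)


def _grid_points(space: SearchSpace) -> list[tuple[float, float]]:
    n = max(1, int(np.floor(np.sqrt(space.budget))))
    n_alpha = n
    n_idp = max(1, space.budget // n_alpha)
    alphas = np.geomspace(*space.alpha_bounds, num=n_alpha)
    lo, hi = space.minidp_bounds
    idps = np.linspace(lo, hi, num=n_idp) if hi > lo else np.array([lo])
    pts = [(float(a), float(m)) for a in alphas for m in idps]
    return pts[: space.budget]


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    from scipy.stats import norm

    sd = np.maximum(sd, 1e-12)
    z = (mu - best) / sd
    return (mu - best) * norm.cdf(z) + sd * norm.pdf(z)


def tune(
    X0: DiagnosisMatrix,
    Y: DiagnosisMatrix,
    space: SearchSpace,
    model_order: int,
    **cv_kwargs,
) -> TuneResult:
    """Maximise cross-validated total F1 over (α, minIDP_min).

    Every evaluation calls :func:`phenonet.mnb.cross_validate` with the
    candidate hyperparameters; the argmax configuration and the full
    evaluation history are returned.  Deterministic given ``space.seed``.
    """
    rng = np.random.default_rng(space.seed)
    evaluated: list[dict] = []

    def evaluate(alpha: float, minidp: float) -> float:
        cv = cross_validate(
            X0, Y, model_order=model_order, alpha=alpha, minidp_min=minidp,
            seed=space.seed, **cv_kwargs,
        )
        evaluated.append(
            {
                "iteration": len(evaluated),
                "alpha": alpha,
                "minidp_min": minidp,
                "mean_f1": cv.mean_total_f1,
                "fold_f1": ",".join(f"{s:.6f}" for s in cv.fold_total_f1),
            }
        )
        return cv.mean_total_f1

    if space.strategy == "grid":
        for alpha, minidp in _grid_points(space):
            evaluate(alpha, minidp)
    else:
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        la_lo, la_hi = np.log10(space.alpha_bounds)
        m_lo, m_hi = space.minidp_bounds

        def sample(n: int) -> np.ndarray:
            u = rng.random((n, 2))
            return np.column_stack(
                [la_lo + u[:, 0] * (la_hi - la_lo), m_lo + u[:, 1] * (m_hi - m_lo + 1e-12)]
            )

        n_init = min(4, space.budget)
        X_obs = sample(n_init)
        y_obs = [evaluate(10.0 ** x[0], float(x[1])) for x in X_obs]
        while len(evaluated) < space.budget:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), normalize_y=True,
                random_state=int(rng.integers(2**31)),
            )
            gp.fit(X_obs, np.asarray(y_obs))
            cands = sample(256)
            mu, sd = gp.predict(cands, return_std=True)
            pick = cands[int(np.argmax(_expected_improvement(mu, sd, max(y_obs))))]
            y_obs.append(evaluate(10.0 ** pick[0], float(pick[1])))
            X_obs = np.vstack([X_obs, pick])

    if not evaluated:
        raise RuntimeError("search budget exhausted with no successful evaluation")
    history = pd.DataFrame(evaluated)
    best = history.loc[history["mean_f1"].idxmax()]
    return TuneResult(
        alpha=float(best["alpha"]),
        minidp_min=float(best["minidp_min"]),
        best_score=float(best["mean_f1"]),
        history=history,
    )
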