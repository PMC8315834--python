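"""The generalized disease network: similarity, WCM backbone, clusters.

Nodes are diagnosis features; two features are similar when they predict
similar targets.  Similarity is the Gaussian approximation to mutual
information, Φ(f1,f2) = −½·ln(1−ρ²), with ρ the Pearson correlation of
the two coefficient rows C(f1,·) and C(f2,·) — invariant under affine
rescaling of either row.

The dense Φ matrix is filtered with a maximum-entropy backbone: weights
are discretised into integer bins, the weighted configuration model (the
maximum-entropy ensemble of weighted networks fixing every node strength
s_i = Σ_j w_ij) is fitted by least squares over y ∈ [0,1)^N, and an edge
survives iff the null probability γ_ij = (y*_i·y*_j)^{w_ij} of drawing a
weight at least as large falls below the significance threshold.  This
simultaneously adjusts for multiple testing and for hub-induced class
imbalance.  Louvain modularity clustering on the backbone, restricted to
its giant component, yields the final network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mnb import MNBResults

__all__ = [
    "SimilarityMatrix",
    "similarity",
    "similarity_from_coef",
    "discretize",
    "fit_wcm",
    "backbone",
    "cluster_and_reduce",
    "index_disease_view",
    "build_disease_network",
    "WCMConvergenceError",
]

_RHO_EPS = 1e-12


class WCMConvergenceError(RuntimeError):
    """Weighted-configuration-model fit failed to reach the residual tolerance."""


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative feature×feature similarity Φ (self-loops zero)."""

    labels: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.labels)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match labels")


def similarity(results: MNBResults) -> SimilarityMatrix:
    """Pairwise Φ = −½·ln(1−ρ²) of fitted coefficient rows."""
    return similarity_from_coef(results.coef_db)


def similarity_from_coef(coef: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Φ = −½·ln(1−ρ²) of coefficient rows (natural log).

    Constant rows have undefined Pearson correlation; their ρ is defined as
    0 (no similarity).  |ρ| = 1 is clipped so that Φ stays finite.
    """
    C = coef.to_numpy()
    if C.shape[0] < 2:
        raise ValueError("need at least two features")
    if C.shape[1] < 2:
        raise ValueError("need at least two targets for a correlation")
    sd = C.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(C)
    rho[~np.isfinite(rho)] = 0.0  # constant rows
    rho2 = np.clip(rho**2, 0.0, 1.0 - _RHO_EPS)
    phi = -0.5 * np.log(1.0 - rho2)
    np.fill_diagonal(phi, 0.0)
    phi[sd == 0, :] = 0.0
    phi[:, sd == 0] = 0.0
    return SimilarityMatrix(labels=list(coef.index), phi=phi)


def discretize(sim: SimilarityMatrix, n_bins: int = 30) -> np.ndarray:
    """Equal-width integer binning of Φ into {0} ∪ {1..n_bins}.

    Self-loops are zeroed first; exact zeros stay zero (absent similarity
    must not create null-model mass); positive entries are binned over the
    off-diagonal [min, max] range, the maximum mapping to bin n_bins.
    """
    phi = sim.phi.copy()
    np.fill_diagonal(phi, 0.0)
    if not np.isfinite(phi).all():
        raise ValueError("phi must be finite")
    off = phi[~np.eye(len(phi), dtype=bool)]
    lo, hi = off.min(), off.max()
    W = np.zeros_like(phi, dtype=int)
    pos = phi > 0
    if hi <= lo:
        if pos.any():
            warnings.warn("degenerate similarity range; all weights map to bin 1", stacklevel=2)
            W[pos] = 1
        return W
    width = (hi - lo) / n_bins
    W[pos] = np.clip(np.ceil((phi[pos] - lo) / width), 1, n_bins).astype(int)
    return W


def _wcm_residual(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    P = np.outer(y, y)
    G = P / (1.0 - P)
    np.fill_diagonal(G, 0.0)
    return G.sum(axis=1) - s


def _wcm_jac(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    P = np.outer(y, y)
    D = 1.0 / (1.0 - P) ** 2  # d g(x)/dx at x = y_i y_j
    np.fill_diagonal(D, 0.0)
    J = D * y[:, None]  # ∂r_i/∂y_j = y_i g'(y_i y_j)
    np.fill_diagonal(J, (D * y[None, :]).sum(axis=1))  # ∂r_i/∂y_i = Σ_j y_j g'
    return J


def fit_wcm(
    W: np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_restarts: int = 5,
) -> np.ndarray:
    """Fit the weighted-configuration-model hidden variables y* ∈ [0,1)^N.

    Minimises the per-node residual Σ_{j≠i} y_i y_j/(1−y_i y_j) − s_i with a
    trust-region least-squares solver from random starting points in [0,1),
    restarting on failure; raises :class:`WCMConvergenceError` with the
    residual report when the max |residual| never falls below ``tol``.
    """
    s = np.asarray(W, dtype=float).sum(axis=1)
    rng = np.random.default_rng(seed)
    n = len(s)
    best_res = np.inf
    for attempt in range(max_restarts):
        if attempt == 0:
            # constant random start preserves the symmetry of equal-strength
            # nodes (the residuals alone do not pin their ordering)
            y0 = np.full(n, rng.random() * (1 - 1e-6))
        else:
            y0 = rng.random(n) * (1 - 1e-6)
        sol = least_squares(
            _wcm_residual,
            y0,
            jac=_wcm_jac,
            args=(s,),
            bounds=(0.0, 1.0 - 1e-9),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        resid = float(np.abs(_wcm_residual(sol.x, s)).max())
        if resid < tol:
            return sol.x
        best_res = min(best_res, resid)
    raise WCMConvergenceError(
        f"WCM fit did not converge after {max_restarts} restarts; "
        f"best max|residual| = {best_res:.3e} (tol {tol:.1e})"
    )


def backbone(
    sim: SimilarityMatrix,
    W: np.ndarray,
    y_star: np.ndarray,
    alpha: float = 0.05,
    features=None,
) -> nx.Graph:
    """Retain edges whose weight is improbably large under the WCM.

    γ_ij = (y*_i·y*_j)^{w_ij} for w_ij > 0 is the null probability of a
    weight at least as large; an edge survives iff γ_ij < alpha (strict).
    All features stay as nodes so that component structure is meaningful.
    """
    G = nx.Graph()
    labels = sim.labels
    for i, lab in enumerate(labels):
        attrs = {"strength": float(W[i].sum())}
        if features is not None:
            attrs["codes"] = features[i].label
            attrs["support"] = int(features[i].support or features[i].raw_support)
        G.add_node(lab, **attrs)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            w = int(W[i, j])
            if w <= 0:
                continue
            gamma = float((y_star[i] * y_star[j]) ** w)
            if gamma < alpha:
                G.add_edge(
                    labels[i], labels[j],
                    phi=float(sim.phi[i, j]), w=w, gamma=gamma,
                )
    return G


def cluster_and_reduce(G: nx.Graph, seed: int = 0, resolution: float = 1.0) -> nx.Graph:
    """Louvain clustering (edge weight = phi), then restrict to the giant component."""
    if G.number_of_nodes() == 0 or G.number_of_edges() == 0:
        raise ValueError("empty backbone: nothing to cluster")
    communities = nx.community.louvain_communities(
        G, weight="phi", resolution=resolution, seed=seed
    )
    for cid, members in enumerate(communities):
        for node in members:
            G.nodes[node]["cluster_id"] = cid
    giant = max(nx.connected_components(G), key=len)
    H = G.subgraph(giant).copy()
    for node in H.nodes:
        H.nodes[node]["giant_component"] = True
    return H


def index_disease_view(G: nx.Graph, icd3: str) -> pd.DataFrame:
    """Per-cluster counts and fractions of features containing the index code.

    A feature contains the index disease when its code set includes the
    code in either role (primary or secondary).  Fractions are relative to
    all index-code features in the graph; rows sorted by count descending.
    """
    wanted = {icd3 + "p", icd3 + "s"}
    counts: dict[int, int] = {}
    total = 0
    for node, data in G.nodes(data=True):
        codes = set(data.get("codes", node).split())
        if codes & wanted:
            cid = data.get("cluster_id", -1)
            counts[cid] = counts.get(cid, 0) + 1
            total += 1
    if total == 0:
        warnings.warn(f"index code {icd3} not present in any feature", stacklevel=2)
        return pd.DataFrame(columns=["cluster_id", "n_features", "fraction"])
    df = pd.DataFrame(
        [
            {"cluster_id": cid, "n_features": c, "fraction": c / total}
            for cid, c in counts.items()
        ]
    ).sort_values(["n_features", "cluster_id"], ascending=[False, True], ignore_index=True)
    return df


def build_disease_network(
    results: MNBResults,
    n_bins: int = 30,
    gamma_threshold: float = 0.05,
    seed: int = 0,
    resolution: float = 1.0,
) -> nx.Graph:
    """Similarity → binning → WCM fit → backbone → Louvain giant component."""
    sim = similarity(results)
    W = discretize(sim, n_bins=n_bins)
    y_star = fit_wcm(W, seed=seed)
    G = backbone(
        sim, W, y_star, alpha=gamma_threshold,
        features=list(results.model.X.feature_set),
    )
    return cluster_and_reduce(G, seed=seed)


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def write_edges_tsv(G: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tphi\tw\tgamma\n")
        for u, v, d in G.edges(data=True):
            fh.write(f"{u}\t{v}\t{d['phi']:.6f}\t{d['w']}\t{d['gamma']:.3e}\n")
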