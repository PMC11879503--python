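"""Regularized partial-correlation network estimation.

The pipeline is the standard one for psychometric networks: Spearman
rank correlations (subscale sums are bounded, skewed and ordinal-ish),
a nearest-positive-definite repair if needed, the graphical lasso along
a log-spaced penalty path, and Extended BIC model selection with
hyperparameter ``gamma`` (default 0.5).  The selected precision matrix
is reported as a weighted network of partial correlations
``w_ij = -K_ij / sqrt(K_ii K_jj)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._glasso import glasso_bcd, glasso_path
from .datasets import QuestionnaireDataset

__all__ = [
    "CorrelationMatrix",
    "GlassoFit",
    "WeightedNetwork",
    "EstimatorConfig",
    "spearman_matrix",
    "glasso_solve",
    "ebic_score",
    "ebic_glasso_select",
    "estimate_network",
    "kkt_violation",
]

#: |K_ij| below this is reported as an exact zero when counting edges.
ZERO_THRESHOLD = 1e-8


@dataclass
class CorrelationMatrix:
    """A (repaired) Spearman correlation matrix with its sample size."""

    R: np.ndarray
    n: int
    method: str = "spearman"
    repaired: bool = False


@dataclass
class GlassoFit:
    """One point on the graphical-lasso path."""

    K_hat: np.ndarray
    lam: float
    loglik: float
    E: int
    ebic: float
    gamma: float


@dataclass
class WeightedNetwork:
    """Symmetric signed partial-correlation network.

    ``W`` has zero diagonal and entries in (-1, 1); ``communities`` maps
    node name to its instrument (community) label.
    """

    W: np.ndarray
    node_names: list[str]
    communities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("edge-weight matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0):
            raise ValueError("edge-weight matrix must have zero diagonal")
        if np.any(np.abs(W) >= 1):
            raise ValueError("edge weights must lie in (-1, 1)")
        self.W = W

    @property
    def p(self) -> int:
        return self.W.shape[0]

    def global_strength(self) -> float:
        """Sum of absolute edge weights over unordered pairs."""
        return float(np.sum(np.abs(self.W[np.triu_indices(self.p, k=1)])))

    def edge_list(self) -> pd.DataFrame:
        """Long-format (node_i, node_j, weight) table, i < j."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                rows.append((self.node_names[i], self.node_names[j], self.W[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_csv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        G = nx.Graph()
        for i, name in enumerate(self.node_names):
            G.add_node(name, community=self.communities.get(name, ""))
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.W[i, j] != 0.0:
                    G.add_edge(
                        self.node_names[i], self.node_names[j], weight=float(self.W[i, j])
                    )
        nx.write_graphml(G, str(path))


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings of the network estimator used by every resampling stage."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01


def spearman_matrix(data: QuestionnaireDataset | np.ndarray) -> CorrelationMatrix:
    """Pairwise Spearman correlations (average ranks for ties), PD-repaired.

    If the raw rank-correlation matrix is not positive definite, its
    eigenvalues are clipped at 1e-6 and the result rescaled to unit
    diagonal; ``repaired`` records whether that happened.
    """
    if isinstance(data, QuestionnaireDataset):
        X = data.values()
        names = data.node_names
    else:
        X = np.asarray(data, dtype=float)
        names = [str(i) for i in range(X.shape[1])]
    n, p = X.shape
    sds = X.std(axis=0)
    dead = [names[j] for j in range(p) if sds[j] == 0]
    if dead:
        raise ValueError(f"constant column(s): {dead}")
    ranks = stats.rankdata(X, axis=0)
    R = np.corrcoef(ranks, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    repaired = False
    if np.linalg.eigvalsh(R)[0] < 1e-6:
        repaired = True
        vals, vecs = np.linalg.eigh(R)
        R = (vecs * np.maximum(vals, 1e-6)) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R=R, n=n, repaired=repaired)


def kkt_violation(S: np.ndarray, K: np.ndarray, lam: float) -> float:
    """Max subgradient violation of the penalized-likelihood optimum.

    At the optimum, Sigma = K^-1 satisfies Sigma_ii = S_ii,
    Sigma_ij - S_ij = lam * sign(K_ij) where K_ij != 0, and
    |Sigma_ij - S_ij| <= lam elsewhere.
    """
    Sigma = np.linalg.inv(K)
    G = Sigma - S
    p = S.shape[0]
    v = np.max(np.abs(np.diag(G)))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            if K[i, j] != 0.0:
                v = max(v, abs(G[i, j] - lam * np.sign(K[i, j])))
            else:
                v = max(v, max(0.0, abs(G[i, j]) - lam))
    return float(v)


def _as_corr(R, n):
    if isinstance(R, CorrelationMatrix):
        return np.asarray(R.R, dtype=float), R.n
    if n is None:
        raise ValueError("n (sample size) required when R is a bare matrix")
    return np.asarray(R, dtype=float), int(n)


def glasso_solve(
    R: CorrelationMatrix | np.ndarray,
    lam: float,
    n: int | None = None,
    gamma: float = 0.5,
    tol_scale: float = 1e-7,
    max_outer: int = 500,
    kkt_tol: float = 1e-4,
) -> GlassoFit:
    """Solve one graphical-lasso problem and verify its KKT conditions.

    Maximizes ``log det K - tr(R K) - lam * sum_{i!=j} |K_ij|`` (diagonal
    unpenalized) by block coordinate descent.  Raises if the subgradient
    optimality conditions are violated by more than ``kkt_tol``.
    """
    S, n = _as_corr(R, n)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise ValueError("correlation matrix must be positive definite")
    p = S.shape[0]
    tol = tol_scale * max(np.mean(np.abs(S)), 1e-3)
    W = S.copy()
    B = np.zeros((p, p))
    K = glasso_bcd(S, lam, W, B, max_outer, tol)
    viol = kkt_violation(S, K, lam)
    if viol > kkt_tol:
        raise RuntimeError(f"glasso did not converge: KKT violation {viol:.2e}")
    sign, logdet = np.linalg.slogdet(K)
    ll = 0.5 * n * (logdet - float(np.sum(S * K)))
    E = int(np.count_nonzero(K[np.triu_indices(p, k=1)]))
    fit = GlassoFit(K_hat=K, lam=float(lam), loglik=ll, E=E, ebic=np.nan, gamma=gamma)
    fit.ebic = ebic_score(fit, n, p, gamma)
    return fit


def ebic_score(fit: GlassoFit, n: int, p: int, gamma: float) -> float:
    """Extended BIC: ``-2 loglik + E log n + 4 E gamma log p``.

    ``E`` counts unordered nonzero pairs; ``gamma = 0`` reduces to BIC.
    """
    return float(-2.0 * fit.loglik + fit.E * np.log(n) + 4.0 * gamma * fit.E * np.log(p))


def lambda_grid(S: np.ndarray, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    """Log-spaced descending path from lam_max = max off-diagonal |r|."""
    p = S.shape[0]
    lam_max = float(np.max(np.abs(S[~np.eye(p, dtype=bool)]))) if p > 1 else 0.0
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def ebic_glasso_select(
    R: CorrelationMatrix | np.ndarray,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    node_names: list[str] | None = None,
    communities: dict[str, str] | None = None,
    return_path: bool = False,
):
    """Estimate the network by EBIC selection along the glasso path.

    Fits every penalty on a log-spaced grid from ``lam_max`` (the empty
    network) down to ``lam_max * lambda_min_ratio``, selects the minimum
    EBIC (ties to the sparser, larger-penalty model), and converts the
    selected precision matrix to partial correlations.

    Returns ``(network, fit)`` or ``(network, fit, path)`` where ``path``
    is a DataFrame with one row per penalty.
    """
    S, n = _as_corr(R, n)
    p = S.shape[0]
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise ValueError("correlation matrix must be positive definite")
    lambdas = lambda_grid(S, n_lambda, lambda_min_ratio)
    tol = 1e-7 * max(np.mean(np.abs(S)), 1e-3)
    K, idx, logliks, edge_counts, ebics = glasso_path(
        S, lambdas, float(n), float(gamma), 500, tol
    )
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < ZERO_THRESHOLD] = 0.0
    names = node_names or [str(i) for i in range(p)]
    net = WeightedNetwork(W=(W + W.T) / 2.0, node_names=names,
                          communities=dict(communities or {}))
    fit = GlassoFit(
        K_hat=K, lam=float(lambdas[idx]), loglik=float(logliks[idx]),
        E=int(edge_counts[idx]), ebic=float(ebics[idx]), gamma=gamma,
    )
    if not return_path:
        return net, fit
    path = pd.DataFrame(
        {"lam": lambdas, "loglik": logliks, "E": edge_counts, "ebic": ebics}
    )
    return net, fit, path


def estimate_network(
    data: QuestionnaireDataset, config: EstimatorConfig = EstimatorConfig()
) -> WeightedNetwork:
    """Full estimator: Spearman + PD repair + EBIC-glasso selection."""
    corr = spearman_matrix(data)
    net, _ = ebic_glasso_select(
        corr,
        gamma=config.gamma,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        node_names=data.node_names,
        communities=data.communities,
    )
    return net
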