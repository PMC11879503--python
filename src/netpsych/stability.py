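"""Bootstrap accuracy and stability of the estimated network.

Three procedures, all re-running the full estimation pipeline (Spearman
+ EBIC-glasso) on each resample:

* nonparametric bootstrap of edge weights with percentile 95% CIs;
* bootstrapped difference tests for pairs of edges or pairs of node
  centralities (significant when the percentile CI of the difference
  excludes zero);
* case-dropping bootstrap: re-estimate on subsamples with an increasing
  proportion of participants dropped and correlate each replicate's
  centralities with the full-sample ones.  The correlation-stability
  (CS) coefficient is the largest drop proportion at which at least 95%
  of replicates still correlate >= 0.7 with the original.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import bridge_centralities, node_centralities
from .datasets import QuestionnaireDataset
from .ggm import EstimatorConfig, WeightedNetwork, estimate_network

__all__ = [
    "BootstrapResult",
    "CaseDropResult",
    "bootstrap_edges",
    "difference_test",
    "casedrop_bootstrap",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

log = logging.getLogger(__name__)

DEFAULT_DROP_GRID = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.75)


def _centrality_vectors(net: WeightedNetwork, indices) -> dict[str, np.ndarray]:
    node = node_centralities(net)
    have_bridge = any(i.startswith("bridge_") for i in indices)
    bridge = bridge_centralities(net) if have_bridge else None
    out = {}
    for idx in indices:
        src = bridge if idx.startswith("bridge_") else node
        out[idx] = src[idx].to_numpy(dtype=float)
    return out


def _default_indices(data: QuestionnaireDataset) -> tuple[str, ...]:
    base = ("strength", "closeness", "betweenness", "expected_influence")
    if data.communities and len(set(data.communities.values())) >= 2:
        base = base + (
            "bridge_strength",
            "bridge_closeness",
            "bridge_betweenness",
            "bridge_expected_influence",
        )
    return base


def _resample(data: QuestionnaireDataset, rng, size=None, replace=True):
    """Row resample, redrawing (max 10 times) if a column goes constant."""
    n = data.n
    size = size if size is not None else n
    for attempt in range(10):
        rows = rng.choice(n, size=size, replace=replace)
        sub = data.scores.iloc[rows]
        if (sub.var(axis=0, ddof=1) > 0).all():
            return data.subset(rows)
        log.warning("degenerate resample (constant column), redrawing (%d)", attempt + 1)
    raise RuntimeError("could not draw a resample without constant columns")


@dataclass
class BootstrapResult:
    """Edge-weight (and centrality) bootstrap replicates and percentile CIs."""

    B: int
    seed: int | None
    node_names: list[str]
    pair_names: list[tuple[str, str]]
    observed_edges: np.ndarray          # (n_pairs,)
    edge_samples: np.ndarray            # (B, n_pairs)
    centrality_samples: dict[str, np.ndarray] = field(default_factory=dict)
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_i": [a for a, _ in self.pair_names],
                "node_j": [b for _, b in self.pair_names],
                "weight": self.observed_edges,
                "boot_mean": self.edge_samples.mean(axis=0),
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def bootstrap_edges(
    data: QuestionnaireDataset,
    config: EstimatorConfig = EstimatorConfig(),
    B: int = 1000,
    seed: int | None = None,
    indices: tuple[str, ...] = ("strength", "expected_influence",
                                "bridge_expected_influence"),
) -> BootstrapResult:
    """Nonparametric bootstrap of the estimated network.

    Draws ``B`` resamples of the ``n`` participants with replacement,
    re-estimates the full network each time, and returns per-edge
    percentile 95% CIs plus centrality replicates for difference tests.
    Bridge indices are dropped automatically when the dataset carries no
    community structure.
    """
    rng = np.random.default_rng(seed)
    if not (data.communities and len(set(data.communities.values())) >= 2):
        indices = tuple(i for i in indices if not i.startswith("bridge_"))
    net0 = estimate_network(data, config)
    p = net0.p
    iu = np.triu_indices(p, k=1)
    pair_names = [(net0.node_names[i], net0.node_names[j]) for i, j in zip(*iu)]
    edge_samples = np.empty((B, len(pair_names)))
    cent_samples = {idx: np.empty((B, p)) for idx in indices}
    for b in range(B):
        net_b = estimate_network(_resample(data, rng), config)
        edge_samples[b] = net_b.W[iu]
        for idx, vec in _centrality_vectors(net_b, indices).items():
            cent_samples[idx][b] = vec
    lo, hi = np.percentile(edge_samples, [2.5, 97.5], axis=0)
    return BootstrapResult(
        B=B,
        seed=seed,
        node_names=net0.node_names,
        pair_names=pair_names,
        observed_edges=net0.W[iu],
        edge_samples=edge_samples,
        centrality_samples=cent_samples,
        ci_low=lo,
        ci_high=hi,
    )


_KIND_TO_INDEX = {
    "strength": "strength",
    "EI": "expected_influence",
    "bridge_EI": "bridge_expected_influence",
}


def difference_test(
    boot: BootstrapResult, kind: str = "edge", alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise bootstrapped difference test.

    For every pair of edges (``kind="edge"``) or of nodes (``kind`` in
    ``{"strength", "EI", "bridge_EI"}``), the percentile CI of the
    bootstrap distribution of their difference; significant iff it
    excludes zero.  Returns a symmetric boolean DataFrame with a False
    diagonal.
    """
    if kind == "edge":
        samples = boot.edge_samples
        labels = [f"{a}--{b}" for a, b in boot.pair_names]
    else:
        try:
            idx = _KIND_TO_INDEX[kind]
        except KeyError:
            raise ValueError(f"kind must be 'edge' or one of {list(_KIND_TO_INDEX)}")
        if idx not in boot.centrality_samples:
            raise ValueError(f"bootstrap did not record {idx!r} replicates")
        samples = boot.centrality_samples[idx]
        labels = boot.node_names
    m = samples.shape[1]
    sig = np.zeros((m, m), dtype=bool)
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    for a in range(m):
        diff = samples[:, a:a + 1] - samples[:, a + 1:]
        lo, hi = np.percentile(diff, qs, axis=0)
        hit = (lo > 0) | (hi < 0)
        sig[a, a + 1:] = hit
        sig[a + 1:, a] = hit
    return pd.DataFrame(sig, index=labels, columns=labels)


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap correlations per drop proportion and index."""

    drop_proportions: tuple[float, ...]
    correlations: dict[str, np.ndarray]  # index -> (n_props, B)
    original: pd.DataFrame
    B: int
    seed: int | None


def casedrop_bootstrap(
    data: QuestionnaireDataset,
    config: EstimatorConfig = EstimatorConfig(),
    proportions: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int | None = None,
    indices: tuple[str, ...] | None = None,
) -> CaseDropResult:
    """Drop an increasing share of participants and re-estimate.

    Per proportion ``q``, draws ``B`` subsamples without replacement of
    ``round((1-q) n)`` rows, re-estimates the network, and records the
    Pearson correlation between each replicate's (raw) centralities and
    the full-sample centralities.
    """
    props = tuple(sorted(proportions))
    if not all(0 < q < 1 for q in props) or len(set(props)) != len(props):
        raise ValueError("drop proportions must be strictly increasing in (0,1)")
    indices = indices or _default_indices(data)
    smallest = int(round((1 - props[-1]) * data.n))
    if smallest <= 3 * data.p:
        raise ValueError(
            f"largest drop proportion retains {smallest} rows <= 3p={3 * data.p}"
        )
    rng = np.random.default_rng(seed)
    net0 = estimate_network(data, config)
    orig = _centrality_vectors(net0, indices)
    corrs = {idx: np.empty((len(props), B)) for idx in indices}
    for qi, q in enumerate(props):
        keep = int(round((1 - q) * data.n))
        for b in range(B):
            net_b = estimate_network(
                _resample(data, rng, size=keep, replace=False), config
            )
            reps = _centrality_vectors(net_b, indices)
            for idx in indices:
                x, y = orig[idx], reps[idx]
                if x.std() == 0 or y.std() == 0:
                    corrs[idx][qi, b] = np.nan
                else:
                    corrs[idx][qi, b] = np.corrcoef(x, y)[0, 1]
    original = pd.DataFrame(orig, index=net0.node_names)
    return CaseDropResult(props, corrs, original, B, seed)


def cs_coefficient(
    res: CaseDropResult, threshold: float = 0.7, confidence: float = 0.95
) -> pd.Series:
    """Correlation-stability coefficient per centrality index.

    The largest drop proportion in the grid at which at least
    ``confidence`` of the replicates correlate >= ``threshold`` with the
    full-sample centralities; 0 when no grid point qualifies.
    Replicates with an undefined correlation count as failures.
    """
    out = {}
    for idx, mat in res.correlations.items():
        ok = np.nan_to_num(mat, nan=-np.inf) >= threshold
        frac = ok.mean(axis=1)
        qualifying = [q for q, f in zip(res.drop_proportions, frac) if f >= confidence]
        out[idx] = max(qualifying) if qualifying else 0.0
    return pd.Series(out, name="cs_coefficient")
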