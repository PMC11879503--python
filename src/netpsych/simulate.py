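"""Synthetic questionnaire data with known ground-truth dependence.

Downstream estimators (regularized partial-correlation networks,
permutation comparison tests, Bayesian-network structure learning) are
validated by parameter recovery, which requires data whose generating
structure is known.  Two generators are provided:

* a Gaussian copula whose latent dependence is specified either as a
  precision matrix (so the *partial* correlations are controlled
  directly) or as a correlation matrix, with each column mapped to a
  bounded integer "subscale sum" via a shifted beta-binomial quantile
  transform — emulating the bounded, skewed, overdispersed marginals
  typical of questionnaire subscale totals;
* a linear-Gaussian structural-equation sampler over a directed acyclic
  graph, for structure-recovery tests.

Bounded sums of yes/no or Likert items are approximately binomial-shaped;
item-level heterogeneity makes real subscale totals overdispersed relative
to a pure binomial, so the quantile transform uses a shifted
beta-binomial, matching the target mean exactly and the SD too whenever
the target is overdispersed (questionnaire totals virtually always are);
an underdispersed target falls back to the plain binomial.  Skew
direction then follows from the mean's position inside the bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import QuestionnaireDataset

__all__ = [
    "MarginalSpec",
    "PrecisionSpec",
    "DagSpec",
    "build_precision",
    "partial_corr_from_precision",
    "sample_copula",
    "sample_linear_dag",
    "table1_marginals",
    "grouped_dataset",
    "study_like_dataset",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal for one bounded integer subscale score."""

    name: str
    min_score: int
    max_score: int
    mean: float
    sd: float
    skew_direction: str = "none"  # {"left", "right", "none"}

    def __post_init__(self) -> None:
        if not self.min_score < self.max_score:
            raise ValueError(f"{self.name}: min_score must be < max_score")
        if not (self.min_score <= self.mean <= self.max_score):
            raise ValueError(f"{self.name}: mean {self.mean} outside bounds")
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.skew_direction not in ("left", "right", "none"):
            raise ValueError(f"{self.name}: bad skew_direction")

    @property
    def binomial_params(self) -> tuple[int, float]:
        """(m, q) of the shifted binomial matching the target mean."""
        m = self.max_score - self.min_score
        q = (self.mean - self.min_score) / m
        return m, q

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF of the target discrete distribution on [min, max].

        Beta-binomial with overdispersion chosen to match the target SD
        when the target variance exceeds the binomial's; otherwise the
        plain binomial (which then has the closest achievable SD).
        """
        m, q = self.binomial_params
        var_target = self.sd**2
        var_binom = m * q * (1.0 - q)
        if m > 1 and var_target > var_binom and 0 < q < 1:
            rho = (var_target / var_binom - 1.0) / (m - 1.0)
            rho = min(rho, 0.999)
            ab = (1.0 - rho) / rho
            x = stats.betabinom.ppf(u, m, q * ab, (1.0 - q) * ab)
        else:
            x = stats.binom.ppf(u, m, q)
        return self.min_score + x


@dataclass(frozen=True)
class PrecisionSpec:
    """Sparse ground-truth precision matrix given by its partial correlations.

    ``edges`` lists ``(i, j, partial_correlation)`` with ``i < j``; all
    unlisted off-diagonal partials are zero.  If the requested partials
    are jointly infeasible at unit diagonal, the diagonal is inflated
    (which shrinks the achieved partials toward zero) — see
    :func:`build_precision`.
    """

    p: int
    edges: tuple = ()
    diagonal_inflation: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        seen = set()
        for i, j, rho in self.edges:
            if not (0 <= i < j < self.p):
                raise ValueError(f"edge ({i},{j}) out of range or not i<j")
            if not abs(rho) < 1:
                raise ValueError(f"edge ({i},{j}): |partial| must be < 1")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
        if self.diagonal_inflation < 0:
            raise ValueError("diagonal_inflation must be nonnegative")


@dataclass(frozen=True)
class DagSpec:
    """Linear-Gaussian structural equation model over a DAG.

    ``arcs`` lists ``(parent, child, coefficient)`` by node index; each
    node equals the coefficient-weighted sum of its parents plus
    independent Gaussian noise with standard deviation ``noise_sd``.
    """

    p: int
    arcs: tuple = ()
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "arcs", tuple(tuple(a) for a in self.arcs))
        for a, b, c in self.arcs:
            if not (0 <= a < self.p and 0 <= b < self.p) or a == b:
                raise ValueError(f"bad arc ({a},{b})")
            if not np.isfinite(c):
                raise ValueError(f"arc ({a},{b}): coefficient not finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[int]:
        ts = TopologicalSorter({i: [] for i in range(self.p)})
        for a, b, _ in self.arcs:
            ts.add(b, a)
        try:
            return list(ts.static_order())
        except CycleError as err:
            raise ValueError(f"arcs contain a cycle: {err.args[1]}") from None

    def coefficient_matrix(self) -> np.ndarray:
        """B with B[parent, child] = coefficient."""
        B = np.zeros((self.p, self.p))
        for a, b, c in self.arcs:
            B[a, b] = c
        return B

    def implied_covariance(self) -> np.ndarray:
        """Closed-form covariance (I - B)^-T D (I - B)^-1 of the SEM."""
        B = self.coefficient_matrix()
        inv = np.linalg.inv(np.eye(self.p) - B)
        D = np.eye(self.p) * self.noise_sd**2
        return inv.T @ D @ inv


def build_precision(spec: PrecisionSpec, return_info: bool = False):
    """Construct a positive-definite precision matrix with the requested partials.

    Off-diagonals are set to ``-rho_ij`` on a unit diagonal, so
    ``-K_ij / sqrt(K_ii K_jj)`` equals each requested partial
    correlation.  If the result is not positive definite the diagonal is
    inflated geometrically (each step multiplies the added ridge by 2)
    until it is, shrinking the achieved partials; after 50 steps the
    request is declared infeasible.

    Returns ``K``; with ``return_info=True`` also a dict recording the
    inflation applied and the partial correlations actually achieved.
    """
    K = np.eye(spec.p)
    for i, j, rho in spec.edges:
        K[i, j] = K[j, i] = -rho
    inflation = 0.0
    step = spec.diagonal_inflation
    for _ in range(51):
        if np.linalg.eigvalsh(K + inflation * np.eye(spec.p))[0] > 1e-10:
            break
        if step == 0:
            step = 0.05
        inflation = step if inflation == 0.0 else inflation * 2.0
    else:
        worst = sorted(spec.edges, key=lambda e: -abs(e[2]))[:3]
        raise ValueError(
            "requested partial correlations jointly infeasible; "
            f"largest-magnitude edges: {worst}"
        )
    K = K + inflation * np.eye(spec.p)
    if not return_info:
        return K
    achieved = partial_corr_from_precision(K)
    info = {
        "inflation": inflation,
        "achieved_partials": {(i, j): achieved[i, j] for i, j, _ in spec.edges},
    }
    return K, info


def partial_corr_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlations ``-K_ij / sqrt(K_ii K_jj)``, zero diagonal.

    The standard Gaussian graphical model identity: the correlation of
    nodes i and j after linearly controlling for all remaining nodes.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    if np.linalg.eigvalsh(K)[0] <= 0:
        raise ValueError("precision matrix must be positive definite")
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def correlation_from_precision(K: np.ndarray) -> np.ndarray:
    """Marginal correlation matrix implied by precision ``K``."""
    S = np.linalg.inv(K)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _latent_correlation(M: np.ndarray, kind: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if kind == "precision":
        return correlation_from_precision(M)
    if kind == "correlation":
        if np.linalg.eigvalsh(M)[0] <= 0:
            raise ValueError("correlation matrix must be positive definite")
        return M
    raise ValueError("kind must be 'precision' or 'correlation'")


def sample_copula(
    n: int,
    dependence: np.ndarray,
    marginals=None,
    seed: int | None = None,
    kind: str = "precision",
    communities: dict[str, str] | None = None,
) -> QuestionnaireDataset:
    """Sample a questionnaire-like dataset from a Gaussian copula.

    A latent multivariate normal carries the dependence (``kind`` names
    whether ``dependence`` is a precision or a correlation matrix); each
    column is then pushed through its normal CDF and the inverse CDF of
    a shifted (beta-)binomial matched to the target mean and SD,
    yielding integer scores inside the marginal bounds.  ``marginals`` may be None (all
    columns stay continuous) or a list with None entries for columns to
    leave continuous.
    """
    R = _latent_correlation(dependence, kind)
    p = R.shape[0]
    if marginals is not None and len(marginals) != p:
        raise ValueError("marginals length must equal node count")
    if n < 10 * p:
        warnings.warn(
            f"n={n} < 10p={10 * p}: downstream network estimates will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    Z = rng.multivariate_normal(np.zeros(p), R, size=n, method="cholesky")
    names = []
    cols = {}
    for j in range(p):
        m = marginals[j] if marginals is not None else None
        if m is None:
            names.append(f"X{j}")
            cols[f"X{j}"] = Z[:, j]
        else:
            names.append(m.name)
            u = stats.norm.cdf(Z[:, j])
            cols[m.name] = m.quantile(u).astype(int)
    scores = pd.DataFrame(cols, columns=names)
    comm = communities or {}
    return QuestionnaireDataset(scores, dict(comm))


def sample_linear_dag(
    n: int, spec: DagSpec, seed: int | None = None, node_names: list[str] | None = None
) -> QuestionnaireDataset:
    """Sample from a linear-Gaussian SEM in topological order."""
    rng = np.random.default_rng(seed)
    order = spec.topological_order()
    B = spec.coefficient_matrix()
    X = np.zeros((n, spec.p))
    noise = rng.normal(0.0, spec.noise_sd, size=(n, spec.p))
    for j in order:
        parents = np.nonzero(B[:, j])[0]
        X[:, j] = X[:, parents] @ B[parents, j] + noise[:, j]
    names = node_names or [f"X{j}" for j in range(spec.p)]
    return QuestionnaireDataset(pd.DataFrame(X, columns=names))


# ---------------------------------------------------------------- fixtures

_TABLE1_ROWS = [
    # name, community, min, max, mean, sd, skew direction
    ("SPQ.CP", "SPQ", 0, 8, 2.83, 2.08, "right"),
    ("SPQ.I", "SPQ", 0, 8, 2.39, 2.06, "right"),
    ("SPQ.D", "SPQ", 0, 6, 1.06, 1.37, "right"),
    ("ERQ.R", "ERQ", 6, 30, 18.33, 6.72, "left"),
    ("ERQ.S", "ERQ", 4, 20, 10.28, 4.32, "right"),
    ("DASS.D", "DASS", 0, 21, 2.93, 3.89, "right"),
    ("DASS.A", "DASS", 0, 21, 4.11, 4.08, "right"),
    ("DASS.S", "DASS", 0, 21, 3.91, 4.05, "right"),
]

#: Instrument membership of each of the eight subscale nodes.
STUDY_COMMUNITIES = {name: comm for name, comm, *_ in _TABLE1_ROWS}


def table1_marginals() -> list[MarginalSpec]:
    """The eight study subscale marginals (bounds, means, SDs, skew).

    Three schizotypy dimensions (cognitive-perceptual, interpersonal,
    disorganized), two emotion-regulation strategies (reappraisal,
    suppression) and three negative-affect scales (depression, anxiety,
    stress), with the descriptive statistics of the study sample.
    """
    return [
        MarginalSpec(name, lo, hi, mean, sd, skew)
        for name, _, lo, hi, mean, sd, skew in _TABLE1_ROWS
    ]


#: A plausible sparse partial-correlation structure among the eight nodes:
#: within-instrument edges plus weaker cross-instrument bridges.  Used as
#: the default ground truth for study-scale simulations.
DEFAULT_STUDY_EDGES = (
    (0, 1, 0.30),   # SPQ.CP - SPQ.I
    (0, 2, 0.20),   # SPQ.CP - SPQ.D
    (1, 2, 0.25),   # SPQ.I - SPQ.D
    (5, 6, 0.25),   # DASS.D - DASS.A
    (5, 7, 0.30),   # DASS.D - DASS.S
    (6, 7, 0.30),   # DASS.A - DASS.S
    (3, 4, 0.15),   # ERQ.R - ERQ.S
    (0, 6, 0.18),   # SPQ.CP - DASS.A
    (1, 4, 0.11),   # SPQ.I - ERQ.S
    (3, 5, -0.12),  # ERQ.R - DASS.D
    (1, 5, 0.12),   # SPQ.I - DASS.D
    (2, 7, 0.10),   # SPQ.D - DASS.S
)


def _merge_edges(base, overrides):
    merged = {(i, j): r for i, j, r in base}
    for i, j, r in overrides:
        key = (i, j) if i < j else (j, i)
        if r == 0:
            merged.pop(key, None)
        else:
            merged[key] = r
    return tuple((i, j, r) for (i, j), r in sorted(merged.items()))


def grouped_dataset(
    n_per_group: dict[str, int],
    base_spec: PrecisionSpec,
    delta_edges: dict[str, list] | None = None,
    marginals=None,
    seed: int | None = None,
    group_column: str = "group",
    communities: dict[str, str] | None = None,
) -> QuestionnaireDataset:
    """Concatenate per-group copula samples with group labels.

    Group differences are injected only through precision-matrix edge
    perturbations (``delta_edges[group]`` is a list of ``(i, j, rho)``
    overrides; ``rho=0`` removes the base edge), never through the
    marginals — so two-group comparison tests face differences in
    structure, which is what they test.  Empty ``delta_edges`` gives all
    groups one generating distribution (the null case).
    """
    delta_edges = delta_edges or {}
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for name in n_per_group:
        spec_g = PrecisionSpec(
            base_spec.p,
            _merge_edges(base_spec.edges, delta_edges.get(name, [])),
            base_spec.diagonal_inflation,
        )
        K = build_precision(spec_g)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ds = sample_copula(
            n_per_group[name], K, marginals, seed=sub_seed, kind="precision",
            communities=communities,
        )
        parts.append(ds.scores)
        labels.extend([name] * n_per_group[name])
    scores = pd.concat(parts, ignore_index=True)
    groups = pd.DataFrame({group_column: labels})
    return QuestionnaireDataset(scores, dict(communities or {}), groups)


# Age-band probabilities chosen so that age has mean 10.39 and SD 0.96
# over {9, 10, 11, 12}, matching the study sample's age distribution.
_AGE_PROBS = {9: 0.20, 10: 0.35, 11: 0.31, 12: 0.14}
_GIRL_PROP = 479 / 1019


def study_like_dataset(
    n: int = 1019,
    seed: int | None = None,
    edges=DEFAULT_STUDY_EDGES,
    delta_edges_by_gender: dict[str, list] | None = None,
) -> QuestionnaireDataset:
    """A full study-scale synthetic sample: eight subscale nodes plus
    gender and age-band grouping columns.

    Scores come from the Gaussian copula over ``edges`` with the study
    marginals; gender and age are drawn independently of the scores
    unless ``delta_edges_by_gender`` injects a structural difference.
    """
    rng = np.random.default_rng(seed)
    marg = table1_marginals()
    n_girls = int(round(n * _GIRL_PROP))
    n_per = {"boy": n - n_girls, "girl": n_girls}
    base = PrecisionSpec(8, edges)
    ds = grouped_dataset(
        n_per, base, delta_edges_by_gender, marg,
        seed=int(rng.integers(0, 2**31 - 1)),
        group_column="gender", communities=STUDY_COMMUNITIES,
    )
    # shuffle rows so gender is not blocked, then attach age bands
    perm = rng.permutation(ds.n)
    ds = ds.subset(perm)
    ages = rng.choice(list(_AGE_PROBS), size=ds.n, p=list(_AGE_PROBS.values()))
    groups = ds.groups.copy()
    groups["age"] = ages
    groups["age_band"] = np.where(ages <= 10, "9-10", "11-12")
    return QuestionnaireDataset(ds.scores, dict(ds.communities), groups)
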