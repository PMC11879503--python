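"""Score-based Bayesian-network structure learning with bootstrap averaging.

Hill climbing over single-arc moves (add / delete / reverse) maximizing
the decomposable Gaussian BIC, with random restarts and random
perturbations of the incumbent to escape local optima.  Learned DAGs are
reduced to their Markov equivalence class (CPDAG: skeleton plus
v-structures, orientations propagated to closure), and a consensus
network is built from bootstrap frequencies: an edge is retained when it
appears in at least 85% of bootstrap CPDAGs, and oriented in the
direction estimated in more than 50% of them (undirected CPDAG edges
contribute half to each direction).

Scores are computed on per-column z-scored data; the Gaussian BIC is
scale-invariant up to intercepts, so this only fixes a convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import QuestionnaireDataset

__all__ = [
    "DagStructure",
    "Cpdag",
    "ArcStrengthTable",
    "ConsensusDAG",
    "bic_g_score",
    "hill_climb",
    "cpdag",
    "bootstrap_arcs",
    "consensus_network",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DagStructure:
    """A directed acyclic graph over ``p`` nodes: a frozenset of (parent, child)."""

    p: int
    arcs: frozenset

    def __post_init__(self) -> None:
        arcs = frozenset((int(a), int(b)) for a, b in self.arcs)
        object.__setattr__(self, "arcs", arcs)
        for a, b in arcs:
            if a == b:
                raise ValueError(f"self-loop on node {a}")
            if not (0 <= a < self.p and 0 <= b < self.p):
                raise ValueError(f"arc ({a},{b}) out of range")
        if self._has_cycle():
            raise ValueError("arc set is cyclic")

    def _has_cycle(self) -> bool:
        children = {i: [] for i in range(self.p)}
        indeg = {i: 0 for i in range(self.p)}
        for a, b in self.arcs:
            children[a].append(b)
            indeg[b] += 1
        stack = [i for i in range(self.p) if indeg[i] == 0]
        seen = 0
        while stack:
            u = stack.pop()
            seen += 1
            for v in children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
        return seen < self.p

    def parents(self, j: int) -> tuple[int, ...]:
        return tuple(sorted(a for a, b in self.arcs if b == j))


# ------------------------------------------------------------- scoring


class _Scorer:
    """Decomposable Gaussian BIC with a (node, parent-set) cache.

    Local score of node j given parents P:
        loglik_j - (|P| + 2) / 2 * log n
    where loglik_j is the maximized Gaussian log-likelihood of the
    linear regression of j on P with intercept (residual variance at its
    MLE), computed from the covariance of the z-scored data.
    """

    def __init__(self, data: QuestionnaireDataset):
        X = data.values()
        self.n, self.p = X.shape
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        self.C = (Z.T @ Z) / self.n  # MLE covariance of z-scored data
        self.names = data.node_names
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, j: int, parents: tuple[int, ...]) -> float:
        key = (j, parents)
        if key in self._cache:
            return self._cache[key]
        if parents:
            Cpp = self.C[np.ix_(parents, parents)]
            Cpj = self.C[np.ix_(parents, [j])]
            if np.linalg.eigvalsh(Cpp)[0] < 1e-10:
                raise ValueError(f"collinear parents for node {self.names[j]}")
            sol = np.linalg.solve(Cpp, Cpj)
            sigma2 = float(self.C[j, j] - (Cpj.T @ sol)[0, 0])
        else:
            sigma2 = float(self.C[j, j])
        if sigma2 < 1e-12:
            raise ValueError(f"collinear parents for node {self.names[j]}")
        ll = -0.5 * self.n * (np.log(2.0 * np.pi * sigma2) + 1.0)
        k = len(parents) + 2  # coefficients + intercept + variance
        val = ll - 0.5 * k * np.log(self.n)
        self._cache[key] = val
        return val

    def total(self, parents_of: list[set]) -> float:
        return sum(self.local(j, tuple(sorted(parents_of[j]))) for j in range(self.p))


def bic_g_score(dag: DagStructure, data: QuestionnaireDataset) -> float:
    """Gaussian BIC of a DAG (higher is better); decomposes over nodes."""
    scorer = _Scorer(data)
    if data.n <= max((len(dag.parents(j)) for j in range(dag.p)), default=0) + 2:
        raise ValueError("sample too small for the largest parent set")
    return sum(scorer.local(j, dag.parents(j)) for j in range(dag.p))


# --------------------------------------------------------- hill climbing


def _creates_cycle(parents_of: list[set], a: int, b: int) -> bool:
    """Would adding arc a->b create a cycle (i.e. is a reachable from b)?"""
    stack, seen = [b], set()
    while stack:
        u = stack.pop()
        if u == a:
            return True
        if u in seen:
            continue
        seen.add(u)
        # children of u
        stack.extend(v for v in range(len(parents_of)) if u in parents_of[v])
    return False


def _legal_moves(parents_of: list[set], p: int):
    for a in range(p):
        for b in range(p):
            if a == b:
                continue
            if a in parents_of[b]:
                yield ("delete", a, b)
                if not _would_cycle_on_reverse(parents_of, a, b):
                    yield ("reverse", a, b)
            elif not _creates_cycle(parents_of, a, b):
                yield ("add", a, b)


def _would_cycle_on_reverse(parents_of, a, b) -> bool:
    parents_of[b].discard(a)
    bad = _creates_cycle(parents_of, b, a)
    parents_of[b].add(a)
    return bad


def _apply(parents_of, move):
    kind, a, b = move
    if kind == "add":
        parents_of[b].add(a)
    elif kind == "delete":
        parents_of[b].discard(a)
    else:
        parents_of[b].discard(a)
        parents_of[a].add(b)


def _move_delta(scorer, parents_of, move):
    kind, a, b = move
    old_b = tuple(sorted(parents_of[b]))
    if kind == "add":
        new_b = tuple(sorted(parents_of[b] | {a}))
        return scorer.local(b, new_b) - scorer.local(b, old_b)
    if kind == "delete":
        new_b = tuple(sorted(parents_of[b] - {a}))
        return scorer.local(b, new_b) - scorer.local(b, old_b)
    old_a = tuple(sorted(parents_of[a]))
    new_b = tuple(sorted(parents_of[b] - {a}))
    new_a = tuple(sorted(parents_of[a] | {b}))
    return (
        scorer.local(b, new_b) + scorer.local(a, new_a)
        - scorer.local(b, old_b) - scorer.local(a, old_a)
    )


def _climb(scorer, parents_of):
    """Greedy ascent: apply the best strictly improving move until none."""
    while True:
        best_delta, best_move = 0.0, None
        for move in _legal_moves(parents_of, scorer.p):
            try:
                delta = _move_delta(scorer, parents_of, move)
            except ValueError:
                continue  # collinear parent set: treat as inadmissible
            if delta > best_delta + 1e-12:
                best_delta, best_move = delta, move
        if best_move is None:
            return
        _apply(parents_of, best_move)


def hill_climb(
    data: QuestionnaireDataset,
    restarts: int = 5,
    perturbations: int = 10,
    seed: int | None = None,
    return_score: bool = False,
):
    """Learn a DAG by greedy BIC hill climbing with restarts.

    The first climb starts from the empty graph.  Each of the
    ``restarts`` further climbs starts from the best DAG found so far
    perturbed by ``perturbations`` random legal single-arc moves.  The
    best-scoring DAG over all climbs is returned; deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    scorer = _Scorer(data)
    p = scorer.p
    parents_of = [set() for _ in range(p)]
    _climb(scorer, parents_of)
    best = [set(s) for s in parents_of]
    best_score = scorer.total(best)
    for _ in range(restarts):
        current = [set(s) for s in best]
        for _ in range(perturbations):
            moves = list(_legal_moves(current, p))
            if not moves:
                break
            _apply(current, moves[rng.integers(len(moves))])
        try:
            _climb(scorer, current)
            score = scorer.total(current)
        except ValueError:
            continue  # perturbation reached a collinear configuration
        if score > best_score + 1e-12:
            best, best_score = current, score
    dag = DagStructure(
        p, frozenset((a, b) for b in range(p) for a in best[b])
    )
    return (dag, best_score) if return_score else dag


# ----------------------------------------------------------------- CPDAG


@dataclass(frozen=True)
class Cpdag:
    """Partially directed graph: compelled arcs + reversible (undirected) edges."""

    p: int
    directed: frozenset  # (a, b) compelled
    undirected: frozenset  # frozenset({a, b})

    def skeleton(self) -> frozenset:
        edges = {frozenset(e) for e in self.undirected}
        edges |= {frozenset((a, b)) for a, b in self.directed}
        return frozenset(edges)


def cpdag(dag: DagStructure) -> Cpdag:
    """Markov-equivalence class of a DAG.

    Keeps the skeleton; orients v-structures (colliders whose parents
    are non-adjacent); propagates orientations with the standard closure
    rules (no new v-structures, no directed cycles, and the
    three-fork rule); everything else is left undirected.
    """
    adj = {frozenset((a, b)) for a, b in dag.arcs}
    directed: set[tuple[int, int]] = set()
    # v-structures a -> z <- b with a, b non-adjacent
    for z in range(dag.p):
        pars = dag.parents(z)
        for i in range(len(pars)):
            for j in range(i + 1, len(pars)):
                a, b = pars[i], pars[j]
                if frozenset((a, b)) not in adj:
                    directed.add((a, z))
                    directed.add((b, z))
    undirected = {e for e in adj if not any((a, b) in directed for a, b in _both(e))}

    def is_adj(a, b):
        return frozenset((a, b)) in adj

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                # rule 1: w -> x, x - y, w and y non-adjacent  =>  x -> y
                r1 = any(
                    (w, x) in directed and not is_adj(w, y) and w != y
                    for w in range(dag.p)
                )
                # rule 2: x -> z -> y and x - y  =>  x -> y
                r2 = any(
                    (x, z) in directed and (z, y) in directed for z in range(dag.p)
                )
                # rule 3: x - z1, x - z2, z1 -> y, z2 -> y, z1,z2 non-adjacent
                r3 = False
                for z1 in range(dag.p):
                    if frozenset((x, z1)) not in undirected or (z1, y) not in directed:
                        continue
                    for z2 in range(z1 + 1, dag.p):
                        if (
                            frozenset((x, z2)) in undirected
                            and (z2, y) in directed
                            and not is_adj(z1, z2)
                        ):
                            r3 = True
                            break
                    if r3:
                        break
                if r1 or r2 or r3:
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
    return Cpdag(dag.p, frozenset(directed), frozenset(undirected))


def _both(e):
    a, b = tuple(e)
    return ((a, b), (b, a))


# ------------------------------------------------- bootstrap arc strength


@dataclass
class ArcStrengthTable:
    """Bootstrap presence and direction frequencies per node pair.

    ``presence[{i,j}]`` is the fraction of bootstrap CPDAGs whose
    skeleton contains the edge; ``direction[(i,j)]`` is, among those,
    the fraction orienting i -> j (undirected CPDAG edges count 0.5 to
    each direction), so the two directions of a present pair sum to 1.
    """

    node_names: list[str]
    B: int
    presence: dict = field(default_factory=dict)  # frozenset -> float
    direction: dict = field(default_factory=dict)  # (i, j) -> float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, pres in sorted(self.presence.items(), key=lambda kv: -kv[1]):
            i, j = sorted(pair)
            dij = self.direction.get((i, j), 0.5)
            rows.append(
                (
                    self.node_names[i],
                    self.node_names[j],
                    pres,
                    dij,
                    1.0 - dij,
                )
            )
        return pd.DataFrame(
            rows,
            columns=["node_i", "node_j", "presence", "direction_ij", "direction_ji"],
        )


def bootstrap_arcs(
    data: QuestionnaireDataset,
    B: int = 1000,
    restarts: int = 5,
    perturbations: int = 10,
    seed: int | None = None,
) -> ArcStrengthTable:
    """Arc presence/direction frequencies over bootstrap resamples.

    Each of ``B`` row-resamples (with replacement; redrawn when a column
    goes constant) is hill-climbed and reduced to its CPDAG before
    counting, so frequencies refer to equivalence classes rather than
    arbitrary members of them.
    """
    rng = np.random.default_rng(seed)
    n, p = data.n, data.p
    presence_cnt: dict[frozenset, float] = {}
    dir_cnt: dict[tuple[int, int], float] = {}
    for _ in range(B):
        for attempt in range(10):
            rows = rng.choice(n, size=n, replace=True)
            sub = data.scores.iloc[rows]
            if (sub.var(axis=0, ddof=1) > 0).all():
                break
            log.warning("degenerate bootstrap resample, redrawing (%d)", attempt + 1)
        else:
            raise RuntimeError("could not resample without constant columns")
        dag = hill_climb(
            data.subset(rows), restarts, perturbations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cp = cpdag(dag)
        for a, b in cp.directed:
            key = frozenset((a, b))
            presence_cnt[key] = presence_cnt.get(key, 0.0) + 1.0
            i, j = sorted(key)
            dir_cnt[(i, j)] = dir_cnt.get((i, j), 0.0) + (1.0 if (a, b) == (i, j) else 0.0)
        for e in cp.undirected:
            presence_cnt[e] = presence_cnt.get(e, 0.0) + 1.0
            i, j = sorted(e)
            dir_cnt[(i, j)] = dir_cnt.get((i, j), 0.0) + 0.5
    presence = {k: c / B for k, c in presence_cnt.items()}
    direction = {}
    for (i, j), c in dir_cnt.items():
        direction[(i, j)] = c / presence_cnt[frozenset((i, j))]
    return ArcStrengthTable(list(data.node_names), B, presence, direction)


@dataclass
class ConsensusDAG:
    """Thresholded consensus of the bootstrap networks.

    ``arcs`` rows: (parent, child, presence, direction) for pairs with
    presence >= edge_threshold whose majority direction exceeds
    direction_threshold; pairs split exactly 50/50 are kept undirected
    and listed in ``undirected_pairs``.  ``listing`` is the full
    reference table of every pair with presence >= 0.5.
    """

    arcs: pd.DataFrame
    undirected_pairs: pd.DataFrame
    listing: pd.DataFrame
    edge_threshold: float
    direction_threshold: float

    def to_dot(self) -> str:
        lines = ["digraph consensus {"]
        for _, r in self.arcs.iterrows():
            lines.append(
                f'  "{r.parent}" -> "{r.child}" '
                f'[label="{r.presence:.2f}/{r.direction:.2f}"];'
            )
        for _, r in self.undirected_pairs.iterrows():
            lines.append(f'  "{r.node_i}" -> "{r.node_j}" [dir=none];')
        lines.append("}")
        return "\n".join(lines)


def consensus_network(
    table: ArcStrengthTable,
    edge_threshold: float = 0.85,
    direction_threshold: float = 0.5,
) -> ConsensusDAG:
    """Apply the presence/direction thresholds to a bootstrap table."""
    names = table.node_names
    arc_rows, undec_rows, listing_rows = [], [], []
    for pair, pres in sorted(table.presence.items(), key=lambda kv: -kv[1]):
        i, j = sorted(pair)
        dij = table.direction[(i, j)]
        if pres >= 0.5:
            listing_rows.append((names[i], names[j], pres, dij, 1 - dij))
        if pres < edge_threshold:
            continue
        if dij > direction_threshold:
            arc_rows.append((names[i], names[j], pres, dij))
        elif (1 - dij) > direction_threshold:
            arc_rows.append((names[j], names[i], pres, 1 - dij))
        else:
            undec_rows.append((names[i], names[j], pres, dij))
    return ConsensusDAG(
        arcs=pd.DataFrame(arc_rows, columns=["parent", "child", "presence", "direction"]),
        undirected_pairs=pd.DataFrame(
            undec_rows, columns=["node_i", "node_j", "presence", "direction_ij"]
        ),
        listing=pd.DataFrame(
            listing_rows,
            columns=["node_i", "node_j", "presence", "direction_ij", "direction_ji"],
        ),
        edge_threshold=edge_threshold,
        direction_threshold=direction_threshold,
    )
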