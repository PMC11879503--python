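"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a different route than the package
(direct formulas, exhaustive enumeration, generic convex optimization),
so agreement is evidence of correctness rather than self-confirmation.
"""

from __future__ import annotations

import itertools

import numpy as np


# ------------------------------------------------------------- spearman

def spearman_formula(x, y) -> float:
    """Rank-difference formula 1 - 6 sum d^2 / (n (n^2 - 1)); no ties."""
    x, y = np.asarray(x), np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d = rx - ry
    n = len(x)
    return 1 - 6 * float(d @ d) / (n * (n**2 - 1))


# ----------------------------------------------------- penalized likelihood

def _soft_offdiag(K, t):
    out = np.sign(K) * np.maximum(np.abs(K) - t, 0.0)
    np.fill_diagonal(out, np.diag(K))
    return out


def ista_glasso(S, lam, max_iter=200_000, tol=1e-10):
    """Proximal-gradient minimizer of -logdet K + tr(SK) + lam*||K||_1,offdiag.

    Generic first-order method with backtracking, entirely independent
    of the block-coordinate-descent solver under test.
    """
    p = S.shape[0]
    K = np.diag(1.0 / np.diag(S))

    def smooth(K):
        sign, ld = np.linalg.slogdet(K)
        if sign <= 0:
            return np.inf
        return -ld + float(np.sum(S * K))

    f = smooth(K)
    t = 1.0
    for _ in range(max_iter):
        G = S - np.linalg.inv(K)
        while True:
            K_new = _soft_offdiag(K - t * G, t * lam)
            try:
                np.linalg.cholesky(K_new)
            except np.linalg.LinAlgError:
                t *= 0.5
                continue
            f_new = smooth(K_new)
            diff = K_new - K
            quad = f + float(np.sum(G * diff)) + float(np.sum(diff * diff)) / (2 * t)
            if f_new <= quad + 1e-15:
                break
            t *= 0.5
        delta = np.max(np.abs(K_new - K))
        K, f = K_new, f_new
        t *= 1.1
        if delta < tol:
            break
    return K


# --------------------------------------------------- partial correlations

def partial_corr_by_regression(Sigma: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of i and j given the rest, from the covariance,
    via the correlation of regression residuals."""
    p = Sigma.shape[0]
    rest = [k for k in range(p) if k not in (i, j)]
    if not rest:
        return Sigma[i, j] / np.sqrt(Sigma[i, i] * Sigma[j, j])
    Srr = Sigma[np.ix_(rest, rest)]
    bi = np.linalg.solve(Srr, Sigma[rest, i])
    bj = np.linalg.solve(Srr, Sigma[rest, j])
    vii = Sigma[i, i] - Sigma[i, rest] @ bi
    vjj = Sigma[j, j] - Sigma[j, rest] @ bj
    vij = Sigma[i, j] - Sigma[i, rest] @ bj
    return float(vij / np.sqrt(vii * vjj))


# -------------------------------------------------- path-based centrality

def _edge_lengths(W):
    p = W.shape[0]
    return {
        (i, j): 1.0 / abs(W[i, j])
        for i in range(p)
        for j in range(p)
        if i != j and W[i, j] != 0
    }


def _all_simple_paths(p, s, t):
    middle = [v for v in range(p) if v not in (s, t)]
    for r in range(len(middle) + 1):
        for combo in itertools.permutations(middle, r):
            yield (s, *combo, t)


def brute_shortest_paths(W, s, t, rtol=1e-9):
    """All minimal-length simple paths s..t by exhaustive enumeration."""
    lengths = _edge_lengths(W)
    best, paths = np.inf, []
    for path in _all_simple_paths(W.shape[0], s, t):
        total = 0.0
        ok = True
        for a, b in zip(path, path[1:]):
            if (a, b) not in lengths:
                ok = False
                break
            total += lengths[(a, b)]
        if not ok:
            continue
        if total < best * (1 - rtol):
            best, paths = total, [path]
        elif abs(total - best) <= rtol * best:
            paths.append(path)
    return best, paths


def brute_centralities(W):
    """strength / closeness / betweenness / EI by definition + enumeration."""
    p = W.shape[0]
    strength = np.abs(W).sum(axis=1)
    ei = W.sum(axis=1)
    closeness = np.zeros(p)
    for i in range(p):
        total = 0.0
        for j in range(p):
            if j == i:
                continue
            d, paths = brute_shortest_paths(W, i, j)
            if paths:
                total += d
        closeness[i] = 1.0 / total if total > 0 else 0.0
    betweenness = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            d, paths = brute_shortest_paths(W, s, t)
            if not paths:
                continue
            for i in range(p):
                if i in (s, t):
                    continue
                betweenness[i] += sum(1 for q in paths if i in q[1:-1]) / len(paths)
    return strength, closeness, betweenness, ei


def brute_bridge(W, comm):
    """Bridge strength / closeness / betweenness / EI by definition."""
    p = W.shape[0]
    outside = [[j for j in range(p) if comm[j] != comm[i]] for i in range(p)]
    b_str = np.array([sum(abs(W[i, j]) for j in outside[i]) for i in range(p)])
    b_ei = np.array([sum(W[i, j] for j in outside[i]) for i in range(p)])
    b_clo = np.zeros(p)
    for i in range(p):
        dists = []
        for j in outside[i]:
            d, paths = brute_shortest_paths(W, i, j)
            if paths:
                dists.append(d)
        b_clo[i] = 1.0 / np.mean(dists) if dists else 0.0
    b_btw = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if comm[s] == comm[t]:
                continue
            d, paths = brute_shortest_paths(W, s, t)
            if not paths:
                continue
            for i in range(p):
                if i in (s, t):
                    continue
                b_btw[i] += sum(1 for q in paths if i in q[1:-1]) / len(paths)
    return b_str, b_clo, b_btw, b_ei


# ------------------------------------------------------------ 3-node DAGs

def all_3node_dags():
    """All 25 DAGs on three nodes (each of the 3 pairs: absent, ->, <-)."""
    pairs = [(0, 1), (0, 2), (1, 2)]
    out = []
    for choice in itertools.product((None, "fwd", "rev"), repeat=3):
        arcs = set()
        for (a, b), c in zip(pairs, choice):
            if c == "fwd":
                arcs.add((a, b))
            elif c == "rev":
                arcs.add((b, a))
        if not _cyclic(3, arcs):
            out.append(frozenset(arcs))
    return out


def _cyclic(p, arcs):
    children = {i: [a[1] for a in arcs if a[0] == i] for i in range(p)}

    def reach(u, target, seen):
        for v in children[u]:
            if v == target or (v not in seen and reach(v, target, seen | {v})):
                return True
        return False

    return any(reach(i, i, set()) for i in range(p))


def skeleton_and_vstructures(p, arcs):
    """The Markov-equivalence invariants of a DAG."""
    skel = frozenset(frozenset(a) for a in arcs)
    vs = set()
    for z in range(p):
        parents = sorted(a for a, b in arcs if b == z)
        for x in range(len(parents)):
            for y in range(x + 1, len(parents)):
                a, b = parents[x], parents[y]
                if frozenset((a, b)) not in skel:
                    vs.add((a, z, b))
    return skel, frozenset(vs)
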