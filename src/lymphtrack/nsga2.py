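"""A compact NSGA-II implementation for box-bounded multi-objective search.

Standard components: fast non-dominated sorting, crowding distance,
binary-tournament mating selection, simulated binary crossover (SBX) and
polynomial mutation. Minimisation throughout. The evaluator may return
extra columns beyond the declared objectives (e.g. holdout diagnostics);
selection uses only the first ``n_obj`` columns.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fast_non_dominated_sort", "crowding_distance", "nsga2"]


def _dominates(f: np.ndarray, g: np.ndarray) -> bool:
    return bool(np.all(f <= g) and np.any(f < g))


def fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Partition rows of F into fronts; fronts[0] is the non-dominated set."""
    n = len(F)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(F[i], F[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif _dominates(F[j], F[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts = []
    current = np.nonzero(n_dominating == 0)[0]
    while len(current):
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(nxt), dtype=int)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        span = F[order[-1], k] - F[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (F[order[2:], k] - F[order[:-2], k]) / span
    return dist


def _tournament(rank, crowd, rng, n_pick):
    n = len(rank)
    winners = np.empty(n_pick, dtype=int)
    for i in range(n_pick):
        a, b = rng.integers(0, n, size=2)
        if rank[a] < rank[b] or (rank[a] == rank[b] and crowd[a] > crowd[b]):
            winners[i] = a
        else:
            winners[i] = b
    return winners


def _sbx(p1, p2, lo, hi, rng, eta=15.0, prob=0.9):
    c1, c2 = p1.copy(), p2.copy()
    if rng.uniform() > prob:
        return c1, c2
    for k in range(len(p1)):
        if rng.uniform() > 0.5 or p1[k] == p2[k]:
            continue
        x1, x2 = sorted((p1[k], p2[k]))
        u = rng.uniform()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[k] = 0.5 * ((x1 + x2) - beta * (x2 - x1))
        c2[k] = 0.5 * ((x1 + x2) + beta * (x2 - x1))
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _polynomial_mutation(x, lo, hi, rng, eta=20.0, prob=None):
    d = len(x)
    prob = 1.0 / d if prob is None else prob
    y = x.copy()
    for k in range(d):
        if rng.uniform() > prob or hi[k] == lo[k]:
            continue
        u = rng.uniform()
        delta = (2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5 else 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[k] = np.clip(y[k] + delta * (hi[k] - lo[k]), lo[k], hi[k])
    return y


def _rank_and_crowd(F: np.ndarray):
    rank = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, front in enumerate(fast_non_dominated_sort(F)):
        rank[front] = r
        crowd[front] = crowding_distance(F[front])
    return rank, crowd


def _environmental_selection(X, F, pop_size, n_obj):
    rank, crowd = _rank_and_crowd(F[:, :n_obj])
    order = np.lexsort((-crowd, rank))
    keep = order[:pop_size]
    return X[keep], F[keep]


def nsga2(evaluate, bounds, pop_size, n_gen, seed, n_obj=None, callback=None):
    """Minimise a vector objective with NSGA-II.

    Parameters
    ----------
    evaluate : callable ``(X, gen) -> F``
        Batch evaluator; ``X`` is (m, d) decision rows, ``gen`` the
        generation index (0 for the initial population). ``F`` may have
        more columns than ``n_obj``; extras are carried but not optimised.
    bounds : sequence of (lo, hi)
    pop_size : even int ≥ 4
    n_gen : maximum number of offspring generations
    seed : RNG seed (all randomness derives from it)
    callback : callable ``(gen, X, F) -> bool`` — return True to stop early.

    Returns ``(X, F, n_evaluations)`` of the final population.
    """
    if pop_size < 4 or pop_size % 2:
        raise ValueError("pop_size must be even and ≥ 4")
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("infeasible bounds: each upper must exceed its lower")
    rng = np.random.default_rng(seed)
    d = len(bounds)

    X = lo + rng.uniform(size=(pop_size, d)) * (hi - lo)
    F = np.asarray(evaluate(X, 0), dtype=float)
    n_obj = F.shape[1] if n_obj is None else n_obj
    n_eval = pop_size
    if callback is not None and callback(0, X, F):
        return X, F, n_eval

    for gen in range(1, n_gen + 1):
        rank, crowd = _rank_and_crowd(F[:, :n_obj])
        parents = _tournament(rank, crowd, rng, pop_size)
        children = []
        for i in range(0, pop_size, 2):
            c1, c2 = _sbx(X[parents[i]], X[parents[i + 1]], lo, hi, rng)
            children.append(_polynomial_mutation(c1, lo, hi, rng))
            children.append(_polynomial_mutation(c2, lo, hi, rng))
        Xc = np.asarray(children)
        Fc = np.asarray(evaluate(Xc, gen), dtype=float)
        n_eval += pop_size
        X, F = _environmental_selection(
            np.vstack([X, Xc]), np.vstack([F, Fc]), pop_size, n_obj)
        if callback is not None and callback(gen, X, F):
            break
    return X, F, n_eval
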