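"""Diversity-maximizing sub-ensemble selection.

Running a very large ensemble at inference time is wasteful; a small
sub-ensemble chosen for *diversity* — not for individual accuracy —
retains the spread of opinions that makes the ensemble variance map
informative.  Member dissimilarity is the mean squared error between
their probability maps, averaged over a validation set (no ground truth
needed); choosing the m members whose pairwise distances sum to a
maximum is the maximum diversity problem (MDP).  The max–min variant
(MMDP), which maximizes the smallest pairwise distance instead, is
available as an alternative objective.

Solvers: exhaustive enumeration for small member pools, and a seeded
genetic algorithm over subset masks with a 2-swap local-search polish
for larger ones.  Two accuracy-based baselines — the m best members,
and m members sampled in equal steps through the score distribution —
serve as comparison points.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np

ENUMERATION_GUARD = 15


def validate_distance_matrix(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")
    return D


def pairwise_distance_matrix(stacks: Sequence[np.ndarray]) -> np.ndarray:
    """Mean-MSE distance between members over a set of validation images.

    ``stacks`` holds one (n, H, W) prediction stack per image, all with
    the same member count n.  Entry (i, j) is the MSE between member i's
    and member j's maps, averaged over pixels and then over images.
    """
    if len(stacks) == 0:
        raise ValueError("need at least one validation image")
    n = np.asarray(stacks[0]).shape[0]
    total = np.zeros((n, n))
    for stack in stacks:
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3 or stack.shape[0] != n:
            raise ValueError("inconsistent member counts across stacks")
        flat = stack.reshape(n, -1)
        sq = np.einsum("ij,ij->i", flat, flat)
        gram = flat @ flat.T
        total += (sq[:, None] + sq[None, :] - 2 * gram) / flat.shape[1]
    D = total / len(stacks)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


@dataclasses.dataclass
class SubsetSelection:
    """An m-subset of member indices and its diversity objective value."""

    indices: tuple[int, ...]
    objective: float

    def __post_init__(self) -> None:
        self.indices = tuple(sorted(int(i) for i in self.indices))
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("subset indices must be distinct")


def subset_objective(D: np.ndarray, indices, objective: str = "sum") -> float:
    """Sum (MDP) or minimum (MMDP) of the pairwise distances in a subset."""
    idx = np.fromiter(indices, dtype=int)
    if idx.size < 2:
        return 0.0
    sub = np.asarray(D)[np.ix_(idx, idx)]
    if objective == "sum":
        return float(sub.sum() / 2.0)
    if objective == "min":
        return float(sub[np.triu_indices(idx.size, k=1)].min())
    raise ValueError(f"unknown objective {objective!r}")


def mdp_exact(D, m: int, objective: str = "sum") -> SubsetSelection:
    """Optimal m-subset by exhaustive enumeration (guarded to small pools).

    Ties break toward the lexicographically smallest index set, which
    enumeration order provides for free.
    """
    D = validate_distance_matrix(D)
    n = D.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n={n}")
    if n > ENUMERATION_GUARD:
        raise ValueError(f"n={n} exceeds the enumeration guard ({ENUMERATION_GUARD}); "
                         "use mdp_heuristic")
    best, best_obj = None, -np.inf
    for combo in itertools.combinations(range(n), m):
        obj = subset_objective(D, combo, objective)
        if obj > best_obj:
            best, best_obj = combo, obj
    return SubsetSelection(indices=best, objective=best_obj)


def _greedy_subset(D: np.ndarray, m: int) -> np.ndarray:
    """Greedy MDP construction: seed with the farthest pair, then add the
    member with the largest total distance to the current subset."""
    n = D.shape[0]
    if m == 1:
        return np.array([0])
    i, j = np.unravel_index(np.argmax(D), D.shape)
    chosen = [min(i, j), max(i, j)] if i != j else [0, 1 % n]
    while len(chosen) < m:
        contrib = D[:, chosen].sum(axis=1)
        contrib[chosen] = -np.inf
        chosen.append(int(np.argmax(contrib)))
    return np.array(sorted(chosen))


def _local_search(D: np.ndarray, subset: np.ndarray, objective: str) -> np.ndarray:
    """2-swap hill climbing: exchange one inside member for one outside
    while the objective improves."""
    n = D.shape[0]
    subset = np.array(sorted(subset))
    if subset.size in (0, n):
        return subset
    while True:
        inside = np.zeros(n, dtype=bool)
        inside[subset] = True
        if objective == "sum":
            contrib = D[:, subset].sum(axis=1)
            # delta of swapping i (in) for j (out): contrib[j] - D[j,i] - contrib[i]
            out_idx = np.flatnonzero(~inside)
            deltas = contrib[out_idx][None, :] - D[np.ix_(subset, out_idx)] - contrib[subset][:, None]
            best = np.unravel_index(np.argmax(deltas), deltas.shape)
            if deltas[best] <= 1e-12:
                return subset
            i, j = subset[best[0]], out_idx[best[1]]
            subset = np.array(sorted(np.append(subset[subset != i], j)))
        else:
            cur = subset_objective(D, subset, objective)
            improved = False
            for i in subset:
                for j in np.flatnonzero(~inside):
                    cand = np.append(subset[subset != i], j)
                    if subset_objective(D, cand, objective) > cur + 1e-12:
                        subset = np.array(sorted(cand))
                        improved = True
                        break
                if improved:
                    break
            if not improved:
                return subset


def _population_objectives(D: np.ndarray, pop: np.ndarray, objective: str) -> np.ndarray:
    if objective == "sum":
        return np.einsum("pi,ij,pj->p", pop, D, pop) / 2.0
    masked = np.where(pop[:, :, None] & pop[:, None, :], D[None], np.inf)
    iu = np.triu_indices(D.shape[0], k=1)
    return np.min(masked[:, iu[0], iu[1]], axis=1)


def mdp_heuristic(D, m: int, population: int = 50, generations: int = 200,
                  seed=None, objective: str = "sum", patience: int = 30) -> SubsetSelection:
    """Genetic algorithm for the MDP with local-search polishing.

    Individuals are boolean subset masks with exactly m members.
    Crossover keeps the parents' common members and fills up from their
    symmetric difference; mutation swaps a member in/out.  The initial
    population contains the greedy solution and a few locally optimized
    random subsets, so the result is never worse than the greedy
    baseline; the final best individual is polished by 2-swap hill
    climbing.  Evolution stops early when the best objective has not
    improved for ``patience`` generations.
    """
    D = validate_distance_matrix(D)
    n = D.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n={n}")
    if m in (1,):
        return SubsetSelection(indices=(0,), objective=0.0)
    if m == n:
        return SubsetSelection(indices=tuple(range(n)),
                               objective=subset_objective(D, range(n), objective))
    rng = np.random.default_rng(seed)

    def as_mask(idx) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        mask[np.asarray(idx, dtype=int)] = True
        return mask

    pop = np.zeros((population, n), dtype=bool)
    pop[0] = as_mask(_local_search(D, _greedy_subset(D, m), objective))
    for p in range(1, population):
        idx = rng.choice(n, size=m, replace=False)
        if p < 5:
            idx = _local_search(D, idx, objective)
        pop[p] = as_mask(idx)
    fitness = _population_objectives(D, pop, objective)

    best_i = int(np.argmax(fitness))
    best_mask, best_obj = pop[best_i].copy(), float(fitness[best_i])
    stale = 0
    for _ in range(generations):
        # tournament selection (size 2) for each parent slot
        cand = rng.integers(0, population, size=(2, 2 * population))
        winners = np.where(fitness[cand[0]] >= fitness[cand[1]], cand[0], cand[1])
        children = np.zeros_like(pop)
        for c in range(population):
            p1, p2 = pop[winners[2 * c]], pop[winners[2 * c + 1]]
            core = p1 & p2
            need = m - int(core.sum())
            child = core.copy()
            if need > 0:
                pool = np.flatnonzero(p1 ^ p2)
                child[rng.choice(pool, size=need, replace=False)] = True
            if rng.random() < 0.3:  # swap mutation
                inside = np.flatnonzero(child)
                outside = np.flatnonzero(~child)
                child[rng.choice(inside)] = False
                child[rng.choice(outside)] = True
            children[c] = child
        child_fit = _population_objectives(D, children, objective)
        # elitism: keep the incumbent best in the new population
        worst = int(np.argmin(child_fit))
        children[worst], child_fit[worst] = best_mask, best_obj
        pop, fitness = children, child_fit
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_obj + 1e-12:
            best_mask, best_obj = pop[gen_best].copy(), float(fitness[gen_best])
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    # polish phase: 2-swap hill climbing from the GA elite and from a few
    # random restarts guards against shallow local optima of the evolution
    candidates = [np.flatnonzero(best_mask)]
    for i in np.argsort(fitness)[::-1][:5]:
        candidates.append(np.flatnonzero(pop[i]))
    for _ in range(8):
        candidates.append(rng.choice(n, size=m, replace=False))
    best_idx, best_val = None, -np.inf
    for cand in candidates:
        polished = _local_search(D, np.asarray(cand), objective)
        val = subset_objective(D, polished, objective)
        if val > best_val + 1e-15:
            best_idx, best_val = polished, val
    return SubsetSelection(indices=tuple(best_idx), objective=best_val)


def select_n_best(member_scores, m: int) -> list[int]:
    """Indices of the m highest-scoring members; ties go to lower indices."""
    scores = np.asarray(member_scores, dtype=float)
    if not 0 <= m <= scores.size:
        raise ValueError("m must be between 0 and the member count")
    order = sorted(range(scores.size), key=lambda i: (-scores[i], i))
    return sorted(order[:m])


def select_n_steps(member_scores, m: int) -> list[int]:
    """m members sampled in equal steps through the sorted score range.

    Members are ranked by ascending score; ranks ``round(i*(n-1)/(m-1))``
    for ``i = 0..m-1`` pick the worst, evenly spaced intermediates, and
    the best.  Requires m >= 2.
    """
    scores = np.asarray(member_scores, dtype=float)
    n = scores.size
    if m < 2 or m > n:
        raise ValueError("need 2 <= m <= n")
    order = sorted(range(n), key=lambda i: (scores[i], i))
    ranks = [int(np.floor(i * (n - 1) / (m - 1) + 0.5)) for i in range(m)]
    return sorted(order[r] for r in ranks)
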