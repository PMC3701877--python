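"""Core structure of a directed network: k-core decomposition with
sub-shells, rich-club detection against degree-preserving nulls, and
knotty-centrality with knotty-center search.

All three measures rank or peel nodes by *total* degree (in + out, each
arc counted once) on the current subgraph, the only reading consistent
with "nodes that have i or fewer connections" for a directed binary
graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .centrality import normalized_betweenness
from .connectome import Connectome
from .nulls import (
    DEFAULT_N_SAMPLES,
    DEFAULT_SWAPS_PER_EDGE,
    EnsembleStat,
    null_ensemble,
)

__all__ = [
    "CoreReport",
    "k_core_decomposition",
    "RichClubCurve",
    "rich_club",
    "KnottySubset",
    "knotty_centrality",
    "find_knotty_center",
]


# -- k-core ----------------------------------------------------------------

@dataclass(frozen=True)
class CoreReport:
    """Result of iterative total-degree peeling.

    ``core_level[r]`` is the largest i such that r belongs to the i-th
    k-core (the maximal subgraph with all total degrees >= i);
    ``shell[r] = (i, j)`` records that r was removed in the j-th sweep of
    the peel at threshold i; ``erosion_level`` is the smallest i whose
    i-core is empty.
    """

    core_level: dict[str, int]
    shell: dict[str, tuple[int, int]]
    erosion_level: int

    def innermost_core(self) -> set[str]:
        top = max(self.core_level.values())
        return {r for r, lev in self.core_level.items() if lev == top}

    def subshells_ranked(self) -> list[tuple[tuple[int, int], set[str]]]:
        """Sub-shells from outermost to innermost (removal order)."""
        order: dict[tuple[int, int], set[str]] = {}
        for r, s in self.shell.items():
            order.setdefault(s, set()).add(r)
        return [(s, order[s]) for s in sorted(order)]

    def innermost_subshells(self, k: int = 1) -> set[str]:
        """Union of the k last-removed sub-shells."""
        ranked = self.subshells_ranked()
        out: set[str] = set()
        for _, members in ranked[-k:]:
            out |= members
        return out


def k_core_decomposition(c: Connectome) -> CoreReport:
    """Peel nodes of total degree <= i for i = 1, 2, ... until empty.

    Within threshold i, removal proceeds in sweeps: sweep j removes every
    node whose degree in the current subgraph is <= i; nodes removed at
    threshold i have core level i.  Degrees are recomputed on the
    shrinking subgraph.
    """
    n = c.n_regions
    A = c.adjacency.astype(np.int64)
    alive = np.ones(n, dtype=bool)
    shell: dict[str, tuple[int, int]] = {}
    core_level: dict[str, int] = {}
    i = -1  # threshold 0 clears isolated nodes (they are outside the 1-core)
    while alive.any():
        i += 1
        sweep = 0
        while True:
            ids = np.where(alive)[0]
            sub = A[np.ix_(ids, ids)]
            deg = sub.sum(axis=0) + sub.sum(axis=1)
            drop = ids[deg <= i]
            if len(drop) == 0:
                break
            sweep += 1
            for v in drop:
                shell[c.regions[v]] = (i, sweep)
                core_level[c.regions[v]] = i
            alive[drop] = False
    # the erosion level is the first threshold whose k-core is empty: the
    # peel at threshold i consumed the i-core, so the (i+1)-core is empty
    return CoreReport(core_level, shell, erosion_level=i + 1)


# -- rich club -------------------------------------------------------------

@dataclass(frozen=True)
class RichClubCurve:
    """Density among the top-k total-degree nodes vs rewired nulls.

    ``phi[k] = E_k / (N_k (N_k - 1))`` with ``E_k`` the number of directed
    arcs among the k top-ranked nodes (ties ordered to maximize phi).
    ``phi_norm[k] = phi[k] / mean null phi[k]``.  The club is the largest
    top set whose members all carry ``phi_norm > 1`` at their own rank.
    """

    ranking: tuple[str, ...]
    n_k: tuple[int, ...]
    e_k: tuple[int, ...]
    phi: tuple[float, ...]
    phi_rand: tuple[EnsembleStat, ...]
    phi_norm: tuple[float, ...]
    club: frozenset[str]


def _phi_ranking(A: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Total-degree descending ranking with greedy tie maximization.

    Nodes of equal total degree are ordered so that, at each step, the
    tied node adding the most arcs to the already-ranked prefix comes
    first, implementing "relative rankings of nodes of equal total degree
    can be assigned to maximize phi(k)".
    Returns (ranking, phi values for prefix sizes 1..n).
    """
    n = len(A)
    tot = A.sum(axis=0) + A.sum(axis=1)
    ranking: list[int] = []
    remaining = list(range(n))
    while remaining:
        top_deg = max(tot[v] for v in remaining)
        tied = [v for v in remaining if tot[v] == top_deg]
        while tied:
            best = max(
                tied,
                key=lambda v: (
                    sum(A[v, u] + A[u, v] for u in ranking),
                    -v,  # deterministic tie-break
                ),
            )
            ranking.append(best)
            tied.remove(best)
            remaining.remove(best)
    phi = np.zeros(n)
    e = 0
    for k, v in enumerate(ranking, start=1):
        e += sum(A[v, u] + A[u, v] for u in ranking[:k])
        phi[k - 1] = e / (k * (k - 1)) if k > 1 else 0.0
    return ranking, phi


def rich_club(
    c: Connectome,
    n_null: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> RichClubCurve:
    """Rich-club curve and club detection.

    The null ensemble preserves every node's in- and out-degree; the
    identical ranking procedure (including tie maximization) is applied to
    every null sample.  Because phi and its null use the same denominator
    convention, any constant factor cancels in ``phi_norm``.
    """
    A = c.adjacency.astype(np.int64)
    n = c.n_regions
    ranking, phi = _phi_ranking(A)
    null_phi = np.zeros((n_null, n))
    for s, g in enumerate(null_ensemble(c, "rewire", n_null, seed, swaps_per_edge)):
        _, np_phi = _phi_ranking(g.adjacency.astype(np.int64))
        null_phi[s] = np_phi
    stats = tuple(
        EnsembleStat.from_samples(phi[k], null_phi[:, k]) for k in range(n)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_norm = np.array(
            [
                phi[k] / stats[k].null_mean if stats[k].null_mean > 0 else np.nan
                for k in range(n)
            ]
        )
    # largest K such that phi_norm > 1 at every prefix size 2..K
    club_size = 0
    for k in range(2, n + 1):
        if phi_norm[k - 1] > 1:
            club_size = k
        else:
            break
    club = frozenset(c.regions[v] for v in ranking[:club_size])
    e_k = [int(round(phi[k - 1] * k * (k - 1))) if k > 1 else 0 for k in range(1, n + 1)]
    return RichClubCurve(
        ranking=tuple(c.regions[v] for v in ranking),
        n_k=tuple(range(1, n + 1)),
        e_k=tuple(e_k),
        phi=tuple(float(x) for x in phi),
        phi_rand=stats,
        phi_norm=tuple(float(x) for x in phi_norm),
        club=club,
    )


# -- knotty-centrality -----------------------------------------------------

@dataclass(frozen=True)
class KnottySubset:
    members: frozenset[str]
    kc: float


def _kc_value(A: np.ndarray, bc_norm: np.ndarray, subset: np.ndarray) -> float:
    ns = len(subset)
    es = int(A[np.ix_(subset, subset)].sum())
    return es / (ns * (ns - 1)) * float(bc_norm[subset].sum())


def knotty_centrality(c: Connectome, members: set[str] | frozenset[str]) -> KnottySubset:
    """KC(S) = [E_S / (N_S (N_S - 1))] * sum_{i in S} bc_norm(i).

    Internal arc density of the subset times the subset's share of total
    (network-normalized) betweenness.
    """
    members = frozenset(members)
    if len(members) < 2:
        raise ValueError("knotty-centrality needs at least 2 members")
    idx = np.array([c.index(r) for r in members])
    bcn = normalized_betweenness(c)
    bc_vec = np.array([bcn[r] for r in c.regions])
    return KnottySubset(members, _kc_value(c.adjacency.astype(np.int64), bc_vec, idx))


def find_knotty_center(
    c: Connectome,
    strategy: str = "exhaustive_topk",
    top_k: int = 12,
    greedy_seeds: int = 5,
    seed: int = 0,
    refine: bool = True,
) -> KnottySubset:
    """Search for the subset maximizing knotty-centrality.

    ``exhaustive_topk`` enumerates every subset (size >= 2) of the
    ``top_k`` highest-betweenness nodes and optionally refines the best
    one by greedy single-node add/remove moves over all nodes.
    ``greedy`` grows subsets from each of the ``greedy_seeds`` top-bc
    seeds by best-improvement add/remove only.
    """
    if strategy not in ("exhaustive_topk", "greedy"):
        raise ValueError(f"unknown strategy {strategy!r}")
    A = c.adjacency.astype(np.int64)
    n = c.n_regions
    bcn = normalized_betweenness(c)
    bc_vec = np.array([bcn[r] for r in c.regions])
    order = sorted(range(n), key=lambda v: (-bc_vec[v], c.regions[v]))

    def greedy_improve(subset: set[int]) -> tuple[set[int], float]:
        best = _kc_value(A, bc_vec, np.array(sorted(subset)))
        improved = True
        while improved:
            improved = False
            for v in range(n):
                if v in subset:
                    if len(subset) <= 2:
                        continue
                    cand = subset - {v}
                else:
                    cand = subset | {v}
                val = _kc_value(A, bc_vec, np.array(sorted(cand)))
                if val > best + 1e-15:
                    best, subset, improved = val, cand, True
        return subset, best

    best_val = -np.inf
    best_sub: set[int] = set()
    if strategy == "exhaustive_topk":
        pool = order[: min(top_k, n)]
        for r in range(2, len(pool) + 1):
            for comb in itertools.combinations(pool, r):
                val = _kc_value(A, bc_vec, np.array(comb))
                if val > best_val:
                    best_val, best_sub = val, set(comb)
        if refine:
            best_sub, best_val = greedy_improve(best_sub)
    else:
        for s in order[: min(greedy_seeds, n - 1)]:
            start = {s, next(v for v in order if v != s)}
            sub, val = greedy_improve(start)
            if val > best_val:
                best_val, best_sub = val, sub
    return KnottySubset(
        frozenset(c.regions[v] for v in best_sub), float(best_val)
    )
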