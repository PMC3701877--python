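"""Directed modularity: the Leicht–Newman quality function Q, a stochastic
multi-restart optimizer, and recursive sub-module analysis.

With the package-wide orientation (row = source) and m = number of arcs,

    Q(P) = (1/m) * sum_ij [ A_ij - k_out(i) k_in(j) / m ] * [c_i == c_j]

which is the directed generalization of Newman modularity: intra-module arc
density in excess of the expectation for a random digraph with the same in-
and out-degree sequences.  (Formulations that index A as "from j to i" are
the transpose of this one; Q is identical once in/out are swapped
consistently.)

The optimizer is a Louvain-style greedy agglomeration for directed Q:
randomized-order local moves followed by community aggregation, repeated to
a local optimum, with independent restarts.  Directed modularity landscapes
are glassy, so the returned value is a lower bound on the optimum.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .connectome import Connectome, induced_subgraph

__all__ = [
    "Partition",
    "modularity_q",
    "optimize_partition",
    "recursive_modules",
    "read_partition_csv",
    "write_partition_csv",
]

DEFAULT_N_RESTARTS = 100


@dataclass(frozen=True)
class Partition:
    """Assignment of regions to modules (ids contiguous from 1).

    ``children`` optionally maps a module id to the sub-partition of that
    module's induced subgraph, and ``child_q`` to its within-module Q.
    """

    assignment: dict[str, int]
    children: dict[int, "Partition"] = field(default_factory=dict)
    child_q: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mods = sorted(set(self.assignment.values()))
        if mods and mods != list(range(1, len(mods) + 1)):
            raise ValueError("module ids must be contiguous from 1")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module: int) -> list[str]:
        return [r for r, m in self.assignment.items() if m == module]

    @classmethod
    def from_labels(
        cls, regions: tuple[str, ...], labels: np.ndarray
    ) -> "Partition":
        """Relabel arbitrary integer labels to contiguous ids from 1."""
        _, contiguous = np.unique(labels, return_inverse=True)
        return cls({r: int(k) + 1 for r, k in zip(regions, contiguous)})

    def labels(self, regions: tuple[str, ...]) -> np.ndarray:
        return np.array([self.assignment[r] for r in regions], dtype=np.int64)


def modularity_q(c: Connectome, p: Partition) -> float:
    """Directed Leicht–Newman modularity of partition ``p`` on ``c``."""
    missing = set(c.regions) - set(p.assignment)
    if missing:
        raise ValueError(f"partition misses regions: {sorted(missing)}")
    m = c.n_edges
    if m == 0:
        raise ValueError("modularity undefined for an empty graph")
    A = c.adjacency.astype(float)
    kin = A.sum(axis=0)
    kout = A.sum(axis=1)
    labels = p.labels(c.regions)
    same = labels[:, None] == labels[None, :]
    return float(((A - np.outer(kout, kin) / m) * same).sum() / m)


def _local_moves(
    W: np.ndarray, labels: np.ndarray, rng: np.random.Generator, m: float
) -> bool:
    """One randomized sweep of single-node moves; True if anything moved."""
    n = len(labels)
    kin = W.sum(axis=0)
    kout = W.sum(axis=1)
    n_comm = labels.max() + 1
    Kin = np.bincount(labels, weights=kin, minlength=n_comm)
    Kout = np.bincount(labels, weights=kout, minlength=n_comm)
    improved = False
    for v in rng.permutation(n):
        cv = labels[v]
        # arc weight from/to v per community (v's own self-loop excluded:
        # it travels with v and cancels in the comparison)
        w_out = np.bincount(labels, weights=W[v], minlength=n_comm)
        w_in = np.bincount(labels, weights=W[:, v], minlength=n_comm)
        w_out[cv] -= W[v, v]
        w_in[cv] -= W[v, v]
        Kin_ = Kin.copy()
        Kout_ = Kout.copy()
        Kin_[cv] -= kin[v]
        Kout_[cv] -= kout[v]
        # gain of placing v in community C (self-pair term cancels)
        gain = (w_out + w_in) / m - (kout[v] * Kin_ + kin[v] * Kout_) / m**2
        best = int(np.argmax(gain))
        if gain[best] > gain[cv] + 1e-12:
            labels[v] = best
            Kin[cv] -= kin[v]
            Kout[cv] -= kout[v]
            Kin[best] += kin[v]
            Kout[best] += kout[v]
            improved = True
    return improved


def _aggregate(W: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    comms, dense = np.unique(labels, return_inverse=True)
    k = len(comms)
    Wa = np.zeros((k, k))
    np.add.at(Wa, (dense[:, None], dense[None, :]), W)
    return Wa, dense


def _louvain_once(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    m = float(A.sum())
    W = A.astype(float)
    membership = np.arange(len(A))  # original node -> current supernode
    while True:
        labels = np.arange(len(W))
        moved = False
        while _local_moves(W, labels, rng, m):
            moved = True
        if not moved:
            break
        W, dense = _aggregate(W, labels)
        membership = dense[membership]
        if len(W) == 1:
            break
    return membership


def optimize_partition(
    c: Connectome,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
) -> tuple[Partition, float]:
    """Best directed-Q partition over ``n_restarts`` randomized restarts.

    Deterministic given ``seed``; never worse than the all-in-one
    partition.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if c.n_edges == 0:
        raise ValueError("modularity undefined for an empty graph")
    best_q = -np.inf
    best: Partition | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        membership = _louvain_once(c.adjacency, rng)
        p = Partition.from_labels(c.regions, membership)
        q = modularity_q(c, p)
        if q > best_q:
            best_q, best = q, p
    one = Partition({r: 1 for r in c.regions})
    q_one = modularity_q(c, one)
    if best is None or q_one > best_q:
        best, best_q = one, q_one
    return best, float(best_q)


def recursive_modules(
    c: Connectome,
    p: Partition,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
    min_size: int = 4,
) -> Partition:
    """Re-run the optimizer inside each module with >= ``min_size`` nodes.

    Returns a copy of ``p`` whose ``children``/``child_q`` record the
    best sub-partition and within-module Q of each decomposable module.
    """
    children: dict[int, Partition] = {}
    child_q: dict[int, float] = {}
    for mod in sorted(set(p.assignment.values())):
        members = p.members(mod)
        if len(members) < min_size:
            continue
        sub = induced_subgraph(c, members)
        if sub.n_edges == 0:
            continue
        child, q = optimize_partition(sub, n_restarts, seed + mod)
        children[mod] = child
        child_q[mod] = q
    return Partition(dict(p.assignment), children, child_q)


# -- partition files -------------------------------------------------------

def write_partition_csv(p: Partition, path: str | Path) -> None:
    """CSV ``region,module[,submodule]``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["region", "module", "submodule"])
        for region, mod in sorted(p.assignment.items()):
            sub = ""
            if mod in p.children and region in p.children[mod].assignment:
                sub = p.children[mod].assignment[region]
            w.writerow([region, mod, sub])


def read_partition_csv(path: str | Path) -> Partition:
    assignment: dict[str, int] = {}
    subs: dict[int, dict[str, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["region", "module"]:
            raise ValueError("expected header 'region,module[,submodule]'")
        for row in reader:
            if not row or not row[0].strip():
                continue
            region, mod = row[0].strip(), int(row[1])
            assignment[region] = mod
            if len(row) > 2 and row[2].strip():
                subs.setdefault(mod, {})[region] = int(row[2])
    children = {m: Partition(a) for m, a in subs.items()}
    return Partition(assignment, children)
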