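"""Synthetic directed graphs with planted structure.

A directed stochastic block model with an optional hub overlay: ordered
node pairs inside a module receive an arc with probability ``p_in``,
cross-module pairs with ``p_out``, and designated hub nodes gain extra
cross-module in- and out-arcs with probability ``hub_boost``.  The
generator returns the ground-truth partition (and hub set), giving every
analysis stage a parameter-recovery test without external data.

Defaults mimic the scale of the packaged pigeon connectome: 52 nodes,
five modules, overall density ~0.13.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .modularity import Partition

__all__ = ["PlantedSpec", "planted_partition", "planted_hubs"]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the planted-structure generator.

    ``modules`` are module sizes summing to ``n``; ``0 <= p_out < p_in <= 1``.
    ``nested`` optionally lists, per module, child module sizes for
    two-level structure (child blocks use ``p_in``; the parent block
    off-child density is ``p_mid``).
    """

    n: int = 52
    modules: tuple[int, ...] = (16, 14, 9, 7, 6)
    p_in: float = 0.35
    p_out: float = 0.04
    hubs: int = 0
    hub_boost: float = 0.0
    nested: dict[int, tuple[int, ...]] = field(default_factory=dict)
    p_mid: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.modules) != self.n:
            raise ValueError("module sizes must sum to n")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for mod, sizes in self.nested.items():
            if not 1 <= mod <= len(self.modules):
                raise ValueError(f"nested key {mod} is not a module id")
            if sum(sizes) != self.modules[mod - 1]:
                raise ValueError(f"nested sizes for module {mod} must sum to its size")


def _labels(spec: PlantedSpec) -> np.ndarray:
    labels = np.zeros(spec.n, dtype=np.int64)
    start = 0
    for mod, size in enumerate(spec.modules, start=1):
        labels[start : start + size] = mod
        start += size
    return labels


def _region_names(n: int) -> tuple[str, ...]:
    return tuple(f"r{i:03d}" for i in range(n))


def planted_partition(spec: PlantedSpec) -> tuple[Connectome, Partition]:
    """Directed SBM draw plus its ground-truth partition.

    Every ordered pair (i, j), i != j, receives an arc independently with
    probability ``p_in`` (same module; or same child module when nested
    structure is requested), ``p_mid`` (same parent module, different
    child), or ``p_out`` (different modules).  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec)
    prob = np.where(labels[:, None] == labels[None, :], spec.p_in, spec.p_out)
    if spec.nested:
        child = np.zeros(spec.n, dtype=np.int64)
        for mod, sizes in spec.nested.items():
            ids = np.where(labels == mod)[0]
            start = 0
            for ci, size in enumerate(sizes, start=1):
                child[ids[start : start + size]] = ci
                start += size
            same_parent = (labels[:, None] == mod) & (labels[None, :] == mod)
            same_child = child[:, None] == child[None, :]
            prob = np.where(same_parent & ~same_child, spec.p_mid, prob)
    A = (rng.random((spec.n, spec.n)) < prob).astype(np.int8)
    np.fill_diagonal(A, 0)
    regions = _region_names(spec.n)
    part = Partition({r: int(m) for r, m in zip(regions, labels)})
    return Connectome(regions, A), part


def planted_hubs(
    spec: PlantedSpec,
) -> tuple[Connectome, Partition, frozenset[str]]:
    """As :func:`planted_partition`, plus planted connector hubs.

    The first ``spec.hubs`` nodes of each module in round-robin order are
    designated hubs; every absent cross-module arc incident to a hub is
    added independently with probability ``hub_boost``, raising both the
    degree and the betweenness of hub nodes.  With ``hub_boost = 0`` the
    graph is identical to :func:`planted_partition` at the same seed.
    """
    if spec.hubs < 1:
        raise ValueError("spec.hubs must be >= 1 for planted_hubs")
    c, part = planted_partition(spec)
    labels = _labels(spec)
    # spread hubs across modules: first node of module 1, of module 2, ...
    starts = np.concatenate(([0], np.cumsum(spec.modules)[:-1]))
    hub_ids = []
    round_ = 0
    while len(hub_ids) < spec.hubs:
        for s, size in zip(starts, spec.modules):
            if round_ < size and len(hub_ids) < spec.hubs:
                hub_ids.append(int(s + round_))
        round_ += 1
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    A = np.array(c.adjacency, dtype=np.int8)
    if spec.hub_boost > 0:
        for h in hub_ids:
            cross = labels != labels[h]
            add_out = cross & (A[h] == 0) & (rng.random(spec.n) < spec.hub_boost)
            add_in = cross & (A[:, h] == 0) & (rng.random(spec.n) < spec.hub_boost)
            A[h, add_out] = 1
            A[add_in, h] = 1
    np.fill_diagonal(A, 0)
    hubs = frozenset(c.regions[h] for h in hub_ids)
    return Connectome(c.regions, A), part, hubs
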