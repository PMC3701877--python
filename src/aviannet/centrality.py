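"""Betweenness centrality, directed participation coefficient, and the
hub / connector-hub classification used for connective-core analysis.

A region is a *hub* when it sits in the top ``bc_top`` by betweenness AND
in the top ``deg_top`` by in-degree AND by out-degree; a hub is a
*connector hub* when its participation coefficient additionally exceeds
``p_threshold``.  Ties at a rank boundary include all tied regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import Connectome
from .modularity import Partition

__all__ = [
    "CentralityRecord",
    "betweenness",
    "normalized_betweenness",
    "participation",
    "classify_hubs",
]


def betweenness(c: Connectome) -> dict[str, float]:
    """Raw directed betweenness: for each node h, the sum over ordered
    pairs (s, t), s != t != h, of the fraction of shortest directed s->t
    paths passing through h.  Unreachable pairs contribute zero.

    Computed with Brandes accumulation (networkx); the contract is the
    ratio-sum definition, which the test suite checks against exhaustive
    path enumeration.
    """
    bc = nx.betweenness_centrality(c.to_networkx(), normalized=False)
    return {r: float(bc[r]) for r in c.regions}


def normalized_betweenness(c: Connectome) -> dict[str, float]:
    """Betweenness as a share of the network total (sums to 1)."""
    bc = betweenness(c)
    total = sum(bc.values())
    if total == 0:
        return {r: 0.0 for r in c.regions}
    return {r: v / total for r, v in bc.items()}


def participation(c: Connectome, p: Partition) -> dict[str, float]:
    """Directed participation coefficient per region.

    ``P(i) = 1 - 0.5 * (sum_c (k_in(i,c)/k_in(i))^2
                        + sum_c (k_out(i,c)/k_out(i))^2)``

    where ``k_in(i,c)`` counts arcs into i from module c.  A node with
    zero in-degree (resp. out-degree) has that half treated as fully
    concentrated (the squared-share sum is 1): absent connectivity cannot
    be spread across modules.  Hence ``P`` is always in [0, 1] and is 0
    whenever the partition has a single module.
    """
    missing = set(c.regions) - set(p.assignment)
    if missing:
        raise ValueError(f"partition misses regions: {sorted(missing)}")
    A = c.adjacency
    labels = p.labels(c.regions)
    n_mod = labels.max() + 1
    out: dict[str, float] = {}
    for i, region in enumerate(c.regions):
        halves = []
        for vec in (A[:, i], A[i, :]):  # incoming then outgoing
            k = vec.sum()
            if k == 0:
                halves.append(1.0)
                continue
            per_mod = np.bincount(labels, weights=vec.astype(float), minlength=n_mod)
            halves.append(float(((per_mod / k) ** 2).sum()))
        out[region] = 1.0 - 0.5 * (halves[0] + halves[1])
    return out


@dataclass(frozen=True)
class CentralityRecord:
    region: str
    bc: float
    bc_norm: float
    in_degree: int
    out_degree: int
    participation: float
    is_hub: bool
    is_connector_hub: bool


def _top_with_ties(values: dict[str, float], k: int) -> set[str]:
    """Regions with value >= the k-th largest value (ties included)."""
    if k <= 0 or not values:
        return set()
    cut = sorted(values.values(), reverse=True)[min(k, len(values)) - 1]
    return {r for r, v in values.items() if v >= cut}


def classify_hubs(
    c: Connectome,
    p: Partition,
    bc_top: int = 5,
    deg_top: int = 10,
    p_threshold: float = 0.35,
) -> list[CentralityRecord]:
    """Full centrality table with hub and connector-hub flags, in region
    order."""
    bc = betweenness(c)
    total_bc = sum(bc.values())
    kin = {r: int(c.adjacency[:, i].sum()) for i, r in enumerate(c.regions)}
    kout = {r: int(c.adjacency[i, :].sum()) for i, r in enumerate(c.regions)}
    part = participation(c, p)
    hubs = (
        _top_with_ties(bc, bc_top)
        & _top_with_ties({r: float(v) for r, v in kin.items()}, deg_top)
        & _top_with_ties({r: float(v) for r, v in kout.items()}, deg_top)
    )
    records = []
    for r in c.regions:
        is_hub = r in hubs
        records.append(
            CentralityRecord(
                region=r,
                bc=bc[r],
                bc_norm=bc[r] / total_bc if total_bc > 0 else 0.0,
                in_degree=kin[r],
                out_degree=kout[r],
                participation=part[r],
                is_hub=is_hub,
                is_connector_hub=is_hub and part[r] > p_threshold,
            )
        )
    return records
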