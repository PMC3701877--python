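"""Labelled directed binary graphs and the packaged pigeon telencephalon fixture.

The central container is :class:`Connectome`: an ordered list of region labels
plus a dense 0/1 adjacency matrix with the orientation *row = source,
column = target* (``adjacency[i, j] == 1`` iff a directed connection exists
from region ``i`` to region ``j``).  All metric modules consume this one
object and use the region order as the canonical key for matrix-indexed
output.

Two edge-list dialects are supported:

``plain``
    UTF-8 text, one ``SRC<TAB>DST`` per line, ``#`` comments.

``table2``
    The row convention used by printed connection tables of tract-tracing
    meta-analyses: each line is a row region followed by semicolon-separated
    statements ``→ X: citations`` (row → X) and ``← X: citations`` (X → row).
    Citation numbers are discarded; duplicate mentions collapse.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Connectome",
    "DegreeRecord",
    "PIGEON_REGIONS",
    "load_edge_list",
    "parse_table2_text",
    "pigeon_connectome",
    "degrees",
    "induced_subgraph",
    "write_edge_list",
    "to_matrix_csv",
    "to_graphml",
]

#: The 52 telencephalic regions of the pigeon fixture, alphabetically ordered.
#: "Field L1/L2/L3" are registered under the short labels used as row keys.
PIGEON_REGIONS: tuple[str, ...] = (
    "AA", "AD", "AI", "AIvm", "AM", "APH", "AV", "Ac", "BO", "Bas",
    "CDL", "CPP", "CPi", "Ee", "Ei", "Ep", "GP", "HA", "HD", "HI",
    "HL", "Hp-DM", "Hp-VM", "IHA", "L1", "L2", "L3", "MC", "MD", "MM",
    "MVL", "NCC", "NCL", "NCM", "NCVl", "NDB", "NFL", "NFM", "NIL",
    "NIMl", "NMm", "NSTL", "PoA", "SL", "SM", "SpA", "StL", "StM",
    "TPO", "TnA", "TuO", "VP",
)

# Long-form labels occurring inside table rows are normalized to registry keys.
_LABEL_ALIASES = {"Field L1": "L1", "Field L2": "L2", "Field L3": "L3"}


class ConnectomeError(ValueError):
    """Malformed edge-list input or a label outside the enforced registry."""


@dataclass(frozen=True)
class DegreeRecord:
    """In-, out- and total degree of one region."""

    region: str
    in_degree: int
    out_degree: int

    @property
    def total_degree(self) -> int:
        return self.in_degree + self.out_degree


@dataclass(frozen=True, eq=False)
class Connectome:
    """A labelled, simple, binary digraph.

    Parameters
    ----------
    regions
        Ordered region labels; must be unique and non-empty.
    adjacency
        ``(n, n)`` matrix with entries in {0, 1}, zero diagonal;
        ``adjacency[i, j] == 1`` means an arc ``regions[i] -> regions[j]``.
    """

    regions: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.int8)
        n = len(self.regions)
        if A.shape != (n, n):
            raise ConnectomeError(f"adjacency shape {A.shape} != ({n}, {n})")
        if not np.isin(A, (0, 1)).all():
            raise ConnectomeError("adjacency entries must be 0 or 1")
        if np.diagonal(A).any():
            raise ConnectomeError("self-loops are not allowed")
        if len(set(self.regions)) != n or any(not r for r in self.regions):
            raise ConnectomeError("region labels must be unique and non-empty")
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "adjacency", A)
        A.setflags(write=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return self.regions == other.regions and np.array_equal(
            self.adjacency, other.adjacency
        )

    def __hash__(self) -> int:
        return hash((self.regions, self.adjacency.tobytes()))

    # -- basic accessors ---------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def index(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}") from None

    def has_edge(self, src: str, dst: str) -> bool:
        return bool(self.adjacency[self.index(src), self.index(dst)])

    def edges(self) -> list[tuple[str, str]]:
        """All arcs as (source, target) label pairs, row-major order."""
        src, dst = np.nonzero(self.adjacency)
        return [(self.regions[i], self.regions[j]) for i, j in zip(src, dst)]

    def to_networkx(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(self.regions)
        G.add_edges_from(self.edges())
        return G

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        regions: Sequence[str] | None = None,
    ) -> "Connectome":
        """Build from (source, target) pairs; region set defaults to the
        union of mentioned labels in sorted order."""
        edges = list(edges)
        if regions is None:
            regions = sorted({x for e in edges for x in e})
        regions = tuple(regions)
        idx = {r: i for i, r in enumerate(regions)}
        A = np.zeros((len(regions), len(regions)), dtype=np.int8)
        for a, b in edges:
            if a not in idx or b not in idx:
                raise ConnectomeError(f"edge ({a!r}, {b!r}) outside region set")
            if a == b:
                raise ConnectomeError(f"self-loop on {a!r}")
            A[idx[a], idx[b]] = 1
        return cls(regions, A)


# -- parsing ---------------------------------------------------------------

_TABLE2_STMT = re.compile(r"^(?:[A-Za-z0-9\-]+\s*)?(→|←|->|<-)\s*(.+?)\s*:")


def _normalize_label(label: str) -> str:
    return _LABEL_ALIASES.get(label, label)


def parse_table2_text(
    text: str, registry: Sequence[str] | None = None
) -> Connectome:
    """Parse the ``table2`` dialect from a string.

    Each non-comment line is ``ROW<TAB>statements``.  A statement
    ``→ X: refs`` under row R denotes the arc R → X, ``← X: refs`` denotes
    X → R.  A stray repeat of the row label before the arrow (a known
    typographic artefact) is tolerated; trailing citation lists after the
    colon are discarded.
    """
    edges: set[tuple[str, str]] = set()
    mentioned: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" not in line:
            raise ConnectomeError(f"line {lineno}: expected 'ROW<TAB>statements'")
        row, rest = line.split("\t", 1)
        row = _normalize_label(row.strip())
        mentioned.add(row)
        for stmt in rest.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            m = _TABLE2_STMT.match(stmt)
            if m is None:
                raise ConnectomeError(f"line {lineno}: malformed statement {stmt!r}")
            arrow, other = m.group(1), _normalize_label(m.group(2).strip())
            mentioned.add(other)
            src, dst = (row, other) if arrow in ("→", "->") else (other, row)
            if src == dst:
                raise ConnectomeError(f"line {lineno}: self-loop on {src!r}")
            edges.add((src, dst))
    if registry is not None:
        unknown = mentioned - set(registry)
        if unknown:
            raise ConnectomeError(f"labels outside registry: {sorted(unknown)}")
        return Connectome.from_edges(edges, regions=registry)
    return Connectome.from_edges(edges)


def load_edge_list(
    path: str | Path,
    dialect: str = "plain",
    registry: Sequence[str] | None = None,
) -> Connectome:
    """Read a connectome from ``path`` in the given dialect.

    With a ``registry``, the region set (and its order) is taken from the
    registry and any label outside it is an error; otherwise the region set
    is the sorted union of mentioned labels.
    """
    text = Path(path).read_text(encoding="utf-8")
    if dialect == "table2":
        return parse_table2_text(text, registry=registry)
    if dialect != "plain":
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: set[tuple[str, str]] = set()
    mentioned: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ConnectomeError(f"line {lineno}: expected 'SRC<TAB>DST'")
        a, b = parts[0].strip(), parts[1].strip()
        if a == b:
            raise ConnectomeError(f"line {lineno}: self-loop on {a!r}")
        mentioned.update((a, b))
        edges.add((a, b))
    if registry is not None:
        unknown = mentioned - set(registry)
        if unknown:
            raise ConnectomeError(f"labels outside registry: {sorted(unknown)}")
        return Connectome.from_edges(edges, regions=registry)
    return Connectome.from_edges(edges)


def write_edge_list(c: Connectome, path: str | Path) -> None:
    """Write the ``plain`` dialect (round-trips with ``load_edge_list``)."""
    lines = ["# aviannet plain edge list: SRC<TAB>DST"]
    lines += [f"{a}\t{b}" for a, b in c.edges()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def to_matrix_csv(c: Connectome, path: str | Path) -> None:
    """Dense 0/1 matrix CSV with region labels as header row and column."""
    rows = ["," + ",".join(c.regions)]
    for i, r in enumerate(c.regions):
        rows.append(r + "," + ",".join(str(int(x)) for x in c.adjacency[i]))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def to_graphml(c: Connectome, path: str | Path) -> None:
    nx.write_graphml(c.to_networkx(), str(path))


# -- packaged fixture ------------------------------------------------------

_FIXTURE_CACHE: dict[str, Connectome] = {}


def _fixture_text() -> str:
    return (
        resources.files("aviannet.data")
        .joinpath("pigeon_table2.txt")
        .read_text(encoding="utf-8")
    )


def pigeon_fixture_sha256() -> str:
    """Checksum of the frozen transcription file (reviewed data gate)."""
    return hashlib.sha256(_fixture_text().encode("utf-8")).hexdigest()


def pigeon_connectome() -> Connectome:
    """The packaged pigeon telencephalon connectome.

    52 regions (see :data:`PIGEON_REGIONS`), 344 directed connections,
    transcribed from the published tract-tracing meta-analysis table.
    Idempotent and bit-identical across calls.
    """
    if "pigeon" not in _FIXTURE_CACHE:
        _FIXTURE_CACHE["pigeon"] = parse_table2_text(
            _fixture_text(), registry=PIGEON_REGIONS
        )
    return _FIXTURE_CACHE["pigeon"]


# -- degrees and subgraphs -------------------------------------------------

def degrees(c: Connectome) -> list[DegreeRecord]:
    """One :class:`DegreeRecord` per region, in region order."""
    kin = c.adjacency.sum(axis=0)
    kout = c.adjacency.sum(axis=1)
    return [
        DegreeRecord(r, int(kin[i]), int(kout[i]))
        for i, r in enumerate(c.regions)
    ]


def induced_subgraph(c: Connectome, keep: Iterable[str]) -> Connectome:
    """Restrict to ``keep`` (original region order preserved)."""
    keep = set(keep)
    unknown = keep - set(c.regions)
    if unknown:
        raise KeyError(f"unknown regions: {sorted(unknown)}")
    ids = [i for i, r in enumerate(c.regions) if r in keep]
    sub = c.adjacency[np.ix_(ids, ids)] if ids else np.zeros((0, 0), dtype=np.int8)
    return Connectome(tuple(c.regions[i] for i in ids), sub)
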