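"""Readers, writers and container types for the five input data kinds.

All formats are UTF-8, tab-separated text; lines starting with ``#`` are
comments.  Protein identifiers are opaque, case-sensitive strings — no ID
normalisation or cross-database mapping is attempted.

The five kinds:

* **network** — two-column edge list of an undirected PPI graph,
* **expression** — matrix with a header of time-point labels, one row per
  protein (its expression time course),
* **subcellular** — two-column (protein, location) annotation records,
* **complexes** — one protein complex per line, members tab-separated,
* **essential** — one known-essential protein ID per line.

Loaders validate aggressively (hard errors name the offending line) because
downstream scores silently absorb missing proteins via neutral defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DataFormatError",
    "ProteinNetwork",
    "ExpressionMatrix",
    "SubcellularData",
    "ComplexCatalog",
    "EssentialSet",
    "load_network",
    "write_network",
    "load_expression",
    "write_expression",
    "load_subcellular",
    "write_subcellular",
    "load_complexes",
    "write_complexes",
    "load_essential",
    "write_essential",
    "write_ranking",
    "load_ranking",
]


class DataFormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


class ProteinNetwork:
    """Simple undirected graph over protein identifiers.

    Maintains per-node neighbor sets; guarantees no self-loops, no parallel
    edges, and symmetry of the adjacency relation.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        self._adj: dict[str, set[str]] = {}
        for n in nodes:
            self._adj.setdefault(n, set())
        for i, j in edges:
            self.add_edge(i, j)

    def add_node(self, n: str) -> None:
        self._adj.setdefault(n, set())

    def add_edge(self, i: str, j: str) -> bool:
        """Add an undirected edge; self-loops are ignored.

        Returns True if the edge was new.
        """
        if i == j:
            return False
        self._adj.setdefault(i, set())
        self._adj.setdefault(j, set())
        if j in self._adj[i]:
            return False
        self._adj[i].add(j)
        self._adj[j].add(i)
        return True

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {
            frozenset((i, j)) for i, nbrs in self._adj.items() for j in nbrs if i < j
        }

    def edge_list(self) -> list[tuple[str, str]]:
        """Deterministically ordered edges as (min, max) ID pairs."""
        return sorted(
            (min(i, j), max(i, j))
            for i, nbrs in self._adj.items()
            for j in nbrs
            if i < j
        )

    def neighbors(self, n: str) -> set[str]:
        return self._adj[n]

    def degree(self, n: str) -> int:
        return len(self._adj[n])

    def has_node(self, n: str) -> bool:
        return n in self._adj

    def has_edge(self, i: str, j: str) -> bool:
        return i in self._adj and j in self._adj[i]

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def __contains__(self, n: str) -> bool:
        return n in self._adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinNetwork):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProteinNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def to_networkx(self):
        """Export as a networkx.Graph (nodes preserved, including isolates)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._adj)
        g.add_edges_from(self.edge_list())
        return g

    @classmethod
    def from_networkx(cls, g) -> "ProteinNetwork":
        net = cls(nodes=(str(n) for n in g.nodes))
        for i, j in g.edges:
            net.add_edge(str(i), str(j))
        return net

    def connected_components(self) -> list[set[str]]:
        """Connected components, largest first (ties by smallest member ID)."""
        seen: set[str] = set()
        comps: list[set[str]] = []
        for start in self.sorted_nodes():
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in self._adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps


@dataclass
class ExpressionMatrix:
    """Per-protein gene-expression time courses of a common length T."""

    profiles: dict[str, np.ndarray]
    T: int

    def __post_init__(self) -> None:
        if self.T < 2:
            raise DataFormatError(f"need at least 2 time points, got T={self.T}")
        for pid, vec in self.profiles.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (self.T,):
                raise DataFormatError(
                    f"profile for {pid!r} has length {arr.size}, expected {self.T}"
                )
            self.profiles[pid] = arr

    def __contains__(self, pid: str) -> bool:
        return pid in self.profiles

    def __getitem__(self, pid: str) -> np.ndarray:
        return self.profiles[pid]

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class SubcellularData:
    """Unique (protein, location) annotation records."""

    records: set[tuple[str, str]]

    @property
    def locations(self) -> set[str]:
        return {loc for _, loc in self.records}

    @property
    def proteins(self) -> set[str]:
        return {pid for pid, _ in self.records}

    def locations_of(self, pid: str) -> set[str]:
        return {loc for p, loc in self.records if p == pid}


@dataclass
class ComplexCatalog:
    """Ordered catalog of protein complexes (duplicate member sets removed)."""

    complexes: list[frozenset[str]]

    @property
    def M(self) -> int:
        return len(self.complexes)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class EssentialSet:
    """Ground-truth set of known essential protein IDs."""

    members: set[str]

    def __contains__(self, pid: str) -> bool:
        return pid in self.members

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# loaders


def load_network(path: str | Path) -> ProteinNetwork:
    """Read a two-column TSV edge list into a simple undirected graph.

    Repeated interactions (in either orientation) and self-connecting
    interactions are removed; the counts of dropped records are logged.
    """
    path = Path(path)
    net = ProteinNetwork()
    n_dup = n_self = n_kept = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise DataFormatError(
                f"{path}:{lineno}: expected at least 2 tab-separated fields"
            )
        i, j = fields[0], fields[1]
        if i == j:
            n_self += 1
        elif net.add_edge(i, j):
            n_kept += 1
        else:
            n_dup += 1
    if n_kept == 0:
        raise DataFormatError(f"{path}: no valid edges found")
    logger.info(
        "loaded network from %s: %d nodes, %d edges (%d duplicate, %d self-loop "
        "records dropped)",
        path, net.n_nodes, net.n_edges, n_dup, n_self,
    )
    return net


def write_network(network: ProteinNetwork, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in network.edge_list():
            fh.write(f"{i}\t{j}\n")
    return path


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix: header of T labels, rows of ID + T values.

    Rows containing non-numeric cells are rejected (with a warning); a row
    with the wrong number of fields, or a duplicate protein ID, is a hard
    error.
    """
    path = Path(path)
    it = _data_lines(path)
    try:
        _, header = next(it)
    except StopIteration:
        raise DataFormatError(f"{path}: empty file") from None
    labels = header.split("\t")
    # header may or may not carry a leading ID-column label; data rows decide
    profiles: dict[str, np.ndarray] = {}
    T: int | None = None
    for lineno, line in it:
        fields = line.split("\t")
        if T is None:
            T = len(fields) - 1
            if T < 2:
                raise DataFormatError(f"{path}:{lineno}: need at least 2 time points")
            if len(labels) not in (T, T + 1):
                raise DataFormatError(
                    f"{path}: header has {len(labels)} fields, inconsistent with "
                    f"rows of 1 ID + {T} values"
                )
        if len(fields) != T + 1:
            raise DataFormatError(
                f"{path}:{lineno}: expected {T + 1} fields, got {len(fields)}"
            )
        pid = fields[0]
        if pid in profiles:
            raise DataFormatError(f"{path}:{lineno}: duplicate protein ID {pid!r}")
        try:
            vec = np.array([float(x) for x in fields[1:]])
        except ValueError:
            logger.warning("%s:%d: non-numeric cell, row %r rejected", path, lineno, pid)
            continue
        profiles[pid] = vec
    if T is None or not profiles:
        raise DataFormatError(f"{path}: no expression rows found")
    return ExpressionMatrix(profiles=profiles, T=T)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\t" + "\t".join(f"t{k}" for k in range(expr.T)) + "\n")
        for pid in sorted(expr.profiles):
            vals = "\t".join(repr(float(v)) for v in expr.profiles[pid])
            fh.write(f"{pid}\t{vals}\n")
    return path


def load_subcellular(path: str | Path) -> SubcellularData:
    """Read two-column (protein, location) records; duplicates collapse."""
    path = Path(path)
    records: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise DataFormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields"
            )
        records.add((fields[0], fields[1]))
    return SubcellularData(records=records)


def write_subcellular(subcell: SubcellularData, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for pid, loc in sorted(subcell.records):
            fh.write(f"{pid}\t{loc}\n")
    return path


def load_complexes(path: str | Path) -> ComplexCatalog:
    """Read one complex per line; complexes with identical member sets merge."""
    path = Path(path)
    complexes: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for lineno, line in _data_lines(path):
        members = frozenset(f for f in line.split("\t") if f)
        if not members:
            raise DataFormatError(f"{path}:{lineno}: empty complex")
        if members not in seen:
            seen.add(members)
            complexes.append(members)
    return ComplexCatalog(complexes=complexes)


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for c in catalog.complexes:
            fh.write("\t".join(sorted(c)) + "\n")
    return path


def load_essential(path: str | Path) -> EssentialSet:
    path = Path(path)
    members: set[str] = set()
    for _, line in _data_lines(path):
        members.add(line.split("\t")[0])
    return EssentialSet(members=members)


def write_essential(essential: EssentialSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(essential.members):
            fh.write(pid + "\n")
    return path


def write_ranking(
    ranking: Sequence[str],
    path: str | Path,
    scores: Mapping[str, float] | None = None,
) -> Path:
    """Write a ranked protein list as TSV with columns rank, protein, score."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tprotein\tscore\n")
        for k, pid in enumerate(ranking, start=1):
            s = "" if scores is None else repr(float(scores[pid]))
            fh.write(f"{k}\t{pid}\t{s}\n")
    return path


def load_ranking(path: str | Path) -> list[str]:
    """Read back a ranked-output TSV (rank, protein, score) into an ID list."""
    path = Path(path)
    out: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "rank":
            continue
        if len(fields) < 2:
            raise DataFormatError(f"{path}:{lineno}: expected rank/protein columns")
        out.append(fields[1])
    return out
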