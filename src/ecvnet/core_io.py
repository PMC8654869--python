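"""Domain types and tab-delimited readers/writers shared across the pipeline.

All on-disk formats are UTF-8 TSV:

* expression matrix  -- header row of sample ids, first column gene ids,
  numeric body (genes x samples, log-scale values);
* edge list          -- two columns ``parent<TAB>child``, no header;
* SIF                -- ``parent<TAB>pd<TAB>child`` (Cytoscape "pd" interaction);
* clinical table     -- header ``sample_id  time  event``.

Readers validate type invariants and raise :class:`ValueError` on violations
rather than coercing silently.  Matrices are addressed by id everywhere;
positional indexing is an implementation detail of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (len(gene_ids), len(sample_ids))

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r} (missing values are not supported)"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector (over samples) of one gene."""
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not present in expression matrix") from None

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class EdgeId:
    """Directed edge ``parent -> child``; canonical string form "parent->child"."""

    parent: str
    child: str

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise ValueError(f"self-loop edge {self.parent!r}->{self.child!r}")

    def __str__(self) -> str:
        return f"{self.parent}->{self.child}"

    @classmethod
    def from_string(cls, s: str) -> "EdgeId":
        parent, sep, child = s.partition("->")
        if not sep or not parent or not child:
            raise ValueError(f"malformed edge id {s!r}; expected 'parent->child'")
        return cls(parent, child)

    def as_tuple(self) -> tuple[str, str]:
        return (self.parent, self.child)


class NetworkStructure:
    """Directed acyclic graph over gene ids.

    Edges are (parent, child) pairs; duplicates and self-loops are rejected,
    and construction fails with one offending cycle spelled out if the edge
    set is cyclic.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        _check_unique(self.nodes, "node")
        node_set = set(self.nodes)
        self.edges: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for parent, child in edges:
            if parent == child:
                raise ValueError(f"self-loop on node {parent!r}")
            if (parent, child) in seen:
                raise ValueError(f"duplicate edge {parent!r}->{child!r}")
            for endpoint in (parent, child):
                if endpoint not in node_set:
                    node_set.add(endpoint)
                    self.nodes.append(endpoint)
            seen.add((parent, child))
            self.edges.append((parent, child))
        cycle = find_cycle(self.nodes, self.edges)
        if cycle is not None:
            raise ValueError("edge set contains a cycle: " + " -> ".join(cycle))
        self._parents: dict[str, list[str]] = {n: [] for n in self.nodes}
        self._children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for parent, child in self.edges:
            self._parents[child].append(parent)
            self._children[parent].append(child)

    def parents(self, node: str) -> list[str]:
        return list(self._parents[node])

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def has_edge(self, parent: str, child: str) -> bool:
        return (parent, child) in set(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_ids(self) -> list[EdgeId]:
        return [EdgeId(p, c) for p, c in self.edges]

    def topological_order(self) -> list[str]:
        order: list[str] = []
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        frontier = [n for n in self.nodes if indeg[n] == 0]
        while frontier:
            n = frontier.pop(0)
            order.append(n)
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    frontier.append(c)
        return order

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkStructure):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(other.edges)

    def __repr__(self) -> str:
        return f"NetworkStructure({len(self.nodes)} nodes, {len(self.edges)} edges)"


def find_cycle(nodes: Sequence[str], edges: Sequence[tuple[str, str]]) -> list[str] | None:
    """Return one directed cycle as a node list (closed walk), or None."""
    children: dict[str, list[str]] = {n: [] for n in nodes}
    for p, c in edges:
        children.setdefault(p, []).append(c)
        children.setdefault(c, [])
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in children}
    stack: list[str] = []

    def visit(n: str) -> list[str] | None:
        color[n] = GRAY
        stack.append(n)
        for c in children[n]:
            if color[c] == GRAY:
                i = stack.index(c)
                return stack[i:] + [c]
            if color[c] == WHITE:
                found = visit(c)
                if found is not None:
                    return found
        stack.pop()
        color[n] = BLACK
        return None

    for n in list(children):
        if color[n] == WHITE:
            found = visit(n)
            if found is not None:
                return found
    return None


@dataclass
class SurvivalData:
    """One right-censored survival record: time in days, event 1=death, 0=censored."""

    sample_id: str
    time: float
    event: int
    group: str | None = None

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"sample {self.sample_id!r}: time must be finite and >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event!r}")
        self.event = int(self.event)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (header = sample ids)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: expected a tab-delimited header with sample ids")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {len(sample_ids) + 1}"
                )
            gene_ids.append(fields[0])
            row = []
            for col, cell in enumerate(fields[1:]):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at gene {fields[0]!r}, "
                        f"sample {sample_ids[col]!r} (line {lineno})"
                    ) from None
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_edges(path: str | Path, nodes: Iterable[str] | None = None) -> NetworkStructure:
    """Read a two-column (parent, child) edge-list TSV into a DAG."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'parent<TAB>child'")
            edges.append((fields[0], fields[1]))
    return NetworkStructure(list(nodes) if nodes else [], edges)


def write_edges(structure: NetworkStructure, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for parent, child in structure.edges:
            fh.write(f"{parent}\t{child}\n")


def write_sif(structure: NetworkStructure, path: str | Path) -> None:
    """Write Cytoscape SIF lines ``parent<TAB>pd<TAB>child`` (isolated nodes as bare lines)."""
    path = Path(path)
    linked = {n for e in structure.edges for n in e}
    with path.open("w", encoding="utf-8") as fh:
        for parent, child in structure.edges:
            fh.write(f"{parent}\tpd\t{child}\n")
        for node in structure.nodes:
            if node not in linked:
                fh.write(f"{node}\n")


def read_clinical(path: str | Path) -> list[SurvivalData]:
    """Read a clinical TSV with header columns sample_id, time, event."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        event_raw = row["event"]
        if float(event_raw) not in (0.0, 1.0):
            raise ValueError(f"{path}: sample {row['sample_id']!r}: event must be 0 or 1, got {event_raw!r}")
        records.append(SurvivalData(str(row["sample_id"]), float(row["time"]), int(float(event_raw))))
    return records


def write_clinical(records: Sequence[SurvivalData], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{repr(r.time)}\t{r.event}\n")
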