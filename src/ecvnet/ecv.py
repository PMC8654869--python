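"""Edge contribution values (ECv), multi-group contrasts, and
subtype-specific edge extraction.

The ECv of edge ``parent -> child`` for one sample is the fitted smooth
``m_k`` of that edge evaluated at the sample's parent expression, i.e. the
additive share of the edge in the child's fitted value.  Collecting all
edges over all samples gives the samples x edges ECv matrix; its rows are
the per-patient "quantified networks".

For M patient groups, each edge's contrast for group r is the absolute
difference between the group-r mean ECv and the pooled mean ECv over all
other groups.  Per group, the top fraction of edges by this contrast is
selected, and an edge is *specific* to a group iff no other group also
selected it (Venn exclusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import EdgeId, ExpressionMatrix, NetworkStructure
from .network import FittedNetwork

__all__ = [
    "ECvMatrix",
    "GroupAssignment",
    "DeltaECvTable",
    "compute_ecv",
    "delta_ecv",
    "extract_subtype_specific_edges",
    "induced_subnetwork",
    "largest_weak_component",
    "out_degrees",
]


@dataclass
class ECvMatrix:
    """Samples (rows) x edges (columns) matrix of edge contribution values."""

    sample_ids: list[str]
    edge_ids: list[str]  # canonical "parent->child" strings
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.edge_ids = list(self.edge_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in ECv matrix")
        if len(set(self.edge_ids)) != len(self.edge_ids):
            raise ValueError("duplicate edge ids in ECv matrix")
        if self.values.shape != (len(self.sample_ids), len(self.edge_ids)):
            raise ValueError("ECv value shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ECv matrix contains non-finite values")
        self._row = {s: i for i, s in enumerate(self.sample_ids)}
        self._col = {e: i for i, e in enumerate(self.edge_ids)}

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    def column(self, edge_id: str) -> np.ndarray:
        return self.values[:, self._col[edge_id]]

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self._row[sample_id]]

    def subset_edges(self, edge_ids: Sequence[str]) -> "ECvMatrix":
        idx = [self._col[e] for e in edge_ids]
        return ECvMatrix(self.sample_ids, list(edge_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.edge_ids)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("sample_id\t" + "\t".join(self.edge_ids) + "\n")
            for s, row in zip(self.sample_ids, self.values):
                fh.write(s + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ECvMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(map(str, df.index)), list(df.columns), df.to_numpy(dtype=float))


class GroupAssignment:
    """Mapping sample id -> group label, with at least two non-empty groups."""

    def __init__(self, labels: Mapping[str, str | int]):
        self.labels: dict[str, str] = {str(s): str(g) for s, g in labels.items()}
        groups: dict[str, list[str]] = {}
        for s, g in self.labels.items():
            groups.setdefault(g, []).append(s)
        if len(groups) < 2:
            raise ValueError("need at least two groups")
        self.groups: dict[str, list[str]] = {g: sorted(ms) for g, ms in groups.items()}

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups)

    def members(self, group: str) -> list[str]:
        return list(self.groups[group])

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class DeltaECvTable:
    """Per-(group, edge) contrast values plus per-group selected/specific sets."""

    group_names: list[str]
    edge_ids: list[str]
    values: np.ndarray  # (n_groups, n_edges), all >= 0
    top_sets: dict[str, list[str]] = field(default_factory=dict)
    exclusive_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.group_names), len(self.edge_ids)):
            raise ValueError("delta table shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("contrast values must be >= 0")

    def value(self, group: str, edge_id: str) -> float:
        return float(
            self.values[self.group_names.index(group), self.edge_ids.index(edge_id)]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.group_names):
            top = set(self.top_sets.get(g, []))
            excl = set(self.exclusive_sets.get(g, []))
            for ei, e in enumerate(self.edge_ids):
                rows.append(
                    {
                        "edge": e,
                        "group": g,
                        "delta_ecv": self.values[gi, ei],
                        "selected": int(e in top),
                        "exclusive": int(e in excl),
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_ecv(network: FittedNetwork, X: ExpressionMatrix) -> ECvMatrix:
    """ECv matrix of all network edges for all samples of X.

    Samples need not be the training samples; parent values outside a
    smooth's training range are clamped to it.  Intercept-only children
    contribute no columns.
    """
    edge_ids: list[str] = []
    cols: list[np.ndarray] = []
    for child in network.structure.nodes:
        model = network.models[child]
        for k, parent in enumerate(model.parents):
            if not X.has_gene(parent):
                raise ValueError(f"edge {parent}->{child}: gene {parent!r} absent from X")
            edge_ids.append(str(EdgeId(parent, child)))
            cols.append(model.component(k, X.gene(parent)))
    values = (
        np.column_stack(cols) if cols else np.empty((X.n_samples, 0))
    )
    return ECvMatrix(list(X.sample_ids), edge_ids, values)


def delta_ecv(ecv: ECvMatrix, groups: GroupAssignment) -> DeltaECvTable:
    """Per-group absolute mean-vs-rest contrast for every edge.

    For each group r: |mean over r  -  mean over the pooled complement|.
    With two groups the two rows are identical by symmetry.
    """
    names = groups.group_names
    row_indices: dict[str, np.ndarray] = {}
    for g in names:
        members = [s for s in groups.members(g) if s in ecv._row]
        if not members:
            raise ValueError(f"group {g!r} has no samples in the ECv matrix")
        row_indices[g] = np.array([ecv._row[s] for s in members])

    values = np.zeros((len(names), ecv.n_edges))
    for gi, g in enumerate(names):
        inside = ecv.values[row_indices[g]]
        rest_idx = np.concatenate([row_indices[h] for h in names if h != g])
        rest = ecv.values[rest_idx]
        values[gi] = np.abs(inside.mean(axis=0) - rest.mean(axis=0))
    return DeltaECvTable(names, list(ecv.edge_ids), values)


def extract_subtype_specific_edges(
    table: DeltaECvTable, top_fraction: float = 0.01
) -> DeltaECvTable:
    """Fill per-group top sets and Venn-exclusive (subtype-specific) sets.

    Each group selects the ceil(top_fraction * E) edges with largest
    contrast (ties broken by ascending edge id); an edge is specific to a
    group iff it appears in that group's top set only.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    E = len(table.edge_ids)
    n_top = min(E, math.ceil(top_fraction * E))
    top_sets: dict[str, list[str]] = {}
    for gi, g in enumerate(table.group_names):
        order = sorted(range(E), key=lambda i: (-table.values[gi, i], table.edge_ids[i]))
        top_sets[g] = [table.edge_ids[i] for i in order[:n_top]]
    exclusive: dict[str, list[str]] = {}
    for g in table.group_names:
        others = set().union(
            *(set(top_sets[h]) for h in table.group_names if h != g)
        )
        exclusive[g] = [e for e in top_sets[g] if e not in others]
    return DeltaECvTable(
        table.group_names, table.edge_ids, table.values, top_sets, exclusive
    )


def induced_subnetwork(
    network: NetworkStructure | FittedNetwork,
    edge_ids: Iterable[str | EdgeId],
    largest_component: bool = False,
) -> NetworkStructure:
    """Subgraph of the network on the given edges.

    With ``largest_component=True``, restrict further to the largest weakly
    connected component.
    """
    structure = network.structure if isinstance(network, FittedNetwork) else network
    known = set(structure.edges)
    edges: list[tuple[str, str]] = []
    for e in edge_ids:
        pair = EdgeId.from_string(e).as_tuple() if isinstance(e, str) else e.as_tuple()
        if pair not in known:
            raise ValueError(f"edge {pair[0]}->{pair[1]} not present in the network")
        edges.append(pair)
    nodes = list(dict.fromkeys(n for e in edges for n in e))
    sub = NetworkStructure(nodes, edges)
    if largest_component and sub.edges:
        sub = largest_weak_component(sub)
    return sub


def largest_weak_component(structure: NetworkStructure) -> NetworkStructure:
    """Largest weakly connected component (ties: smallest member node id)."""
    g = nx.DiGraph()
    g.add_nodes_from(structure.nodes)
    g.add_edges_from(structure.edges)
    components = sorted(
        nx.weakly_connected_components(g), key=lambda c: (-len(c), min(c))
    )
    if not components:
        return NetworkStructure([], [])
    keep = components[0]
    edges = [(p, c) for p, c in structure.edges if p in keep and c in keep]
    return NetworkStructure(sorted(keep), edges)


def out_degrees(structure: NetworkStructure) -> dict[str, int]:
    """Out-degree per node (hub ranking of subtype subnetworks)."""
    deg = {n: 0 for n in structure.nodes}
    for parent, _child in structure.edges:
        deg[parent] += 1
    return deg
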