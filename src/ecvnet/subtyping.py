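"""Edge selection by cross-patient variance and hierarchical clustering of
patients into subtypes.

Edges are ranked by the unbiased sample variance of their ECv across
patients and the top N (default 250) are kept; patients are then clustered
agglomeratively (Ward/Euclidean by default) on the reduced matrix.  Cluster
labels are renumbered 1..k by decreasing cluster size (ties: smallest member
sample id) so assignments are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

from .ecv import ECvMatrix, GroupAssignment

__all__ = [
    "EdgeSelection",
    "SubtypeAssignment",
    "rank_edges_by_variance",
    "select_top_edges",
    "cluster_patients",
    "compare_assignments",
    "adjusted_rand_index",
    "rank_genes_by_variance",
    "silhouette_scan",
    "linkage_to_newick",
]

_LINKAGES = ("ward", "single", "complete", "average")


@dataclass
class EdgeSelection:
    """Edges ranked by descending ECv variance (ties: ascending edge id)."""

    edge_ids: list[str]
    variances: np.ndarray
    n_selected: int

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances < 0):
            raise ValueError("variances must be >= 0")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("ranking is not consistent with stored variances")

    def selected(self) -> list[str]:
        return self.edge_ids[: self.n_selected]


@dataclass
class SubtypeAssignment:
    """Patient -> subtype labels (1..k) plus the agglomeration tree."""

    labels: dict[str, int]
    merge_tree: np.ndarray  # scipy linkage matrix, (n-1, 4)
    k: int
    linkage_method: str
    distance_metric: str
    scaled_columns: bool
    sample_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        got = sorted(set(self.labels.values()))
        if got != list(range(1, self.k + 1)):
            raise ValueError(f"labels must be contiguous 1..{self.k}, got {got}")
        if self.merge_tree.shape[0] != len(self.labels) - 1:
            raise ValueError("agglomeration tree must have n-1 merges")

    def as_groups(self) -> GroupAssignment:
        return GroupAssignment({s: str(l) for s, l in self.labels.items()})

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("sample_id\tsubtype\n")
            for s in sorted(self.labels):
                fh.write(f"{s}\t{self.labels[s]}\n")


def rank_edges_by_variance(ecv: ECvMatrix, n_selected: int | None = None) -> EdgeSelection:
    """Rank edges by unbiased (n-1) variance of ECv across patients."""
    if len(ecv.sample_ids) < 2:
        raise ValueError("variance ranking needs at least 2 samples")
    variances = ecv.values.var(axis=0, ddof=1)
    order = sorted(range(ecv.n_edges), key=lambda i: (-variances[i], ecv.edge_ids[i]))
    n = n_selected if n_selected is not None else ecv.n_edges
    return EdgeSelection(
        edge_ids=[ecv.edge_ids[i] for i in order],
        variances=variances[order],
        n_selected=min(n, ecv.n_edges),
    )


def select_top_edges(
    selection: EdgeSelection, ecv: ECvMatrix, n: int = 250
) -> ECvMatrix:
    """Reduced ECv matrix with the min(n, E) highest-variance edges in rank order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return ecv.subset_edges(selection.edge_ids[: min(n, len(selection.edge_ids))])


def _relabel_by_size(sample_ids: Sequence[str], raw: np.ndarray, k: int) -> dict[str, int]:
    clusters: dict[int, list[str]] = {}
    for s, c in zip(sample_ids, raw):
        clusters.setdefault(int(c), []).append(s)
    ranked = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    labels: dict[str, int] = {}
    for new, members in enumerate(ranked, start=1):
        for s in members:
            labels[s] = new
    return labels


def cluster_patients(
    ecv: ECvMatrix,
    k: int = 3,
    linkage_method: str = "ward",
    distance_metric: str = "euclidean",
    scale_columns: bool = False,
) -> SubtypeAssignment:
    """Agglomerative clustering of patients (rows) cut to exactly k clusters."""
    n = len(ecv.sample_ids)
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    V = ecv.values.copy()
    if scale_columns:
        sd = V.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        V = (V - V.mean(axis=0)) / sd
    tree = linkage(pdist(V, metric=distance_metric), method=linkage_method)
    raw = cut_tree(tree, n_clusters=k).ravel()
    return SubtypeAssignment(
        labels=_relabel_by_size(ecv.sample_ids, raw, k),
        merge_tree=tree,
        k=k,
        linkage_method=linkage_method,
        distance_metric=distance_metric,
        scaled_columns=scale_columns,
        sample_order=list(ecv.sample_ids),
    )


def adjusted_rand_index(a: Mapping[str, object], b: Mapping[str, object]) -> float:
    """ARI over the shared sample ids by the pair-counting contingency formula."""
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("assignments share no samples")
    la = [a[s] for s in shared]
    lb = [b[s] for s in shared]
    cats_a = {c: i for i, c in enumerate(dict.fromkeys(la))}
    cats_b = {c: i for i, c in enumerate(dict.fromkeys(lb))}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for x, y in zip(la, lb):
        table[cats_a[x], cats_b[y]] += 1
    n = table.sum()
    comb = lambda v: v * (v - 1) // 2
    sum_cells = int(sum(comb(v) for v in table.ravel()))
    sum_rows = int(sum(comb(v) for v in table.sum(axis=1)))
    sum_cols = int(sum(comb(v) for v in table.sum(axis=0)))
    total = comb(int(n))
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 0.0 if sum_cells != max_index else 1.0
    return (sum_cells - expected) / (max_index - expected)


def compare_assignments(
    a: Mapping[str, object], b: Mapping[str, object]
) -> tuple[pd.DataFrame, float]:
    """Contingency table over shared samples plus the adjusted Rand index."""
    a = a.labels if isinstance(a, SubtypeAssignment) else a
    b = b.labels if isinstance(b, SubtypeAssignment) else b
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("assignments share no samples")
    df = pd.DataFrame({"a": [a[s] for s in shared], "b": [b[s] for s in shared]})
    table = pd.crosstab(df["a"], df["b"])
    return table, adjusted_rand_index(a, b)


def rank_genes_by_variance(values: np.ndarray, gene_ids: Sequence[str]) -> list[str]:
    """Gene ids by descending cross-sample variance (expression-only baseline)."""
    variances = np.asarray(values, dtype=float).var(axis=1, ddof=1)
    order = sorted(range(len(gene_ids)), key=lambda i: (-variances[i], gene_ids[i]))
    return [gene_ids[i] for i in order]


def silhouette_scan(ecv: ECvMatrix, ks: Sequence[int] = (2, 3, 4, 5, 6), **kwargs) -> pd.DataFrame:
    """Mean silhouette width for a range of k — guidance only, not a selection rule."""
    from scipy.spatial.distance import squareform

    rows = []
    D = squareform(pdist(ecv.values, metric=kwargs.get("distance_metric", "euclidean")))
    for k in ks:
        if not 2 <= k < len(ecv.sample_ids):
            continue
        assign = cluster_patients(ecv, k=k, **kwargs)
        labels = np.array([assign.labels[s] for s in ecv.sample_ids])
        sil = _mean_silhouette(D, labels)
        rows.append({"k": k, "mean_silhouette": sil})
    return pd.DataFrame(rows)


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    vals = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        a = D[i, same].mean() if same.any() else 0.0
        bs = [D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]]
        b = min(bs) if bs else 0.0
        denom = max(a, b)
        vals[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(vals.mean())


def linkage_to_newick(tree: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (heights as branch lengths)."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return leaf_names[node]
        left, right, height, _ = tree[node - n]
        parts = []
        for child in (int(left), int(right)):
            blen = height - heights[child]
            parts.append(f"{render(child)}:{max(blen, 0.0):.10g}")
        heights[node] = height
        return "(" + ",".join(parts) + ")"

    for idx in range(tree.shape[0]):
        heights[n + idx] = tree[idx, 2]
    return render(2 * n - 2) + ";"
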