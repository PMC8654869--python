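"""Structure search over DAGs by penalized-score hill climbing.

The total network score decomposes as the sum of per-family local scores
(plus a structure log-prior, uniform by default), so moves are evaluated by
re-scoring only the touched families.  Greedy best-improvement search over
{add, delete, reverse} with random restarts stands in for large-scale
samplers; :func:`exhaustive_search` provides the global optimum on <= 5
nodes as a correctness oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from pathlib import Path
from typing import Sequence

import numpy as np

from .bspline import LocalModel, ScoreConfig, SplineBasis, build_basis, fit_local_model
from .core_io import ExpressionMatrix, NetworkStructure

__all__ = [
    "SearchConfig",
    "FittedNetwork",
    "estimate_network",
    "exhaustive_search",
    "score_network",
    "save_network",
    "load_network",
]


@dataclass
class SearchConfig:
    max_parents: int = 3
    restarts: int = 5
    seed: int = 0
    candidate_parents: int | None = None  # per-child cap by |correlation|; None = all
    debug_check_acyclic: bool = False

    def __post_init__(self) -> None:
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class FittedNetwork:
    structure: NetworkStructure
    models: dict[str, LocalModel]
    total_score: float
    sample_ids: list[str]
    score_config: ScoreConfig

    def __post_init__(self) -> None:
        missing = set(self.structure.nodes) - set(self.models)
        if missing:
            raise ValueError(f"nodes without a local model: {sorted(missing)}")

    def model(self, gene: str) -> LocalModel:
        return self.models[gene]


class _Scorer:
    """Caches per-gene spline bases and per-family local fits for one dataset."""

    def __init__(self, X: ExpressionMatrix, config: ScoreConfig):
        self.X = X
        self.config = config
        self._basis_cache: dict[str, SplineBasis] = {}
        self._fit_cache: dict[tuple[str, frozenset[str]], LocalModel] = {}

    def basis(self, gene: str) -> SplineBasis:
        if gene not in self._basis_cache:
            self._basis_cache[gene] = build_basis(
                self.X.gene(gene), self.config.n_basis, self.config.degree
            )
        return self._basis_cache[gene]

    def fit(self, child: str, parents: Sequence[str]) -> LocalModel:
        key = (child, frozenset(parents))
        if key not in self._fit_cache:
            parent_list = sorted(parents)  # canonical order: cache-friendly, order-free score
            P = (
                np.column_stack([self.X.gene(p) for p in parent_list])
                if parent_list
                else None
            )
            model = fit_local_model(
                self.X.gene(child),
                P,
                self.config,
                child=child,
                parent_ids=parent_list,
                bases=[self.basis(p) for p in parent_list] if parent_list else None,
            )
            if not math.isfinite(model.score):
                raise ValueError(f"non-finite local score for family of {child!r}")
            self._fit_cache[key] = model
        return self._fit_cache[key]

    def score(self, child: str, parents: Sequence[str]) -> float:
        return self.fit(child, parents).score


def _log_structure_prior(n_edges: int, config: ScoreConfig) -> float:
    return -config.edge_penalty * n_edges


class _Graph:
    """Mutable parent-set representation used during search."""

    def __init__(self, nodes: Sequence[str]):
        self.nodes = list(nodes)
        self.parents: dict[str, set[str]] = {n: set() for n in nodes}

    def copy(self) -> "_Graph":
        g = _Graph(self.nodes)
        g.parents = {n: set(ps) for n, ps in self.parents.items()}
        return g

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c, ps in self.parents.items() for p in ps)

    def creates_cycle(self, parent: str, child: str) -> bool:
        """Would adding parent->child create a cycle (path child ~> parent)?"""
        stack, seen = [child], {child}
        children = {n: [] for n in self.nodes}
        for c, ps in self.parents.items():
            for p in ps:
                children[p].append(c)
        while stack:
            n = stack.pop()
            if n == parent:
                return True
            for c in children[n]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def is_acyclic(self) -> bool:
        from .core_io import find_cycle

        return find_cycle(self.nodes, self.edges()) is None


def _candidate_parent_sets(
    X: ExpressionMatrix, cap: int | None
) -> dict[str, set[str]]:
    genes = X.gene_ids
    if cap is None or cap >= len(genes) - 1:
        return {g: set(genes) - {g} for g in genes}
    V = X.values
    sd = V.std(axis=1)
    sd[sd == 0] = 1.0
    C = np.corrcoef(V)
    allowed: dict[str, set[str]] = {}
    for j, g in enumerate(genes):
        order = np.argsort(-np.abs(C[j]))
        picks = [genes[i] for i in order if i != j][:cap]
        allowed[g] = set(picks)
    return allowed


def _greedy(
    graph: _Graph,
    scorer: _Scorer,
    search: SearchConfig,
    allowed: dict[str, set[str]],
) -> tuple[_Graph, float]:
    nodes = graph.nodes
    local = {n: scorer.score(n, graph.parents[n]) for n in nodes}
    total = sum(local.values()) + _log_structure_prior(len(graph.edges()), scorer.config)

    while True:
        best_delta = 0.0
        best_move: tuple[int, str, str] | None = None  # (type, parent, child)
        for child in nodes:
            ps = graph.parents[child]
            # add
            for parent in nodes:
                if parent == child or parent in ps or parent not in allowed[child]:
                    continue
                if len(ps) >= search.max_parents or graph.creates_cycle(parent, child):
                    continue
                delta = (
                    scorer.score(child, ps | {parent})
                    - local[child]
                    - scorer.config.edge_penalty
                )
                move = (0, parent, child)
                if delta > best_delta + 1e-12 or (
                    abs(delta - best_delta) <= 1e-12
                    and best_move is not None
                    and delta > 0
                    and move < best_move
                ):
                    best_delta, best_move = delta, move
            # delete
            for parent in sorted(ps):
                delta = (
                    scorer.score(child, ps - {parent})
                    - local[child]
                    + scorer.config.edge_penalty
                )
                move = (1, parent, child)
                if delta > best_delta + 1e-12 or (
                    abs(delta - best_delta) <= 1e-12
                    and best_move is not None
                    and delta > 0
                    and move < best_move
                ):
                    best_delta, best_move = delta, move
            # reverse parent->child  =>  child->parent
            for parent in sorted(ps):
                if len(graph.parents[parent]) >= search.max_parents:
                    continue
                if child not in allowed[parent]:
                    continue
                trial = graph.copy()
                trial.parents[child].discard(parent)
                if trial.creates_cycle(child, parent):
                    continue
                delta = (
                    scorer.score(child, ps - {parent})
                    + scorer.score(parent, graph.parents[parent] | {child})
                    - local[child]
                    - local[parent]
                )
                move = (2, parent, child)
                if delta > best_delta + 1e-12 or (
                    abs(delta - best_delta) <= 1e-12
                    and best_move is not None
                    and delta > 0
                    and move < best_move
                ):
                    best_delta, best_move = delta, move

        if best_move is None or best_delta <= 1e-9:
            return graph, total
        kind, parent, child = best_move
        if kind == 0:
            graph.parents[child].add(parent)
        elif kind == 1:
            graph.parents[child].discard(parent)
        else:
            graph.parents[child].discard(parent)
            graph.parents[parent].add(child)
        if search.debug_check_acyclic and not graph.is_acyclic():
            raise AssertionError(f"move {best_move} broke acyclicity")
        for n in {child, parent}:
            local[n] = scorer.score(n, graph.parents[n])
        new_total = sum(local.values()) + _log_structure_prior(
            len(graph.edges()), scorer.config
        )
        if new_total <= total - 1e-9:
            raise AssertionError(
                f"greedy decrease: move={best_move} pred={best_delta} actual={new_total - total}"
            )
        total = new_total


def _random_dag(
    nodes: Sequence[str], rng: np.random.Generator, max_parents: int, allowed: dict[str, set[str]]
) -> _Graph:
    g = _Graph(nodes)
    order = list(rng.permutation(list(nodes)))
    for i, child in enumerate(order):
        if i == 0 or max_parents == 0:
            continue
        preds = [p for p in order[:i] if p in allowed[child]]
        if not preds:
            continue
        q = int(rng.integers(0, min(len(preds), max_parents) + 1))
        if q:
            g.parents[child] = set(rng.choice(preds, size=q, replace=False).tolist())
    return g


def _finalize(
    graph: _Graph, scorer: _Scorer, X: ExpressionMatrix
) -> FittedNetwork:
    structure = NetworkStructure(X.gene_ids, graph.edges())
    models = {n: scorer.fit(n, graph.parents[n]) for n in graph.nodes}
    total = sum(m.score for m in models.values()) + _log_structure_prior(
        structure.n_edges, scorer.config
    )
    return FittedNetwork(structure, models, total, list(X.sample_ids), scorer.config)


def estimate_network(
    X: ExpressionMatrix,
    score_config: ScoreConfig | None = None,
    search_config: SearchConfig | None = None,
) -> FittedNetwork:
    """Best-scoring DAG over greedy hill-climbing restarts (deterministic per seed).

    Restart 0 starts from the empty graph; later restarts start from random
    DAGs drawn with the configured seed.
    """
    if X.n_genes == 0:
        raise ValueError("expression matrix has no genes")
    score_config = score_config or ScoreConfig()
    search_config = search_config or SearchConfig()
    scorer = _Scorer(X, score_config)
    allowed = _candidate_parent_sets(X, search_config.candidate_parents)
    rng = np.random.default_rng(search_config.seed)

    best: tuple[float, int, list[tuple[str, str]], _Graph] | None = None
    for r in range(search_config.restarts):
        start = (
            _Graph(X.gene_ids)
            if r == 0
            else _random_dag(X.gene_ids, rng, search_config.max_parents, allowed)
        )
        graph, total = _greedy(start, scorer, search_config, allowed)
        edges = graph.edges()
        if best is None or _better((total, -len(edges), edges), best[:3]):
            best = (total, -len(edges), edges, graph)
    assert best is not None
    return _finalize(best[3], scorer, X)


def exhaustive_search(
    X: ExpressionMatrix,
    score_config: ScoreConfig | None = None,
    max_parents: int | None = None,
    count_sink: dict | None = None,
) -> FittedNetwork:
    """Global score optimum by enumerating all DAGs on p <= 5 labelled nodes.

    Enumerates topological orders x predecessor subsets and deduplicates
    structures; ``count_sink['n_dags']`` receives the number of distinct DAGs
    visited.  Ties break toward fewer edges, then the lexicographically
    smallest edge list.
    """
    p = X.n_genes
    if p > 5:
        raise ValueError("exhaustive search is limited to p <= 5 genes")
    if p == 0:
        raise ValueError("expression matrix has no genes")
    score_config = score_config or ScoreConfig()
    scorer = _Scorer(X, score_config)
    genes = X.gene_ids
    cap = max_parents if max_parents is not None else p - 1

    seen: set[frozenset[tuple[str, str]]] = set()
    best: tuple[float, int, list[tuple[str, str]]] | None = None
    for order in permutations(genes):
        parent_choices: list[list[tuple[str, ...]]] = []
        for i, child in enumerate(order):
            preds = order[:i]
            choices = [
                c
                for size in range(0, min(len(preds), cap) + 1)
                for c in combinations(preds, size)
            ]
            parent_choices.append(choices)

        def rec(i: int, acc: list[tuple[str, ...]]):
            nonlocal best
            if i == len(order):
                edges = frozenset(
                    (p_, order[j]) for j, ps in enumerate(acc) for p_ in ps
                )
                if edges in seen:
                    return
                seen.add(edges)
                total = sum(
                    scorer.score(order[j], acc[j]) for j in range(len(order))
                ) + _log_structure_prior(len(edges), score_config)
                edge_list = sorted(edges)
                cand = (total, -len(edges), edge_list)
                if best is None or _better(cand, best):
                    best = cand
                return
            for choice in parent_choices[i]:
                rec(i + 1, acc + [choice])

        rec(0, [])
    assert best is not None
    if count_sink is not None:
        count_sink["n_dags"] = len(seen)
    graph = _Graph(genes)
    for parent, child in best[2]:
        graph.parents[child].add(parent)
    return _finalize(graph, scorer, X)


def _better(
    a: tuple[float, int, list[tuple[str, str]]],
    b: tuple[float, int, list[tuple[str, str]]],
) -> bool:
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] > b[1]  # fewer edges wins (stored negated)
    return a[2] < b[2]


def score_network(
    X: ExpressionMatrix,
    structure: NetworkStructure,
    score_config: ScoreConfig | None = None,
) -> FittedNetwork:
    """Fit every family of a given structure independently and total the score."""
    score_config = score_config or ScoreConfig()
    scorer = _Scorer(X, score_config)
    missing = set(structure.nodes) - set(X.gene_ids)
    if missing:
        raise ValueError(f"structure references genes absent from X: {sorted(missing)}")
    graph = _Graph(X.gene_ids)
    for parent, child in structure.edges:
        graph.parents[child].add(parent)
    return _finalize(graph, scorer, X)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_network(network: FittedNetwork, path: str | Path) -> None:
    """Serialize a fitted network (structure + all local models) to JSON."""
    doc = {
        "format": "ecvnet-fitted-network",
        "version": 1,
        "nodes": network.structure.nodes,
        "edges": [list(e) for e in network.structure.edges],
        "total_score": network.total_score,
        "sample_ids": network.sample_ids,
        "score_config": {
            "n_basis": network.score_config.n_basis,
            "degree": network.score_config.degree,
            "lambda_grid": list(map(float, network.score_config.lambda_grid)),
            "edge_penalty": network.score_config.edge_penalty,
        },
        "models": {g: m.to_dict() for g, m in network.models.items()},
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_network(path: str | Path) -> FittedNetwork:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "ecvnet-fitted-network":
        raise ValueError(f"{path}: not a fitted-network file")
    structure = NetworkStructure(doc["nodes"], [tuple(e) for e in doc["edges"]])
    models = {g: LocalModel.from_dict(d) for g, d in doc["models"].items()}
    cfg = ScoreConfig(
        n_basis=doc["score_config"]["n_basis"],
        degree=doc["score_config"]["degree"],
        lambda_grid=tuple(doc["score_config"]["lambda_grid"]),
        edge_penalty=doc["score_config"]["edge_penalty"],
    )
    return FittedNetwork(
        structure, models, float(doc["total_score"]), list(doc["sample_ids"]), cfg
    )
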