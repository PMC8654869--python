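"""Additive B-spline regression of one gene on its parents, with a
Laplace-approximated marginal-likelihood score.

Model: ``child = mu + sum_k m_k(parent_k) + eps``, ``eps ~ N(0, sigma2)``,
where each smooth ``m_k`` is a cubic B-spline expansion penalized by its
squared second differences (weight ``lambda_k``).  Each ``m_k`` is
constrained to zero mean over the training samples, so the intercept ``mu``
equals the training mean of the child and the additive decomposition is
identifiable; differences of edge contributions are invariant to this
normalization.

The local score is the log marginal likelihood under a partially improper
Gaussian smoothness prior on the spline coefficients, integrated by Laplace
approximation.  It is decomposable (depends only on the child and its
parents), deterministic, and penalizes dimension like BIC for large n, which
is what the structure search needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, cho_factor, cho_solve, null_space

__all__ = [
    "SplineBasis",
    "LocalModel",
    "ScoreConfig",
    "build_basis",
    "fit_local_model",
    "predict",
    "local_score",
]

_SIGMA2_FLOOR = 1e-12


@dataclass
class ScoreConfig:
    """Knobs for the local fit and score.

    ``lambda_grid`` is swept once with a shared value for all parents, then
    refined one parent at a time (a single coordinate pass); both steps are
    deterministic.  ``edge_penalty`` is an optional per-edge log-prior cost
    on the structure (uniform prior when 0).
    """

    n_basis: int = 10
    degree: int = 3
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-3.0, 3.0, 10))
    edge_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.n_basis < self.degree + 1:
            raise ValueError("n_basis must be at least degree + 1")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid values must be > 0")


@dataclass
class SplineBasis:
    """Open (clamped) B-spline basis on the training range of one covariate."""

    degree: int
    knots: np.ndarray
    n_basis: int
    lo: float
    hi: float

    def clamp(self, x: np.ndarray | float) -> np.ndarray:
        return np.clip(np.asarray(x, dtype=float), self.lo, self.hi)

    def design(self, x: np.ndarray | float) -> np.ndarray:
        """Dense (n, n_basis) design matrix; out-of-range x is clamped."""
        xc = np.atleast_1d(self.clamp(x))
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()


def build_basis(x: np.ndarray, n_basis: int = 10, degree: int = 3) -> SplineBasis:
    """B-spline basis with interior knots at equally spaced quantiles of x.

    Boundary knots sit at min(x)/max(x), each replicated degree+1 times, so
    the basis is a partition of unity on [min, max]; evaluation outside that
    range clamps to the boundary (constant extension).
    """
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if distinct.size < degree + 2:
        raise ValueError(
            f"covariate has only {distinct.size} distinct values; need at least "
            f"{degree + 2} — use fewer basis functions or a lower degree"
        )
    lo, hi = float(distinct[0]), float(distinct[-1])
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.empty(0)
    knots = np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])
    if np.any(np.diff(knots) < 0):  # quantiles are monotone; guard anyway
        knots = np.sort(knots)
    return SplineBasis(degree=degree, knots=knots, n_basis=n_basis, lo=lo, hi=hi)


@dataclass
class LocalModel:
    """Fitted additive model for one child gene."""

    child: str
    parents: list[str]
    mu: float
    bases: list[SplineBasis]
    coefficients: list[np.ndarray]  # gamma_k in the raw basis, length n_basis each
    sigma2: float
    lambdas: list[float]
    score: float
    n_train: int = 0

    def component(self, k: int, x: np.ndarray | float) -> np.ndarray:
        """Evaluate the k-th smooth m_k at covariate values (clamped)."""
        return self.bases[k].design(x) @ self.coefficients[k]

    def to_dict(self) -> dict:
        return {
            "child": self.child,
            "parents": list(self.parents),
            "mu": self.mu,
            "sigma2": self.sigma2,
            "lambdas": list(map(float, self.lambdas)),
            "score": self.score,
            "n_train": self.n_train,
            "smooths": [
                {
                    "degree": b.degree,
                    "knots": [float(v) for v in b.knots],
                    "n_basis": b.n_basis,
                    "lo": b.lo,
                    "hi": b.hi,
                    "coefficients": [float(v) for v in g],
                }
                for b, g in zip(self.bases, self.coefficients)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocalModel":
        bases = [
            SplineBasis(
                degree=s["degree"],
                knots=np.asarray(s["knots"], dtype=float),
                n_basis=s["n_basis"],
                lo=s["lo"],
                hi=s["hi"],
            )
            for s in d["smooths"]
        ]
        coeffs = [np.asarray(s["coefficients"], dtype=float) for s in d["smooths"]]
        return cls(
            child=d["child"],
            parents=list(d["parents"]),
            mu=float(d["mu"]),
            bases=bases,
            coefficients=coeffs,
            sigma2=float(d["sigma2"]),
            lambdas=[float(v) for v in d["lambdas"]],
            score=float(d["score"]),
            n_train=int(d.get("n_train", 0)),
        )


def _second_difference_penalty(n_basis: int) -> np.ndarray:
    d2 = np.diff(np.eye(n_basis), n=2, axis=0)
    return d2.T @ d2


class _FamilyDesign:
    """Precomputed quantities for one (child, parent set) fit, reused across
    the lambda sweep."""

    def __init__(self, y: np.ndarray, blocks: list[np.ndarray], penalties: list[np.ndarray]):
        self.n = y.shape[0]
        self.blocks = blocks
        self.dims = [b.shape[1] for b in blocks]
        X = np.hstack([np.ones((self.n, 1))] + blocks) if blocks else np.ones((self.n, 1))
        self.X = X
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        self.penalties = penalties  # reduced-space K_k, one per parent
        self.ranks = [int(np.linalg.matrix_rank(K)) for K in penalties]

    def penalty_matrix(self, lambdas: Sequence[float]) -> np.ndarray:
        d = self.xtx.shape[0]
        P = np.zeros((d, d))
        off = 1
        for lam, K, dk in zip(lambdas, self.penalties, self.dims):
            P[off : off + dk, off : off + dk] = lam * K
            off += dk
        return P

    def solve(self, lambdas: Sequence[float]) -> tuple[np.ndarray, float, float]:
        """Penalized LS solve; returns (beta, rss, score) for this lambda vector."""
        P = self.penalty_matrix(lambdas)
        A = self.xtx + P
        try:
            cf = cho_factor(A, lower=True)
        except LinAlgError:
            raise ValueError(
                "singular penalized normal equations; reduce the number of basis functions"
            ) from None
        beta = cho_solve(cf, self.xty)
        rss = self.yty - 2.0 * float(beta @ self.xty) + float(beta @ (self.xtx @ beta))
        rss = max(rss, 0.0)
        sigma2 = max(rss / self.n, _SIGMA2_FLOOR)
        score = self._laplace_score(beta, sigma2, lambdas, P)
        return beta, rss, score

    def _laplace_score(
        self, beta: np.ndarray, sigma2: float, lambdas: Sequence[float], P: np.ndarray
    ) -> float:
        n, d = self.n, self.xtx.shape[0]
        ll = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * n
        pen = float(beta @ (P @ beta))
        logprior = -0.5 * pen
        for lam, r in zip(lambdas, self.ranks):
            logprior += 0.5 * r * (math.log(lam) - math.log(2.0 * math.pi))
        H = self.xtx / sigma2 + P
        # eigenvalue clip keeps the logdet finite under near-collinear designs
        eig = np.linalg.eigvalsh(H)
        floor = max(eig[-1], 1.0) * 1e-12
        logdet = float(np.sum(np.log(np.maximum(eig, floor))))
        if not math.isfinite(logdet):
            raise ValueError(
                "non-finite Laplace Hessian determinant; reduce the number of basis functions"
            )
        return ll + logprior + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet


def _constraint_nullspace(block: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the zero-training-mean constraint for one smooth."""
    cbar = block.mean(axis=0, keepdims=True)
    Z = null_space(cbar)
    if Z.shape[1] != block.shape[1] - 1:
        raise ValueError("degenerate basis block; reduce the number of basis functions")
    return Z


def fit_local_model(
    y: np.ndarray,
    parents: np.ndarray | None,
    config: ScoreConfig | None = None,
    *,
    child: str = "",
    parent_ids: Sequence[str] | None = None,
    bases: Sequence[SplineBasis] | None = None,
    lambdas: Sequence[float] | None = None,
) -> LocalModel:
    """Fit the penalized additive model for one child gene.

    ``parents`` is an (n, q) matrix of parent expression values (or None/empty
    for an orphan gene).  ``bases`` may carry pre-built per-parent bases (the
    network search caches them per gene); otherwise they are built here from
    the training covariates.
    """
    config = config or ScoreConfig()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if parents is None:
        parents = np.empty((n, 0))
    parents = np.asarray(parents, dtype=float)
    if parents.ndim == 1:
        parents = parents[:, None]
    q = parents.shape[1]
    if parents.shape[0] != n:
        raise ValueError("parent matrix and child vector disagree on sample count")
    parent_ids = list(parent_ids) if parent_ids is not None else [f"parent{k}" for k in range(q)]
    if len(parent_ids) != q:
        raise ValueError("parent_ids length must match the number of parent columns")

    if q == 0:
        mu = float(y.mean())
        rss = float(np.sum((y - mu) ** 2))
        sigma2 = max(rss / n, _SIGMA2_FLOOR)
        score = (
            -0.5 * n * math.log(2.0 * math.pi * sigma2)
            - 0.5 * n
            + 0.5 * math.log(2.0 * math.pi)
            - 0.5 * math.log(n / sigma2)
        )
        return LocalModel(child, [], mu, [], [], sigma2, [], score, n_train=n)

    if bases is None:
        bases = [build_basis(parents[:, k], config.n_basis, config.degree) for k in range(q)]
    else:
        bases = list(bases)
        if len(bases) != q:
            raise ValueError("bases length must match the number of parents")

    raw_blocks = [bases[k].design(parents[:, k]) for k in range(q)]
    Zs = [_constraint_nullspace(b) for b in raw_blocks]
    blocks = [raw_blocks[k] @ Zs[k] for k in range(q)]
    penalties = [
        Zs[k].T @ _second_difference_penalty(bases[k].n_basis) @ Zs[k] for k in range(q)
    ]
    total_dim = 1 + sum(b.shape[1] for b in blocks)
    if n <= total_dim:
        raise ValueError(
            f"need more than {total_dim} samples to fit {q} parents with "
            f"{config.n_basis} basis functions; got n={n}"
        )
    design = _FamilyDesign(y, blocks, penalties)

    if lambdas is not None:
        if len(lambdas) != q:
            raise ValueError("lambdas must have one entry per parent")
        best_lam = [float(v) for v in lambdas]
        best = design.solve(best_lam)
    else:
        # shared sweep, then one per-parent coordinate refinement pass
        best_lam = None
        best = None
        for lam in config.lambda_grid:
            lams = [float(lam)] * q
            cand = design.solve(lams)
            if best is None or cand[2] > best[2]:
                best, best_lam = cand, lams
        assert best is not None and best_lam is not None
        for k in range(q):
            for lam in config.lambda_grid:
                lams = list(best_lam)
                lams[k] = float(lam)
                cand = design.solve(lams)
                if cand[2] > best[2]:
                    best, best_lam = cand, lams

    beta, rss, score = best
    mu = float(beta[0])
    coeffs = []
    off = 1
    for k in range(q):
        dk = blocks[k].shape[1]
        coeffs.append(Zs[k] @ beta[off : off + dk])
        off += dk
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    return LocalModel(
        child=child,
        parents=parent_ids,
        mu=mu,
        bases=bases,
        coefficients=coeffs,
        sigma2=sigma2,
        lambdas=[float(v) for v in best_lam],
        score=score,
        n_train=n,
    )


def predict(model: LocalModel, parent_values: Sequence[float] | np.ndarray) -> float:
    """Fitted value mu + sum_k m_k(x_k) for one sample (covariates clamped)."""
    parent_values = np.atleast_1d(np.asarray(parent_values, dtype=float))
    if parent_values.shape[0] != len(model.parents):
        raise ValueError(
            f"model for {model.child!r} expects {len(model.parents)} parent values, "
            f"got {parent_values.shape[0]}"
        )
    total = model.mu
    for k in range(len(model.parents)):
        total += float(model.component(k, parent_values[k])[0])
    return total


def local_score(
    y: np.ndarray,
    parents: np.ndarray | None,
    config: ScoreConfig | None = None,
    **kwargs,
) -> float:
    """Decomposable local score of one family (larger is better)."""
    return fit_local_model(y, parents, config, **kwargs).score
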