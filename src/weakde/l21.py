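"""ℓ2,1-regularized multi-class feature ranking with Laplacian smoothing.

The objective minimized over coefficients ``W`` (n_genes × c) and intercept
``b`` (length c) is

    J(W, b) = Σ_i ‖Wᵀx_i + b − y_i‖²
            + (λ/2) Σ_{i,j} ‖Wᵀx_i − Wᵀx_j‖² S_ij
            + γ ‖W‖_{2,1}

where ``x_i`` are sample columns, ``y_i`` indicator target columns, ``S``
a heat-kernel affinity zeroed across classes, and ``‖W‖_{2,1}`` the sum of
row Euclidean norms.  The first term fits class indicators globally, the
second (equal to λ·tr(Wᵀ X L Xᵀ W) with Laplacian L = D − S) keeps
projections of similar same-class samples close, and the ℓ2,1 penalty
drives whole rows of W — uninformative genes — to zero.  Genes are ranked
by descending row norm ‖wᵏ‖.

The solver is iteratively reweighted least squares: the penalty is
majorized by the quadratic γ·tr(Wᵀ D_w W) with D_w = diag(1/(2 max(‖wᵏ‖, ε)))
and each iteration solves the resulting normal equations exactly, with the
intercept eliminated by centering (its exact minimizer given W).  Each step
minimizes a majorizing surrogate, so the objective is nonincreasing.  When
genes far outnumber samples the solve is carried out in the m-dimensional
sample space via the Woodbury identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "L21Params",
    "RankingModel",
    "build_similarity",
    "make_targets",
    "l21_objective",
    "fit_l21",
    "rank_genes",
]


@dataclass
class L21Params:
    """Hyperparameters of the ℓ2,1 ranking objective and its solver.

    ``lam`` weights the Laplacian (local-structure) term, ``gamma`` the
    ℓ2,1 penalty (``None`` → the number of training samples m: the fit
    term is a sum of m squared residuals, so a fixed γ degenerates to
    vanishing regularization as m grows); ``t`` is the heat-kernel
    bandwidth (``None`` → median pairwise training distance); ``eps``
    smooths the row-norm reweighting; iteration stops when the relative
    objective decrease falls below ``tol`` or after ``max_iter`` sweeps.
    """

    lam: float = 1.0
    gamma: float | None = None
    t: float | None = None
    eps: float = 1e-10
    max_iter: int = 30
    tol: float = 1e-6
    solver: str = "auto"   # "auto" | "direct" (n×n) | "dual" (m×m Woodbury)

    def __post_init__(self) -> None:
        if self.solver not in {"auto", "direct", "dual"}:
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.lam < 0 or (self.gamma is not None and self.gamma < 0):
            raise ValueError("lam and gamma must be nonnegative")
        if self.t is not None and self.t <= 0:
            raise ValueError("heat-kernel bandwidth t must be positive")
        if self.eps <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("eps, tol must be positive; max_iter >= 1")


@dataclass
class RankingModel:
    """Fitted coefficients with the per-iteration objective trace."""

    w: np.ndarray                      # (n_genes, c)
    b: np.ndarray                      # (c,)
    objective_trace: list[float] = field(default_factory=list)

    @property
    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.w, axis=1)


def median_pairwise_distance(x: np.ndarray) -> float:
    """Median Euclidean distance between distinct sample columns of ``x``."""
    d2 = _sq_dists(x)
    iu = np.triu_indices(d2.shape[0], k=1)
    med = float(np.sqrt(np.median(d2[iu]))) if iu[0].size else 1.0
    return med if med > 0 else 1.0


def _sq_dists(x: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->j", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x.T @ x)
    np.maximum(d2, 0.0, out=d2)
    return d2


def build_similarity(x: np.ndarray, labels: np.ndarray, t: float) -> np.ndarray:
    """Heat-kernel affinity between same-class sample columns.

    ``s_ij = exp(−‖x_i − x_j‖² / t²)`` when samples i and j share a class
    label, 0 otherwise.
    """
    if t <= 0:
        raise ValueError(f"heat-kernel bandwidth t must be positive, got {t}")
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[1]:
        raise ValueError("one label per sample column required")
    s = np.exp(-_sq_dists(x) / (t * t))
    s[labels[:, None] != labels[None, :]] = 0.0
    return (s + s.T) / 2.0  # exact symmetry against roundoff


def make_targets(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Indicator target matrix Y (c × m): y_{j,i} = 1 iff sample i is in
    class j.  Returns (Y, class order)."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    y = np.zeros((len(classes), labels.shape[0]))
    for j, cls in enumerate(classes):
        y[j, labels == cls] = 1.0
    return y, classes


def l21_objective(
    w: np.ndarray,
    b: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    lam: float,
    gamma: float,
) -> float:
    """Evaluate the ranking objective at (w, b); see module docstring."""
    n, m = x.shape
    if w.shape[0] != n or y.shape[1] != m or s.shape != (m, m):
        raise ValueError("dimension mismatch between w, x, y, s")
    proj = w.T @ x                                   # (c, m)
    resid = proj + b[:, None] - y
    fit = float(np.einsum("ij,ij->", resid, resid))
    deg = s.sum(axis=1)
    lap = float(np.einsum("ij,ij->", proj * deg[None, :], proj)
                - np.einsum("ci,ij,cj->", proj, s, proj))
    penalty = float(np.linalg.norm(w, axis=1).sum())
    return fit + lam * lap + gamma * penalty


def fit_l21(
    x: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    params: L21Params | None = None,
) -> RankingModel:
    """Minimize the ℓ2,1 ranking objective by IRLS.

    Parameters
    ----------
    x
        Training samples, genes × samples.
    y
        Indicator targets, classes × samples.
    s
        Same-class heat-kernel affinity (samples × samples).
    """
    params = params or L21Params()
    n, m = x.shape
    c = y.shape[0]
    if y.shape[1] != m or s.shape != (m, m):
        raise ValueError("dimension mismatch between x, y, s")
    if params.gamma is None:
        params = replace(params, gamma=float(m))
    if (y.sum(axis=1) < 2).any():
        warnings.warn("a class has fewer than 2 training samples", stacklevel=2)

    # M = H + lam*L folds the centered fit term and the Laplacian together:
    # the normal equations read (X M Xᵀ + γ D_w) W = X H Yᵀ.
    h = np.eye(m) - np.full((m, m), 1.0 / m)
    lap = np.diag(s.sum(axis=1)) - s
    mmat = h + params.lam * lap
    r = h @ y.T                                      # (m, c)

    d_inv = np.full(n, 1.0)                          # 1/d_k; first sweep ridge-like
    w = np.zeros((n, c))
    trace: list[float] = []
    # Woodbury path solves the same normal equations in sample space
    use_dual = params.solver == "dual" or (params.solver == "auto" and n > m)

    for _ in range(params.max_iter):
        if use_dual:
            px = d_inv[:, None] * x / params.gamma if params.gamma > 0 else None
            if px is None:
                use_dual = False
            else:
                xtpx = x.T @ px                      # (m, m)
                v = np.linalg.solve(np.eye(m) + xtpx @ mmat, xtpx @ r)
                w = px @ (r - mmat @ v)
        if not use_dual:
            a = x @ mmat @ x.T
            if params.gamma > 0:
                a = a + params.gamma * np.diag(1.0 / d_inv)
            else:
                a = a + params.eps * np.eye(n)
            try:
                w = np.linalg.solve(a, x @ r)
            except np.linalg.LinAlgError:
                warnings.warn("singular normal equations; adding eps ridge",
                              stacklevel=2)
                w = np.linalg.solve(a + params.eps * np.eye(n), x @ r)
        b = (y - w.T @ x).mean(axis=1)
        obj = l21_objective(w, b, x, y, s, params.lam, params.gamma)
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite objective during IRLS")
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(prev - obj) <= params.tol * max(1.0, abs(prev)):
                break
        d_inv = 2.0 * np.maximum(np.linalg.norm(w, axis=1), params.eps)

    return RankingModel(w=w, b=b, objective_trace=trace)


def rank_genes(model: RankingModel) -> np.ndarray:
    """Gene indices sorted by descending row norm ‖wᵏ‖; ties broken by
    ascending original index (stable, deterministic)."""
    return np.argsort(-model.row_norms, kind="stable")
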