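"""SVM and transductive SVM over precomputed Gram matrices.

These routines never touch raw expression: they consume Gram matrices, so
the difference kernel, a linear kernel, or an rbf kernel are interchanged
purely by configuration.  The soft-margin dual QP is solved by libsvm
(through scikit-learn's ``SVC`` with a precomputed kernel, with per-point
box constraints realized via sample weights); transduction follows the
classical label-switching scheme: label the unlabeled points from an
inductive SVM so a fixed fraction is positive, then alternate retraining
with pairwise label swaps of misclassified +/− unlabeled pairs while the
unlabeled box constraint C* is ramped up geometrically.  Swapping a pair
keeps the positive count fixed, so the transduced positive fraction is
enforced by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SVMModel",
    "TSVMModel",
    "TSVMParams",
    "fit_svm",
    "decision_values",
    "fit_tsvm",
    "predict_disease_genes",
    "linear_gram",
    "rbf_gram",
    "check_kkt",
]


@dataclass
class SVMModel:
    """Soft-margin SVM in dual form over a precomputed kernel."""

    alpha: np.ndarray          # nonnegative dual coefficients, one per point
    y: np.ndarray              # ±1 training labels
    bias: float
    c_labeled: float
    sample_weight: np.ndarray | None = None

    @property
    def support_idx(self) -> np.ndarray:
        return np.flatnonzero(self.alpha > 1e-12)


@dataclass
class TSVMParams:
    """Transduction settings: labeled box constraint ``c``, initial and
    final unlabeled constraints (C* ramps geometrically from
    ``c_star_init_frac·c`` up to ``c_star_max``, defaulting to ``c``), the
    positive fraction enforced on the unlabeled set (``None`` → labeled
    positive fraction), and an outer-iteration guard."""

    c: float = 1.0
    c_star_init_frac: float = 1e-5
    c_star_max: float | None = None
    pos_fraction: float | None = None
    max_outer: int = 200

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.pos_fraction is not None and not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must lie in (0, 1)")


@dataclass
class TSVMModel:
    """Transductive fit: the final SVM over labeled ∪ unlabeled points plus
    the transduced ±1 labels and their decision values."""

    base: SVMModel
    transduced_labels: np.ndarray        # ±1 per unlabeled point
    decision_unlabeled: np.ndarray
    c_unlabeled_final: float
    n_switches: int
    pos_fraction: float
    converged: bool = True
    labeled_mask: np.ndarray | None = None


def _repair_psd(k: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues; warn when clearly indefinite."""
    k = np.asarray(k, dtype=float)
    if not np.allclose(k, k.T, atol=1e-8):
        raise ValueError("kernel matrix must be symmetric")
    k = (k + k.T) / 2.0
    w = np.linalg.eigvalsh(k)
    if w[0] < -1e-8 * max(1.0, w[-1]):
        warnings.warn(
            f"kernel matrix indefinite (min eigenvalue {w[0]:.3g}); "
            "clipping eigenvalues at zero", stacklevel=3,
        )
        vals, vecs = np.linalg.eigh(k)
        k = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return k


def _solve_svc(
    k: np.ndarray, y: np.ndarray, c: float, sample_weight: np.ndarray | None
) -> SVMModel:
    svc = SVC(kernel="precomputed", C=c, tol=1e-8, shrinking=True, cache_size=256)
    svc.fit(k, y, sample_weight=sample_weight)
    alpha = np.zeros(len(y))
    # dual_coef_ holds alpha_i * y_i for support vectors
    alpha[svc.support_] = np.abs(svc.dual_coef_[0])
    # sklearn orders classes ascending, so decision > 0 ⇔ class +1 for ±1 labels
    bias = float(svc.intercept_[0])
    return SVMModel(alpha=alpha, y=np.asarray(y, float), bias=bias,
                    c_labeled=c, sample_weight=sample_weight)


def fit_svm(
    k: np.ndarray, y: np.ndarray, c: float = 1.0, repair: bool = True
) -> SVMModel:
    """Fit a soft-margin SVM on a precomputed labeled × labeled kernel.

    ``y`` must contain both classes (±1); ``c`` is the box constraint.
    Slightly indefinite kernels are repaired by eigenvalue clipping.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must be ±1 and contain both classes")
    if c <= 0:
        raise ValueError("box constraint c must be positive")
    if k.shape != (len(y), len(y)):
        raise ValueError("kernel must be square, aligned with labels")
    if repair:
        k = _repair_psd(k)
    return _solve_svc(k, y, c, None)


def decision_values(model: SVMModel, k_cross: np.ndarray) -> np.ndarray:
    """f(x) = Σ_i α_i y_i k(x, x_i) + b for each row of ``k_cross``
    (test × training Gram block)."""
    k_cross = np.atleast_2d(k_cross)
    if k_cross.shape[1] != len(model.alpha):
        raise ValueError("k_cross columns must align with training points")
    return k_cross @ (model.alpha * model.y) + model.bias


def fit_tsvm(
    k_full: np.ndarray,
    y_labeled: np.ndarray,
    params: TSVMParams | None = None,
) -> TSVMModel:
    """Transductive SVM by label switching over a precomputed kernel.

    ``k_full`` is the Gram matrix over labeled followed by unlabeled
    points; ``y_labeled`` gives ±1 labels for the leading block.  The
    unlabeled points are assigned labels so that ``pos_fraction`` of them
    are positive, then +/− pairs whose hinge slacks jointly exceed 2 are
    swapped and the model retrained, doubling the unlabeled box constraint
    C* until it reaches its cap.
    """
    params = params or TSVMParams()
    y_labeled = np.asarray(y_labeled, dtype=float)
    n_total = k_full.shape[0]
    n_l = len(y_labeled)
    n_u = n_total - n_l
    if n_u < 0:
        raise ValueError("more labels than kernel rows")
    k_full = _repair_psd(k_full)
    pos_frac = params.pos_fraction
    if pos_frac is None:
        pos_frac = float(np.mean(y_labeled > 0))
        pos_frac = min(max(pos_frac, 1.0 / max(n_u, 1)), 1 - 1.0 / max(n_u, 1)) \
            if n_u > 0 else pos_frac

    base0 = fit_svm(k_full[:n_l, :n_l], y_labeled, params.c, repair=False)
    if n_u == 0:
        return TSVMModel(base=base0, transduced_labels=np.empty(0),
                         decision_unlabeled=np.empty(0),
                         c_unlabeled_final=0.0, n_switches=0,
                         pos_fraction=pos_frac,
                         labeled_mask=np.ones(n_l, bool))

    f_u = decision_values(base0, k_full[n_l:, :n_l])
    num_pos = int(round(pos_frac * n_u))
    num_pos = min(max(num_pos, 0), n_u)
    # ties in decision value broken by point order for determinism
    order = np.lexsort((np.arange(n_u), -f_u))
    y_u = -np.ones(n_u)
    y_u[order[:num_pos]] = 1.0

    c_star_max = params.c_star_max if params.c_star_max is not None else params.c
    c_star = max(params.c_star_init_frac * params.c, 1e-12)
    n_switches = 0
    outer = 0
    converged = True
    model = base0
    y_all = np.concatenate([y_labeled, y_u])
    weights = np.concatenate([np.full(n_l, params.c), np.full(n_u, c_star)])

    while True:
        outer += 1
        if outer > params.max_outer:
            converged = False
            warnings.warn("TSVM stopped at max_outer without convergence",
                          stacklevel=2)
            break
        weights[n_l:] = c_star
        model = _solve_svc(k_full, y_all, 1.0, weights)
        f_all = decision_values(model, k_full)
        slack = np.maximum(0.0, 1.0 - y_all * f_all)[n_l:]
        # batch-swap disjoint violating +/- pairs, most violating first
        pos_u = np.flatnonzero(y_u > 0)
        neg_u = np.flatnonzero(y_u < 0)
        pos_u = pos_u[np.argsort(-slack[pos_u], kind="stable")]
        neg_u = neg_u[np.argsort(-slack[neg_u], kind="stable")]
        swapped = False
        for i, j in zip(pos_u, neg_u):
            if not (slack[i] > 1e-9 and slack[j] > 1e-9
                    and slack[i] + slack[j] > 2.0 + 1e-9):
                break
            y_u[i], y_u[j] = -1.0, 1.0
            y_all[n_l + i], y_all[n_l + j] = -1.0, 1.0
            n_switches += 1
            swapped = True
        if not swapped:
            if c_star >= c_star_max - 1e-15:
                break
            c_star = min(2.0 * c_star, c_star_max)

    f_u_final = decision_values(model, k_full[n_l:, :])
    return TSVMModel(base=model, transduced_labels=y_u.copy(),
                     decision_unlabeled=f_u_final,
                     c_unlabeled_final=c_star, n_switches=n_switches,
                     pos_fraction=pos_frac, converged=converged,
                     labeled_mask=np.concatenate(
                         [np.ones(n_l, bool), np.zeros(n_u, bool)]))


def predict_disease_genes(
    model: TSVMModel, gene_ids: list[str]
) -> list[tuple[str, float, int]]:
    """Rank unlabeled genes by decision value (descending); label +1 marks
    a predicted disease-related gene."""
    if len(gene_ids) != len(model.transduced_labels):
        raise ValueError("one gene id per unlabeled point required")
    rows = [
        (gid, float(f), int(lbl))
        for gid, f, lbl in zip(gene_ids, model.decision_unlabeled,
                               model.transduced_labels)
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def linear_gram(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Plain inner-product kernel on raw gene profiles."""
    b = a if b is None else b
    return np.atleast_2d(a) @ np.atleast_2d(b).T


def rbf_gram(a: np.ndarray, b: np.ndarray | None = None,
             bandwidth: float | None = None) -> np.ndarray:
    """Gaussian kernel exp(−‖a_i − b_j‖² / (2σ²)) on raw gene profiles;
    σ defaults to the median pairwise distance within ``a``."""
    a = np.atleast_2d(a)
    b = a if b is None else np.atleast_2d(b)
    aa = np.einsum("ij,ij->i", a, a)
    bb = np.einsum("ij,ij->i", b, b)
    d2 = np.maximum(aa[:, None] + bb[None, :] - 2.0 * (a @ b.T), 0.0)
    if bandwidth is None:
        da = np.maximum(aa[:, None] + aa[None, :] - 2.0 * (a @ a.T), 0.0)
        iu = np.triu_indices(a.shape[0], k=1)
        med = np.sqrt(np.median(da[iu])) if iu[0].size else 1.0
        bandwidth = float(med) if med > 0 else 1.0
    return np.exp(-d2 / (2.0 * bandwidth * bandwidth))


def check_kkt(model: SVMModel, k: np.ndarray, tol: float = 1e-6) -> None:
    """Assert dual feasibility and stationarity of a fitted SVM.

    Checks 0 ≤ α ≤ C, Σ α_i y_i = 0, and the margin conditions
    y_i f(x_i) ≥ 1 for α_i = 0, = 1 for interior α, ≤ 1 at the box.
    Raises AssertionError on violation; used by the test suite on every
    fitted model.
    """
    c_i = model.c_labeled * (model.sample_weight
                             if model.sample_weight is not None else 1.0)
    c_i = np.broadcast_to(np.asarray(c_i, float), model.alpha.shape)
    assert (model.alpha >= -tol).all(), "negative dual coefficient"
    assert (model.alpha <= c_i + tol * np.maximum(1.0, c_i)).all(), \
        "dual coefficient above box"
    assert abs(float(model.alpha @ model.y)) < tol * max(1.0, model.alpha.sum()), \
        "equality constraint violated"
    f = decision_values(model, k)
    margin = model.y * f
    free = (model.alpha > tol * c_i) & (model.alpha < c_i * (1 - tol) - tol)
    assert np.all(np.abs(margin[free] - 1.0) < 1e-3), "free SV off the margin"
    zero = model.alpha <= tol * np.maximum(1.0, c_i)
    assert np.all(margin[zero] >= 1.0 - 1e-3), "zero-α point inside margin"
    at_box = model.alpha >= c_i - tol * np.maximum(1.0, c_i)
    assert np.all(margin[at_box] <= 1.0 + 1e-3), "box-α point outside margin"
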