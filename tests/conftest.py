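import numpy as np
import pytest

from weakde import ExpressionMatrix, SynthConfig, generate


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes × 4 samples over two stages."""
    return ExpressionMatrix(
        values=np.array([[1.0, 2.0, 3.0, 4.0],
                         [0.5, 0.5, 2.5, 2.5],
                         [5.0, 4.0, 3.0, 2.0]]),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        sample_qs=np.array([20, 20, 175, 175]),
    )


@pytest.fixture(scope="session")
def hd_small():
    """A small six-stage dataset with planted structure, shared across
    tests that only need shape and signal, not the full benchmark size."""
    cfg = SynthConfig(seed=7, n_genes=300, n_de_late=20, n_de_mid=20,
                      n_de_shared=20, n_labeled_pos=25, n_labeled_neg=120)
    return generate(cfg)


def triple_loop_objective(w, b, x, y, s, lam, gamma):
    """Literal term-by-term evaluation of the ranking objective."""
    n, m = x.shape
    val = 0.0
    for i in range(m):
        val += float(np.sum((w.T @ x[:, i] + b - y[:, i]) ** 2))
    for i in range(m):
        for j in range(m):
            val += lam / 2.0 * float(
                np.sum((w.T @ x[:, i] - w.T @ x[:, j]) ** 2)) * s[i, j]
    for k in range(n):
        val += gamma * float(np.linalg.norm(w[k]))
    return val


def double_loop_gram(genes_a, genes_b, sample_qs, q_order):
    """Brute-force difference kernel: φ·φ per gene pair."""
    from weakde import phi

    out = np.zeros((len(genes_a), len(genes_b)))
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            out[i, j] = float(phi(ga, sample_qs, q_order)
                              @ phi(gb, sample_qs, q_order))
    return out


def slsqp_dual_objective(k, y, c):
    """Independent QP solve of the SVM dual; returns the optimal dual
    objective value."""
    from scipy.optimize import minimize

    y = np.asarray(y, float)
    n = len(y)

    def neg_dual(a):
        v = a * y
        return -(a.sum() - 0.5 * v @ k @ v)

    res = minimize(
        neg_dual, np.full(n, min(c, 1.0) / 2), method="SLSQP",
        bounds=[(0.0, c)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return -res.fun
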