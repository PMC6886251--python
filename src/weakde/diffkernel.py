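"""The difference space and difference kernel over staged group means.

Here *genes* are the data points: a gene's expression vector over samples
is summarized by its per-stage group means m_{Q_1}, …, m_{Q_|Q|} (stages in
ascending numeric order, e.g. Q = 20, 80, 92, 111, 140, 175 for the HD
mouse design), and mapped by

    φ(gene)_i = m_{Q_i} − m_{Q_{i+1}},  i = 1 … |Q| − 1,

into the *difference space* of adjacent-stage expression changes.  Two
genes whose expression moves the same way as the disease progresses have
aligned φ images regardless of their absolute expression level — shared
offsets cancel in the differences.  The difference kernel is the ordinary
inner product in this space, k(a, b) = φ(a)ᵀ φ(b), hence every Gram matrix
is symmetric positive semidefinite.  The direction of differencing
(earlier minus later) only flips the sign of every coordinate and leaves
the kernel unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["QGroupSummary", "group_means", "phi", "phi_matrix", "gram"]


@dataclass
class QGroupSummary:
    """Per-stage means and sample counts for one gene."""

    q_order: tuple[int, ...]
    means: np.ndarray          # length |Q|
    counts: np.ndarray         # samples per stage, length |Q|


def _stage_masks(sample_qs: np.ndarray, q_order: Sequence[int]) -> list[np.ndarray]:
    sample_qs = np.asarray(sample_qs)
    masks = []
    for q in q_order:
        mask = sample_qs == q
        if not mask.any():
            raise ValueError(f"stage Q{q} has no samples")
        masks.append(mask)
    return masks


def group_means(
    gene_row: np.ndarray, sample_qs: np.ndarray, q_order: Sequence[int]
) -> QGroupSummary:
    """Arithmetic mean of a gene's expression within each stage of
    ``q_order``; errors on a stage with no samples."""
    gene_row = np.asarray(gene_row, dtype=float)
    masks = _stage_masks(sample_qs, q_order)
    means = np.array([gene_row[m].mean() for m in masks])
    counts = np.array([int(m.sum()) for m in masks])
    return QGroupSummary(tuple(int(q) for q in q_order), means, counts)


def phi(
    gene_row: np.ndarray, sample_qs: np.ndarray, q_order: Sequence[int]
) -> np.ndarray:
    """Map one gene into difference space: adjacent group-mean differences
    m_{Q_i} − m_{Q_{i+1}} (length |Q| − 1)."""
    if len(q_order) < 2:
        raise ValueError("need at least two stages to form differences")
    means = group_means(gene_row, sample_qs, q_order).means
    return means[:-1] - means[1:]


def phi_matrix(
    genes: np.ndarray, sample_qs: np.ndarray, q_order: Sequence[int]
) -> np.ndarray:
    """Vectorized :func:`phi` for a genes × samples block; returns
    genes × (|Q| − 1)."""
    genes = np.atleast_2d(np.asarray(genes, dtype=float))
    if len(q_order) < 2:
        raise ValueError("need at least two stages to form differences")
    masks = _stage_masks(np.asarray(sample_qs), q_order)
    means = np.column_stack([genes[:, m].mean(axis=1) for m in masks])
    return means[:, :-1] - means[:, 1:]


def gram(
    genes_a: np.ndarray,
    genes_b: np.ndarray,
    sample_qs: np.ndarray,
    q_order: Sequence[int],
) -> np.ndarray:
    """Difference-kernel Gram matrix: entry (i, j) = φ(a_i)ᵀ φ(b_j).

    Both gene blocks must be expression over the same samples.
    """
    genes_a = np.atleast_2d(genes_a)
    genes_b = np.atleast_2d(genes_b)
    if genes_a.shape[1] != genes_b.shape[1]:
        raise ValueError("gene blocks must share the same sample columns")
    pa = phi_matrix(genes_a, sample_qs, q_order)
    pb = phi_matrix(genes_b, sample_qs, q_order)
    return pa @ pb.T
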