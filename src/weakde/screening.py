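"""Iterative weakly supervised screening of differentially expressed genes.

Staged disease data give two kinds of label: *strong* labels — samples that
are clearly normal (e.g. Q20) or clearly diseased (a late stage such as
Q175) — and *weak* labels — intermediate stages whose disease status is
uncertain.  The screening loop exploits both:

  round r:
    1. rank all genes by the ℓ2,1 row-norm criterion on the current
       training samples (normal vs disease indicator targets) and union
       the top M into the DE set;
    2. train a sample classifier (GBDT by default) on the training
       samples restricted to the current DE genes;
    3. classify the remaining weak-label candidates; candidates called
       diseased are absorbed — permanently — into the disease class;
    4. stop when the update fraction |new additions| / |DE set| drops to
       θ or below, when nothing can change any more, or at max_rounds.

Two screening schemes are provided: the *two-label* scheme runs the loop
seeded on the late stage and again seeded on the mid stage (same weak
stages) and intersects the two converged DE sets; the *single-label*
scheme runs once, seeded on the late stage with every other disease stage
as a weak candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from .io import ExpressionMatrix
from .l21 import (L21Params, build_similarity, fit_l21, make_targets,
                  median_pairwise_distance, rank_genes)

__all__ = [
    "GBDTConfig",
    "ScreeningConfig",
    "RoundRecord",
    "ScreeningResult",
    "update_fraction",
    "run_screening",
    "run_two_label",
    "run_single_label",
]


@dataclass
class GBDTConfig:
    """Gradient-boosted decision tree settings for the in-loop sample
    classifier.  The seed is mandatory so runs are bit-reproducible."""

    seed: int
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1

    def build(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.seed,
        )


@dataclass
class ScreeningConfig:
    """Parameters of one screening run.

    ``m_genes`` (M) is the number of top-ranked genes unioned into the DE
    set each round; ``theta`` (θ) the convergence threshold on the update
    fraction.  ``normal_q``/``seed_disease_q`` define the strong-label
    training stages, ``weak_qs`` the weak-label candidate stages.
    """

    classifier: GBDTConfig
    m_genes: int = 1500
    theta: float = 0.05
    normal_q: int = 20
    seed_disease_q: int = 175
    weak_qs: tuple[int, ...] = (140, 92, 80)
    absorb_threshold: float = 0.5
    max_rounds: int = 10
    update_rule: str = "new_over_current"   # or "symmetric"

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.m_genes < 1 or self.max_rounds < 1:
            raise ValueError("m_genes and max_rounds must be positive")
        strong = {self.normal_q, self.seed_disease_q}
        if strong & set(self.weak_qs):
            raise ValueError("weak stages must be disjoint from strong stages")


@dataclass
class RoundRecord:
    round: int
    n_added: int
    n_absorbed: int
    update_fraction: float


@dataclass
class ScreeningResult:
    de_genes: set[str]
    trace: list[RoundRecord] = field(default_factory=list)
    converged: bool = False
    rounds: int = 0


def update_fraction(previous: set, current: set, rule: str = "new_over_current") -> float:
    """Proportion of the current DE set that is newly added.

    Default ``new_over_current`` = |current \\ previous| / |current| (the
    natural reading for a monotone union dynamic); ``symmetric`` uses the
    symmetric difference over the union instead.
    """
    if not current:
        raise ValueError("current DE set is empty")
    if rule == "new_over_current":
        return len(current - previous) / len(current)
    if rule == "symmetric":
        union = previous | current
        return len(previous ^ current) / len(union)
    raise ValueError(f"unknown update rule {rule!r}")


def run_screening(
    x: ExpressionMatrix,
    cfg: ScreeningConfig,
    l21: L21Params | None = None,
) -> ScreeningResult:
    """Run the iterative screening loop (see module docstring).

    ``x`` should already be preprocessed (filtered, per-sample
    normalized).  Raises if M exceeds the gene count or a strong stage is
    underpopulated.
    """
    l21 = l21 or L21Params()
    if cfg.m_genes > x.n_genes:
        raise ValueError(f"M={cfg.m_genes} exceeds {x.n_genes} genes")
    qs = x.sample_qs
    normal_idx = np.flatnonzero(qs == cfg.normal_q)
    seed_idx = np.flatnonzero(qs == cfg.seed_disease_q)
    if normal_idx.size < 2 or seed_idx.size < 2:
        raise ValueError("normal and seed-disease stages each need >= 2 samples")
    candidates = [int(i) for q in cfg.weak_qs
                  for i in np.flatnonzero(qs == q)]

    train_idx = np.concatenate([normal_idx, seed_idx])
    train_y = np.concatenate([np.zeros(normal_idx.size), np.ones(seed_idx.size)])

    de: set[str] = set()
    de_idx: list[int] = []
    in_de = np.zeros(x.n_genes, dtype=bool)
    trace: list[RoundRecord] = []
    converged = False

    for rnd in range(1, cfg.max_rounds + 1):
        xt = x.values[:, train_idx]
        if len(set(train_y.tolist())) < 2:
            raise ValueError("training set collapsed to a single class")
        y_mat, _ = make_targets(train_y)
        t = l21.t if l21.t is not None else median_pairwise_distance(xt)
        s = build_similarity(xt, train_y, t)
        model = fit_l21(xt, y_mat, s, l21)
        top = rank_genes(model)[: cfg.m_genes]
        new = [int(i) for i in top if not in_de[i]]
        in_de[new] = True
        de_idx.extend(new)
        current = de | {x.gene_ids[i] for i in new}
        uf = update_fraction(de, current, cfg.update_rule)
        de = current

        n_absorbed = 0
        if candidates:
            clf = cfg.classifier.build()
            feat = sorted(de_idx)
            clf.fit(xt[feat, :].T, train_y)
            cand = np.asarray(candidates)
            prob = clf.predict_proba(x.values[np.ix_(feat, cand)].T)[:, 1]
            absorbed = cand[prob >= cfg.absorb_threshold]
            if absorbed.size:
                train_idx = np.concatenate([train_idx, absorbed])
                train_y = np.concatenate([train_y, np.ones(absorbed.size)])
                keep = set(cand[prob < cfg.absorb_threshold].tolist())
                candidates = [i for i in candidates if i in keep]
                n_absorbed = int(absorbed.size)

        trace.append(RoundRecord(rnd, len(new), n_absorbed, uf))

        if uf <= cfg.theta:
            converged = True
            break
        if not candidates and n_absorbed == 0:
            # training set can never change again: the next round would
            # reproduce this ranking exactly, so the set has converged
            converged = True
            break

    return ScreeningResult(de_genes=de, trace=trace, converged=converged,
                           rounds=len(trace))


def run_two_label(
    x: ExpressionMatrix,
    cfg_late: ScreeningConfig,
    cfg_mid: ScreeningConfig,
    l21: L21Params | None = None,
) -> tuple[ScreeningResult, ScreeningResult, set[str]]:
    """Two-label scheme: screen seeded on the late stage and on the mid
    stage, then intersect the converged DE sets."""
    late = run_screening(x, cfg_late, l21)
    mid = run_screening(x, cfg_mid, l21)
    inter = late.de_genes & mid.de_genes
    if not inter:
        warnings.warn("two-label DE sets are disjoint; empty intersection",
                      stacklevel=2)
    return late, mid, inter


def run_single_label(
    x: ExpressionMatrix,
    cfg: ScreeningConfig,
    l21: L21Params | None = None,
) -> ScreeningResult:
    """Single-label scheme: one screening run seeded on the late stage
    with all other disease stages as weak candidates."""
    return run_screening(x, cfg, l21)


def default_two_label_configs(
    classifier: GBDTConfig,
    q_order: Sequence[int] = (20, 80, 92, 111, 140, 175),
    **kwargs,
) -> tuple[ScreeningConfig, ScreeningConfig]:
    """Late- and mid-seeded configurations for the two-label scheme on a
    six-stage design: seeds are the last and fourth stages, weak stages the
    remaining disease stages, mirroring Q175/Q111 with weak Q140, Q92, Q80."""
    q = list(q_order)
    if len(q) < 4:
        raise ValueError("two-label scheme needs at least four stages")
    normal, late, mid = q[0], q[-1], q[3]
    weak = tuple(s for s in q[1:] if s not in (late, mid))
    cfg_late = ScreeningConfig(classifier=classifier, normal_q=normal,
                               seed_disease_q=late, weak_qs=weak, **kwargs)
    cfg_mid = ScreeningConfig(classifier=replace(classifier), normal_q=normal,
                              seed_disease_q=mid, weak_qs=weak, **kwargs)
    return cfg_late, cfg_mid


def default_single_label_config(
    classifier: GBDTConfig,
    q_order: Sequence[int] = (20, 80, 92, 111, 140, 175),
    **kwargs,
) -> ScreeningConfig:
    """Single-label configuration: late stage seeds, every other disease
    stage is weak (Q140, Q111, Q92, Q80 on the HD design)."""
    q = list(q_order)
    return ScreeningConfig(classifier=classifier, normal_q=q[0],
                           seed_disease_q=q[-1], weak_qs=tuple(q[1:-1][::-1]),
                           **kwargs)
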