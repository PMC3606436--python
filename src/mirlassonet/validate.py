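"""Enrichment baselines and ROC validation against a gold standard.

Fisher's exact test and the hypergeometric tail test score the overlap
between a gene list and a miRNA's target set within a gene universe; they are
the classical alternatives the regression model is compared against.

ROC analysis labels every (disease, miRNA) pair of the evaluation grid by
gold-standard membership; pairs without a predicted score are imputed 0
(the Lasso zeroes non-associations by construction).  AUC is computed as the
trapezoidal area of the threshold-sweep curve, which equals the Mann-Whitney
rank statistic with the usual tie correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import EdgeList
from .lasso import AssociationNetwork

__all__ = [
    "EnrichmentResult",
    "ROCResult",
    "fisher_enrichment",
    "hypergeometric_enrichment",
    "roc_auc",
    "roc_per_disease",
]


@dataclass
class EnrichmentResult:
    mirna_id: str
    overlap: int
    list_size: int
    target_size: int
    universe_size: int
    p_value: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.list_size, self.target_size):
            raise ValueError("overlap cannot exceed either margin")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _contingency(
    gene_list: Iterable[str], mirna_targets: Iterable[str], universe: Iterable[str]
) -> tuple[int, int, int, int, int]:
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    L = set(gene_list) & universe
    T = set(mirna_targets) & universe
    a = len(L & T)
    b = len(L) - a
    c = len(T) - a
    d = len(universe) - a - b - c
    return a, b, c, d, len(universe)


def fisher_enrichment(
    gene_list: Iterable[str],
    mirna_targets: Iterable[str],
    universe: Iterable[str],
    mirna_id: str = "",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher's exact test on the 2x2 overlap table.

    Two-sided by default (sum of tables no more probable than the observed
    one, margins fixed).  The odds ratio is the sample estimate ad/bc, with
    infinity when bc = 0.
    """
    a, b, c, d, n = _contingency(gene_list, mirna_targets, universe)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return EnrichmentResult(
        mirna_id=mirna_id, overlap=a, list_size=a + b, target_size=a + c,
        universe_size=n, p_value=float(min(p, 1.0)), odds_ratio=odds,
    )


def hypergeometric_enrichment(
    gene_list: Iterable[str],
    mirna_targets: Iterable[str],
    universe: Iterable[str],
    mirna_id: str = "",
) -> EnrichmentResult:
    """One-sided over-representation: P(overlap >= observed) under
    Hypergeometric(universe_size, target_size, list_size)."""
    a, b, c, d, n = _contingency(gene_list, mirna_targets, universe)
    p = float(stats.hypergeom.sf(a - 1, n, a + c, a + b))
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return EnrichmentResult(
        mirna_id=mirna_id, overlap=a, list_size=a + b, target_size=a + c,
        universe_size=n, p_value=min(p, 1.0), odds_ratio=odds,
    )


@dataclass
class ROCResult:
    """ROC curve and area.  ``points`` runs from (0,0) to (1,1) with both
    coordinates non-decreasing; ``auc`` is their trapezoidal area."""

    auc: float
    points: list[tuple[float, float]]
    n_pos: int
    n_neg: int


def _roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0:
        raise ValueError("ROC requires at least one positive pair")
    if n_neg == 0:
        raise ValueError("ROC requires at least one negative pair")

    # threshold sweep, descending; tied scores collapse into one segment
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(l_sorted[i:j].sum())
        fp += (j - i) - int(l_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return ROCResult(auc=auc, points=points, n_pos=n_pos, n_neg=n_neg)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC with midrank tie handling: the probability that a
    random positive outranks a random negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative examples")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _grid_scores(
    predictions: AssociationNetwork | Mapping[tuple[str, str], float],
    gold: EdgeList,
    disease_ids: Sequence[str] | None,
    mirna_ids: Sequence[str] | None,
) -> tuple[list[str], list[str], dict[tuple[str, str], float], set[tuple[str, str]]]:
    if isinstance(predictions, AssociationNetwork):
        score_map = predictions.scores()
    else:
        score_map = dict(predictions)
    gold_pairs = set(gold.edges)
    if disease_ids is None:
        disease_ids = sorted({d for d, _ in gold_pairs} | {d for d, _ in score_map})
    if mirna_ids is None:
        mirna_ids = sorted({m for _, m in gold_pairs} | {m for _, m in score_map})
    return list(disease_ids), list(mirna_ids), score_map, gold_pairs


def roc_auc(
    predictions: AssociationNetwork | Mapping[tuple[str, str], float],
    gold: EdgeList,
    disease_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
) -> ROCResult:
    """Pooled ROC over the full disease x miRNA grid.

    Positives are the gold-standard pairs; negatives are every other grid
    pair.  Pairs without a prediction score 0.
    """
    diseases, mirnas, score_map, gold_pairs = _grid_scores(
        predictions, gold, disease_ids, mirna_ids
    )
    scores, labels = [], []
    for d in diseases:
        for m in mirnas:
            scores.append(score_map.get((d, m), 0.0))
            labels.append((d, m) in gold_pairs)
    return _roc_from_scores(np.array(scores), np.array(labels))


def roc_per_disease(
    predictions: AssociationNetwork | Mapping[tuple[str, str], float],
    gold: EdgeList,
    disease_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
) -> dict[str, ROCResult]:
    """One ROC per disease over its row of the grid.  Diseases without any
    gold positive (or with no negatives) are omitted."""
    diseases, mirnas, score_map, gold_pairs = _grid_scores(
        predictions, gold, disease_ids, mirna_ids
    )
    out: dict[str, ROCResult] = {}
    for d in diseases:
        scores = np.array([score_map.get((d, m), 0.0) for m in mirnas])
        labels = np.array([(d, m) in gold_pairs for m in mirnas])
        if labels.any() and not labels.all():
            out[d] = _roc_from_scores(scores, labels)
    return out


def write_roc_report(results: Mapping[str, ROCResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tauc\tn_pos\tn_neg\n")
        for d, r in results.items():
            fh.write(f"{d}\t{r.auc:.6f}\t{r.n_pos}\t{r.n_neg}\n")


def plot_roc(results: Mapping[str, ROCResult], path) -> None:
    """Optional PNG of the per-disease ROC curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for d, r in results.items():
        xs, ys = zip(*r.points)
        ax.plot(xs, ys, label=f"{d} (AUC={r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
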