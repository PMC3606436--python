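"""Disease gene signatures.

Expression signatures use a moderated mean-difference score in the SAM style:
``d_i = (mean_case_i - mean_control_i) / (s_i + s0)`` where ``s_i`` is the
pooled standard error of the group difference and ``s0`` is a fudge factor
(the median of the ``s_i`` when "auto") that damps scores of low-variance
genes.  Genes are then selected by rank (top-k up, top-k down), so the
permutation-based FDR machinery of full SAM is not needed here.

Text signatures come from a gene-disease relevance table filtered on a
strictly positive relevance score and a minimum citation count; they carry no
direction.  The merged per-disease signature is the union of the two, with the
expression direction kept where known.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    GeneSignature,
    TextRelevanceTable,
    normalize_symbol,
)

__all__ = [
    "DStatResult",
    "DiseaseSignatureMatrix",
    "d_statistic",
    "expression_signature",
    "text_signature",
    "merge_signatures",
    "build_disease_matrix",
]


@dataclass
class DStatResult:
    """Per-gene differential score, with the fudge factor actually used."""

    gene_ids: list[str]
    d: np.ndarray
    s0: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.gene_ids),):
            raise ValueError("one d value required per gene")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite d statistic")


@dataclass
class DiseaseSignatureMatrix:
    """Genes x diseases response matrix.

    Entries are binary membership {0,1} by default, or signed {-1,0,+1}
    when built in signed mode (down-regulated genes get -1).
    """

    gene_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.disease_ids)):
            raise ValueError("values shape must be genes x diseases")
        allowed = {-1.0, 0.0, 1.0} if self.signed else {0.0, 1.0}
        present = set(np.unique(self.values))
        if not present <= allowed:
            raise ValueError(f"invalid matrix entries {sorted(present - allowed)}")

    def column(self, disease_id: str) -> np.ndarray:
        return self.values[:, self.disease_ids.index(disease_id)]


def d_statistic(expr: ExpressionMatrix, s0: float | str = "auto") -> DStatResult:
    """Moderated mean-difference score per gene.

    ``s_i = sqrt((1/n1 + 1/n2) * (ss_control + ss_case) / (n1 + n2 - 2))``
    is the pooled standard error of the case-minus-control difference;
    ``d_i = (mean_case - mean_control) / (s_i + s0)``.

    With ``s0="auto"`` the fudge factor is the median of the ``s_i``.
    """
    expr.require_two_groups()
    labels = np.asarray(expr.group_labels)
    case = expr.values[:, labels == CASE]
    control = expr.values[:, labels == CONTROL]
    n1, n2 = control.shape[1], case.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("d_statistic requires >= 2 samples per group")

    diff = case.mean(axis=1) - control.mean(axis=1)
    ss = ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))

    if isinstance(s0, str):
        if s0 != "auto":
            raise ValueError("s0 must be a non-negative number or 'auto'")
        s0_val = float(np.median(s))
    else:
        s0_val = float(s0)
    if s0_val < 0:
        raise ValueError("s0 must be >= 0")
    denom = s + s0_val
    if np.any(denom == 0):
        raise ValueError(
            "gene(s) with zero variance in both groups; use s0 > 0 "
            "(or s0='auto' with at least one variable gene)"
        )
    return DStatResult(gene_ids=list(expr.gene_ids), d=diff / denom, s0=s0_val)


def _top_k(gene_ids: Sequence[str], d: np.ndarray, k: int, positive: bool) -> set[str]:
    if positive:
        idx = [i for i in range(len(gene_ids)) if d[i] > 0]
    else:
        idx = [i for i in range(len(gene_ids)) if d[i] < 0]
    # ties broken by |d| descending then gene id ascending
    idx.sort(key=lambda i: (-abs(d[i]), gene_ids[i]))
    return {gene_ids[i] for i in idx[:k]}


def expression_signature(
    dstat: DStatResult, k_up: int, k_down: int, disease_id: str
) -> GeneSignature:
    """Top-``k_up`` genes among positive scores and top-``k_down`` among
    negative scores; fewer are taken if fewer qualify."""
    if k_up < 0 or k_down < 0:
        raise ValueError("k_up and k_down must be >= 0")
    return GeneSignature(
        disease_id=disease_id,
        up_genes=_top_k(dstat.gene_ids, dstat.d, k_up, positive=True),
        down_genes=_top_k(dstat.gene_ids, dstat.d, k_down, positive=False),
        source="expression",
    )


def text_signature(
    table: TextRelevanceTable,
    disease_id: str,
    min_relevance: float = 0.0,
    min_citations: int = 11,
) -> GeneSignature:
    """Genes with relevance strictly above ``min_relevance`` and at least
    ``min_citations`` citations.  Direction is unknown for text mining, so all
    selected genes are reported in ``up_genes``."""
    if min_relevance < 0 or min_citations < 0:
        raise ValueError("thresholds must be >= 0")
    disease_id = normalize_symbol(disease_id)
    records = table.for_disease(disease_id)
    if not records:
        warnings.warn(f"disease {disease_id!r} absent from relevance table", stacklevel=2)
    genes = {
        r.gene_id
        for r in records
        if r.relevance_score > min_relevance and r.citation_count >= min_citations
    }
    return GeneSignature(disease_id=disease_id, up_genes=genes, down_genes=set(),
                         source="text")


def merge_signatures(expr_sig: GeneSignature, text_sig: GeneSignature) -> GeneSignature:
    """Union of the expression and text signatures for one disease.

    Direction is kept from the expression signature where available;
    text-only genes are direction-unknown and stored in ``up_genes``.
    """
    if expr_sig.disease_id != text_sig.disease_id:
        raise ValueError(
            f"disease mismatch: {expr_sig.disease_id!r} vs {text_sig.disease_id!r}"
        )
    down = set(expr_sig.down_genes)
    up = set(expr_sig.up_genes) | (text_sig.genes - down)
    return GeneSignature(
        disease_id=expr_sig.disease_id, up_genes=up, down_genes=down, source="merged"
    )


def build_disease_matrix(
    signatures: Sequence[GeneSignature],
    gene_universe: Iterable[str],
    signed: bool = False,
) -> DiseaseSignatureMatrix:
    """Assemble the genes x diseases response matrix over a gene universe.

    Rows are restricted to ``gene_universe`` (order preserved if a sequence,
    sorted if a set).  Membership encoding puts 1 on each gene in the disease's
    signature; signed mode puts -1 on down-regulated genes instead.
    """
    if isinstance(gene_universe, (set, frozenset)):
        universe = sorted(gene_universe)
    else:
        universe = list(gene_universe)
    if not universe:
        raise ValueError("gene_universe must be non-empty")
    row_of = {g: i for i, g in enumerate(universe)}
    disease_ids = [s.disease_id for s in signatures]
    values = np.zeros((len(universe), len(signatures)))
    for j, sig in enumerate(signatures):
        hit = False
        for g in sig.up_genes:
            if g in row_of:
                values[row_of[g], j] = 1.0
                hit = True
        for g in sig.down_genes:
            if g in row_of:
                values[row_of[g], j] = -1.0 if signed else 1.0
                hit = True
        if not hit:
            warnings.warn(
                f"disease {sig.disease_id!r} has an empty signature after "
                "restriction to the gene universe",
                stacklevel=2,
            )
    return DiseaseSignatureMatrix(
        gene_ids=universe, disease_ids=disease_ids, values=values, signed=signed
    )
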