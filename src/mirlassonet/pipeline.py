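"""End-to-end orchestration of the four pipeline stages:

1. disease gene signatures (expression d-statistic + text filter, merged),
2. the miRNA influence matrix (direct targets + PPI-propagated indirect),
3. per-disease Lasso fits over the intersected gene universe,
4. ROC validation of the scored associations against a gold standard.

`run_pipeline` works on in-memory objects (used by the synthetic benchmark
and the tests); the CLI wraps it with file IO and a provenance manifest.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .io import Config, EdgeList, ExpressionMatrix, GeneSignature, TextRelevanceTable, sha256_of
from .lasso import AssociationNetwork, MirnaLassoResults, extract_associations, fit_disease
from .netmir import NetMiRMatrix, build_netmir, indirect_targets, intersect_universe
from .signatures import (
    build_disease_matrix,
    d_statistic,
    expression_signature,
    merge_signatures,
    text_signature,
)
from .validate import ROCResult, roc_auc, roc_per_disease

__all__ = ["PipelineResult", "build_signatures", "build_influence_matrix",
           "run_pipeline", "write_manifest"]


@dataclass
class PipelineResult:
    signatures: list[GeneSignature]
    netmir: NetMiRMatrix
    fits: list[MirnaLassoResults]
    associations: AssociationNetwork
    roc_by_disease: dict[str, ROCResult]
    roc_pooled: ROCResult | None

    @property
    def mean_disease_auc(self) -> float:
        if not self.roc_by_disease:
            raise ValueError("no per-disease ROC results")
        return float(np.mean([r.auc for r in self.roc_by_disease.values()]))


def build_signatures(
    expression: dict[str, ExpressionMatrix],
    text: TextRelevanceTable | None,
    config: Config,
) -> list[GeneSignature]:
    """Merged per-disease signatures from expression and (optionally) text."""
    out: list[GeneSignature] = []
    for disease_id, expr in expression.items():
        dstat = d_statistic(expr, s0="auto")
        expr_sig = expression_signature(dstat, config.k_up, config.k_down, disease_id)
        if text is not None:
            txt_sig = text_signature(
                text, disease_id,
                min_relevance=config.min_relevance,
                min_citations=config.min_citations,
            )
            out.append(merge_signatures(expr_sig, txt_sig))
        else:
            out.append(expr_sig)
    return out


def build_influence_matrix(
    direct: EdgeList,
    ppi: EdgeList | None,
    config: Config,
    use_indirect: bool = True,
) -> NetMiRMatrix:
    """Direct plus (optionally) PPI-propagated indirect targets, over the
    universe of genes with at least one entry and all miRNAs with direct
    edges."""
    if use_indirect and ppi is not None:
        indirect = indirect_targets(
            ppi, direct,
            min_neighbors=config.min_neighbors,
            any_mirna=config.any_mirna_indirect,
        )
    else:
        if use_indirect and ppi is None:
            warnings.warn("no PPI network given; indirect-target step skipped")
        indirect = set()
    genes = sorted(direct.targets() | {g for g, _ in indirect})
    mirnas = sorted(direct.sources())
    return build_netmir(direct, indirect, genes, mirnas)


def run_pipeline(
    expression: dict[str, ExpressionMatrix],
    text: TextRelevanceTable | None,
    direct: EdgeList,
    ppi: EdgeList | None,
    gold: EdgeList | None,
    config: Config | None = None,
    use_indirect: bool = True,
) -> PipelineResult:
    """Run signatures -> influence matrix -> per-disease Lasso -> ROC."""
    config = config or Config()
    sigs = build_signatures(expression, text, config)
    netmir_full = build_influence_matrix(direct, ppi, config, use_indirect)

    sig_universe = sorted(set().union(*(s.genes for s in sigs)))
    disease_matrix = build_disease_matrix(sigs, sig_universe,
                                          signed=config.signed_response)
    netmir, disease_matrix = intersect_universe(netmir_full, disease_matrix)

    fits = [
        fit_disease(netmir, disease_matrix, d, config)
        for d in disease_matrix.disease_ids
    ]
    associations = extract_associations(fits, keep_sign=config.keep_sign)

    roc_by_disease: dict[str, ROCResult] = {}
    roc_pooled: ROCResult | None = None
    if gold is not None and len(gold):
        roc_by_disease = roc_per_disease(
            associations, gold,
            disease_ids=disease_matrix.disease_ids,
            mirna_ids=netmir.mirna_ids,
        )
        roc_pooled = roc_auc(
            associations, gold,
            disease_ids=disease_matrix.disease_ids,
            mirna_ids=netmir.mirna_ids,
        )
    return PipelineResult(
        signatures=sigs, netmir=netmir, fits=fits, associations=associations,
        roc_by_disease=roc_by_disease, roc_pooled=roc_pooled,
    )


def write_manifest(
    outdir: str | Path,
    command: str,
    config: Config,
    seed: int,
    inputs: dict[str, str | Path],
    outputs: dict[str, str | Path],
) -> Path:
    """Provenance record: version, config snapshot, input/output digests."""
    manifest = {
        "tool": "mirlassonet",
        "version": __version__,
        "command": command,
        "config": dataclasses.asdict(config),
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {name: sha256_of(p) for name, p in inputs.items()},
        "outputs": {name: sha256_of(p) for name, p in outputs.items()},
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
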