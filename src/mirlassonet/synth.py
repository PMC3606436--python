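"""Coupled synthetic inputs with planted disease-miRNA ground truth.

The generator emulates every input the pipeline consumes -- a PPI network, a
direct miRNA-target edge list, per-disease two-group expression matrices, a
text-mining relevance table and a gold-standard edge list -- under a simple
planted model: each disease is caused by a few miRNAs, its true gene
signature is a thinned, noise-polluted union of those miRNAs' direct and
PPI-indirect targets, and case samples shift expression of signature genes by
a fixed effect size.  One master seed fixes every artifact.

Defaults are deliberately modest (600 genes, 50 miRNAs, 8 diseases) so a full
pipeline run takes seconds while still exercising every stage.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import (
    CASE,
    CONTROL,
    EdgeList,
    ExpressionMatrix,
    TextRelevanceRecord,
    TextRelevanceTable,
)
from .netmir import indirect_targets

__all__ = ["SynthConfig", "SynthTruth", "SynthData",
           "generate_networks", "generate_disease_data", "generate_all"]


@dataclass
class SynthConfig:
    n_genes: int = 600
    n_mirnas: int = 50
    n_diseases: int = 8
    targets_per_mirna: int = 30
    ppi_mean_degree: float = 6.0
    planted_mirnas_per_disease: int = 3
    signature_noise_frac: float = 0.2   # fraction of signature genes replaced by random genes
    signature_dropout_frac: float = 0.3  # fraction of planted-target genes omitted
    effect_size: float = 2.0            # case-group mean shift, in within-group SDs
    n_samples_per_group: int = 10
    min_neighbors: int = 5              # indirect-target threshold used for the truth
    ppi_model: str = "erdos-renyi"      # or "barabasi-albert" (hub-rich)
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_diseases", "targets_per_mirna",
                     "planted_mirnas_per_disease", "n_samples_per_group",
                     "min_neighbors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("signature_noise_frac", "signature_dropout_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.planted_mirnas_per_disease > self.n_mirnas:
            raise ValueError("planted_mirnas_per_disease cannot exceed n_mirnas")
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna cannot exceed n_genes")
        if self.ppi_mean_degree < 0:
            raise ValueError("ppi_mean_degree must be >= 0")
        if self.ppi_model not in ("erdos-renyi", "barabasi-albert"):
            raise ValueError("ppi_model must be 'erdos-renyi' or 'barabasi-albert'")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def mirna_ids(self) -> list[str]:
        return [f"MIR-{j:03d}" for j in range(1, self.n_mirnas + 1)]

    def disease_ids(self) -> list[str]:
        return [f"D{k:02d}" for k in range(1, self.n_diseases + 1)]


@dataclass
class SynthTruth:
    planted: dict[str, set[str]]          # disease -> planted miRNA ids
    true_signatures: dict[str, set[str]]  # disease -> true signature genes


@dataclass
class SynthData:
    """Everything the pipeline consumes, plus the ground truth."""

    config: SynthConfig
    ppi: EdgeList
    direct_targets: EdgeList
    expression: dict[str, ExpressionMatrix]
    text: TextRelevanceTable
    gold: EdgeList
    truth: SynthTruth


def generate_networks(config: SynthConfig) -> tuple[EdgeList, EdgeList]:
    """PPI (undirected) and direct miRNA->gene target networks.

    PPI: Erdos-Renyi with edge probability ``mean_degree / (n - 1)`` by
    default; a Barabasi-Albert option produces hub-rich degree distributions,
    which interact strongly with the >=k-neighbor indirect rule.  Each miRNA
    draws ``targets_per_mirna`` genes uniformly without replacement.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    n = config.n_genes

    if config.ppi_mean_degree == 0:
        ppi = EdgeList(edges=frozenset(), directed=False)
    elif config.ppi_model == "erdos-renyi":
        p = min(config.ppi_mean_degree / (n - 1), 1.0)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < p
        pairs = [(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])]
        ppi = EdgeList.from_pairs(pairs, directed=False)
    else:
        import networkx as nx
        m = max(1, int(round(config.ppi_mean_degree / 2)))
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        pairs = [(genes[a], genes[b]) for a, b in g.edges()]
        ppi = EdgeList.from_pairs(pairs, directed=False)

    direct_pairs = []
    for mirna in config.mirna_ids():
        targets = rng.choice(n, size=config.targets_per_mirna, replace=False)
        direct_pairs.extend((mirna, genes[t]) for t in targets)
    direct = EdgeList.from_pairs(direct_pairs, directed=True)
    return ppi, direct


def _make_signature(
    rng: np.random.Generator,
    influenced: list[str],
    all_genes: list[str],
    config: SynthConfig,
) -> set[str]:
    """Thin the influenced-gene set by dropout, then replace a fraction with
    random off-target genes (noise)."""
    for attempt in range(10):
        keep_n = len(influenced) - int(round(config.signature_dropout_frac * len(influenced)))
        kept = set(rng.choice(influenced, size=keep_n, replace=False)) if keep_n else set()
        n_replace = int(round(config.signature_noise_frac * len(kept)))
        if n_replace:
            drop = rng.choice(sorted(kept), size=n_replace, replace=False)
            kept -= set(drop)
            pool = [g for g in all_genes if g not in kept]
            kept |= set(rng.choice(pool, size=n_replace, replace=False))
        if kept:
            return kept
        warnings.warn(f"empty signature after thinning (attempt {attempt + 1}); resampling")
    raise RuntimeError("could not draw a non-empty signature in 10 attempts")


def generate_disease_data(
    config: SynthConfig, networks: tuple[EdgeList, EdgeList]
) -> tuple[dict[str, ExpressionMatrix], TextRelevanceTable, EdgeList, SynthTruth]:
    """Per-disease expression matrices, text table, gold standard and truth.

    Per disease: ``planted_mirnas_per_disease`` miRNAs are drawn; the true
    signature is the thinned, polluted union of their direct and indirect
    targets; case samples shift signature-gene expression by +-effect_size
    (sign drawn per gene, fixed within the disease); the text table covers a
    seeded half of the signature (relevance ~ U(0.1, 1), citations ~
    11 + Poisson(20)) plus decoy records that fail the relevance/citation
    filters; the gold standard is exactly the planted pairs.
    """
    ppi, direct = networks
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = config.gene_ids()
    mirnas = config.mirna_ids()

    indirect = indirect_targets(ppi, direct, min_neighbors=config.min_neighbors)
    direct_by_mirna: dict[str, set[str]] = {m: set() for m in mirnas}
    for m, g in direct.edges:
        direct_by_mirna[m].add(g)
    indirect_by_mirna: dict[str, set[str]] = {m: set() for m in mirnas}
    for g, m in indirect:
        indirect_by_mirna[m].add(g)

    expression: dict[str, ExpressionMatrix] = {}
    records: list[TextRelevanceRecord] = []
    gold_pairs: list[tuple[str, str]] = []
    planted: dict[str, set[str]] = {}
    true_sigs: dict[str, set[str]] = {}

    n_per = config.n_samples_per_group
    for disease in config.disease_ids():
        chosen = rng.choice(mirnas, size=config.planted_mirnas_per_disease,
                            replace=False)
        planted[disease] = set(chosen)
        gold_pairs.extend((disease, m) for m in chosen)

        influenced = sorted(
            set().union(*(direct_by_mirna[m] | indirect_by_mirna[m] for m in chosen))
        )
        sig = _make_signature(rng, influenced, genes, config)
        true_sigs[disease] = sig

        values = rng.standard_normal((config.n_genes, 2 * n_per))
        signs = rng.choice([-1.0, 1.0], size=config.n_genes)
        sig_mask = np.array([g in sig for g in genes])
        values[sig_mask, n_per:] += config.effect_size * signs[sig_mask, None]
        expression[disease] = ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=[f"{disease}_S{i:02d}" for i in range(1, 2 * n_per + 1)],
            values=values,
            group_labels=[CONTROL] * n_per + [CASE] * n_per,
        )

        sig_sorted = sorted(sig)
        n_text = len(sig_sorted) // 2
        text_genes = rng.choice(sig_sorted, size=n_text, replace=False) if n_text else []
        for g in text_genes:
            records.append(TextRelevanceRecord(
                disease_id=disease, gene_id=g,
                relevance_score=float(rng.uniform(0.1, 1.0)),
                citation_count=int(11 + rng.poisson(20)),
            ))
        # decoys: random genes that must fail the relevance/citation filters
        decoys = rng.choice(genes, size=20, replace=False)
        for i, g in enumerate(decoys):
            if i % 2 == 0:
                rel, cit = 0.0, int(11 + rng.poisson(20))
            else:
                rel, cit = float(rng.uniform(0.1, 1.0)), int(rng.integers(0, 11))
            records.append(TextRelevanceRecord(
                disease_id=disease, gene_id=g, relevance_score=rel,
                citation_count=cit,
            ))

    gold = EdgeList.from_pairs(gold_pairs, directed=True)
    truth = SynthTruth(planted=planted, true_signatures=true_sigs)
    return expression, TextRelevanceTable(records=records), gold, truth


def generate_all(config: SynthConfig) -> SynthData:
    """Generate the full coupled input bundle from one master seed."""
    networks = generate_networks(config)
    expression, text, gold, truth = generate_disease_data(config, networks)
    return SynthData(
        config=config, ppi=networks[0], direct_targets=networks[1],
        expression=expression, text=text, gold=gold, truth=truth,
    )
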