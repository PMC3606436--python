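"""The miRNA-target influence matrix (genes x miRNAs).

A gene is a *direct* target of a miRNA when a sequence-based prediction links
them.  A gene is an *indirect* target when it is not itself targeted but at
least ``min_neighbors`` of its PPI neighbors are direct targets of that miRNA
-- the miRNA is then taken to influence the gene through its protein context.
The binary union of direct and indirect targets forms the predictor matrix of
the regression model.

Two readings of "not targeted" are supported: per-miRNA (the gene is not a
direct target of the focal miRNA; default, yields informative per-miRNA
columns) and any-miRNA (the gene is not a direct target of any miRNA).
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import EdgeList
from .signatures import DiseaseSignatureMatrix

__all__ = [
    "NetMiRMatrix",
    "indirect_targets",
    "build_netmir",
    "intersect_universe",
]

DIRECT = "direct"
INDIRECT = "indirect"


@dataclass
class NetMiRMatrix:
    """Binary genes x miRNAs influence matrix with per-entry provenance."""

    gene_ids: list[str]
    mirna_ids: list[str]
    values: np.ndarray
    provenance: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.mirna_ids)):
            raise ValueError("values shape must be genes x mirnas")
        if not set(np.unique(self.values)) <= {0.0, 1.0}:
            raise ValueError("NetMiR entries must be binary")
        if int(self.values.sum()) != len(self.provenance):
            raise ValueError("provenance must cover exactly the nonzero entries")

    def column(self, mirna_id: str) -> np.ndarray:
        return self.values[:, self.mirna_ids.index(mirna_id)]

    def targets_of(self, mirna_id: str) -> set[str]:
        col = self.column(mirna_id)
        return {g for g, v in zip(self.gene_ids, col) if v}


def _adjacency(ppi: EdgeList) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in ppi.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def direct_targets_by_mirna(direct: EdgeList) -> dict[str, set[str]]:
    """Group directed miRNA -> gene edges by miRNA."""
    if not direct.directed:
        raise ValueError("direct miRNA-target edges must be directed")
    by_mirna: dict[str, set[str]] = {}
    for mirna, gene in direct.edges:
        by_mirna.setdefault(mirna, set()).add(gene)
    return by_mirna


def indirect_targets(
    ppi: EdgeList,
    direct: EdgeList,
    min_neighbors: int = 5,
    any_mirna: bool = False,
) -> set[tuple[str, str]]:
    """(gene, miRNA) pairs influenced through the protein context.

    A pair (g, j) qualifies when g is not a direct target (of j, or of any
    miRNA when ``any_mirna``) and at least ``min_neighbors`` PPI neighbors of
    g are direct targets of j.
    """
    if ppi.directed:
        raise ValueError("PPI network must be undirected")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    adj = _adjacency(ppi)
    by_mirna = direct_targets_by_mirna(direct)
    targeted_by_any: set[str] = set().union(*by_mirna.values()) if by_mirna else set()

    out: set[tuple[str, str]] = set()
    for mirna, targets in by_mirna.items():
        # count, for every gene, how many of its neighbors j targets
        counts: Counter[str] = Counter()
        for t in targets:
            for n in adj.get(t, ()):
                counts[n] += 1
        excluded = targeted_by_any if any_mirna else targets
        for gene, c in counts.items():
            if c >= min_neighbors and gene not in excluded:
                out.add((gene, mirna))
    return out


def build_netmir(
    direct: EdgeList,
    indirect: set[tuple[str, str]],
    gene_universe: Iterable[str],
    mirna_universe: Iterable[str],
) -> NetMiRMatrix:
    """Binary union of direct and indirect targets within the given universes.

    Direct and indirect pairs are disjoint by construction of
    :func:`indirect_targets`; this is asserted.
    """
    genes = sorted(gene_universe) if isinstance(gene_universe, (set, frozenset)) else list(gene_universe)
    mirnas = sorted(mirna_universe) if isinstance(mirna_universe, (set, frozenset)) else list(mirna_universe)
    if not genes or not mirnas:
        raise ValueError("gene and miRNA universes must be non-empty")
    row_of = {g: i for i, g in enumerate(genes)}
    col_of = {m: j for j, m in enumerate(mirnas)}

    values = np.zeros((len(genes), len(mirnas)))
    provenance: dict[tuple[str, str], str] = {}
    for mirna, gene in direct.edges:
        if gene in row_of and mirna in col_of:
            values[row_of[gene], col_of[mirna]] = 1.0
            provenance[(gene, mirna)] = DIRECT
    for gene, mirna in indirect:
        if gene in row_of and mirna in col_of:
            assert provenance.get((gene, mirna)) != DIRECT, \
                "a pair cannot be both direct and indirect"
            values[row_of[gene], col_of[mirna]] = 1.0
            provenance[(gene, mirna)] = INDIRECT

    empty = [m for j, m in enumerate(mirnas) if values[:, j].sum() == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} miRNA(s) with zero targets in the gene universe "
            f"(e.g. {empty[:3]})",
            stacklevel=2,
        )
    return NetMiRMatrix(gene_ids=genes, mirna_ids=mirnas, values=values,
                        provenance=provenance)


def write_netmir(netmir: NetMiRMatrix, path) -> None:
    """Three-column TSV: gene, miRNA, provenance (direct|indirect)."""
    with open(path, "w") as fh:
        fh.write("gene\tmirna\tprovenance\n")
        for (g, m), prov in sorted(netmir.provenance.items()):
            fh.write(f"{g}\t{m}\t{prov}\n")


def read_netmir(path) -> NetMiRMatrix:
    direct_pairs: list[tuple[str, str]] = []
    indirect_pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene"):
            raise ValueError(f"{path}: expected header 'gene\\tmirna\\tprovenance'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            g, m, prov = parts
            if prov == DIRECT:
                direct_pairs.append((m, g))
            elif prov == INDIRECT:
                indirect_pairs.add((g, m))
            else:
                raise ValueError(f"{path}:{lineno}: unknown provenance {prov!r}")
    direct = EdgeList.from_pairs(direct_pairs, directed=True)
    genes = sorted({g for _, g in direct.edges} | {g for g, _ in indirect_pairs})
    mirnas = sorted({m for m, _ in direct.edges} | {m for _, m in indirect_pairs})
    return build_netmir(direct, indirect_pairs, genes, mirnas)


def intersect_universe(
    netmir: NetMiRMatrix, disease_matrix: DiseaseSignatureMatrix
) -> tuple[NetMiRMatrix, DiseaseSignatureMatrix]:
    """Restrict both matrices to their common gene set, in identical row order
    (order follows the NetMiR matrix)."""
    disease_genes = set(disease_matrix.gene_ids)
    common = [g for g in netmir.gene_ids if g in disease_genes]
    if not common:
        raise ValueError("gene universes of NetMiR and disease matrix are disjoint")

    nm_rows = [netmir.gene_ids.index(g) for g in common]
    dm_rows = [disease_matrix.gene_ids.index(g) for g in common]
    common_set = set(common)
    provenance = {
        (g, m): p for (g, m), p in netmir.provenance.items() if g in common_set
    }
    new_nm = NetMiRMatrix(
        gene_ids=common,
        mirna_ids=list(netmir.mirna_ids),
        values=netmir.values[nm_rows, :],
        provenance=provenance,
    )
    new_dm = DiseaseSignatureMatrix(
        gene_ids=common,
        disease_ids=list(disease_matrix.disease_ids),
        values=disease_matrix.values[dm_rows, :],
        signed=disease_matrix.signed,
    )
    return new_nm, new_dm
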