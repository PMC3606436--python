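"""Shared domain types and readers/writers for the tabular formats used
throughout the pipeline.

All gene, miRNA and disease identifiers are plain symbols.  Normalization is
deliberately minimal -- uppercase, whitespace-stripped -- and idempotent; no
alias resolution is attempted, so inputs must already use a consistent symbol
vocabulary.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("mirlassonet")

CONTROL = "control"
CASE = "case"
VALID_LABELS = frozenset({CONTROL, CASE})


def normalize_symbol(symbol: str) -> str:
    """Normalize an identifier: strip surrounding whitespace, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(x)) == normalize_symbol(x)``.
    """
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with a binary group design.

    Values are assumed to be already normalized (e.g. RMA); units are
    arbitrary.  Both groups must be non-empty before differential analysis.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in ExpressionMatrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label required per sample")
        bad = set(self.group_labels) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_control(self) -> int:
        return self.group_labels.count(CONTROL)

    @property
    def n_case(self) -> int:
        return self.group_labels.count(CASE)

    def require_two_groups(self) -> None:
        if self.n_control == 0 or self.n_case == 0:
            raise ValueError(
                "differential analysis requires non-empty control and case groups "
                f"(got {self.n_control} control / {self.n_case} case)"
            )


@dataclass(frozen=True)
class EdgeList:
    """A deduplicated edge set over normalized symbols.

    Undirected edges are stored canonically as lexicographically ordered
    pairs; self-loops are disallowed in undirected mode.
    """

    edges: frozenset[tuple[str, str]]
    directed: bool

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], directed: bool
    ) -> "EdgeList":
        edges: set[tuple[str, str]] = set()
        n_loops = 0
        for a, b in pairs:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if not directed:
                if a == b:
                    n_loops += 1
                    continue
                if b < a:
                    a, b = b, a
            edges.add((a, b))
        if n_loops:
            warnings.warn(
                f"dropped {n_loops} self-loop(s) from undirected edge list",
                stacklevel=2,
            )
        return cls(edges=frozenset(edges), directed=directed)

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def sources(self) -> set[str]:
        return {a for a, _ in self.edges}

    def targets(self) -> set[str]:
        return {b for _, b in self.edges}


@dataclass(frozen=True)
class TextRelevanceRecord:
    disease_id: str
    gene_id: str
    relevance_score: float
    citation_count: int

    def __post_init__(self) -> None:
        if self.relevance_score < 0:
            raise ValueError("relevance_score must be >= 0")
        if self.citation_count < 0:
            raise ValueError("citation_count must be >= 0")


@dataclass
class TextRelevanceTable:
    """Text-mining gene-disease relevance table (disease, gene, score, citations)."""

    records: list[TextRelevanceRecord]

    def diseases(self) -> set[str]:
        return {r.disease_id for r in self.records}

    def for_disease(self, disease_id: str) -> list[TextRelevanceRecord]:
        return [r for r in self.records if r.disease_id == disease_id]


SIGNATURE_SOURCES = ("expression", "text", "merged")


@dataclass
class GeneSignature:
    """Per-disease up/down gene sets with provenance.

    Text-derived signatures carry no direction, so all their genes live in
    ``up_genes``.  Under membership (unsigned) use, ``up_genes | down_genes``
    is the signature.
    """

    disease_id: str
    up_genes: set[str]
    down_genes: set[str]
    source: str

    def __post_init__(self) -> None:
        if self.source not in SIGNATURE_SOURCES:
            raise ValueError(f"unknown signature source {self.source!r}")
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"genes present in both up and down sets: {sorted(overlap)[:5]}"
            )
        if self.source == "text" and self.down_genes:
            raise ValueError("text signatures carry no direction; down_genes must be empty")

    @property
    def genes(self) -> set[str]:
        return self.up_genes | self.down_genes

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class Config:
    """Pipeline parameters.

    Defaults mirror the study conditions: top-100 up / top-100 down expression
    signatures, text filter (relevance strictly above 0, at least 11
    citations, i.e. strictly more than ten), indirect-target threshold of 5
    PPI neighbors, 10-fold CV over a 100-point log-spaced lambda path.
    """

    k_up: int = 100
    k_down: int = 100
    min_relevance: float = 0.0
    min_citations: int = 11
    min_neighbors: int = 5
    n_folds: int = 10
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 1e-3
    seed: int = 17
    keep_sign: str = "positive"
    # Open-ended choices exposed as configuration: predictors are standardized
    # before the Lasso fit by default, and the response encoding is binary
    # membership (signed three-level encoding available).
    standardize: bool = True
    signed_response: bool = False
    any_mirna_indirect: bool = False

    def __post_init__(self) -> None:
        for name in ("k_up", "k_down", "min_citations", "min_neighbors",
                     "n_folds", "lambda_grid_size"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_grid_size < 2:
            raise ValueError("lambda_grid_size must be >= 2")
        if not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.min_relevance < 0:
            raise ValueError("min_relevance must be >= 0")
        if self.keep_sign not in ("positive", "both"):
            raise ValueError("keep_sign must be 'positive' or 'both'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    labels: str | Path | Mapping[str, str],
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header of sample ids)
    plus a sample -> group-label assignment.

    ``labels`` is either a two-column TSV path (sample, label) or a mapping.
    Duplicate gene rows keep the first occurrence with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed expression TSV {path}: {exc}") from exc
    if df.isna().any().any():
        bad_rows = [i + 2 for i, flag in enumerate(df.isna().any(axis=1)) if flag]
        raise ValueError(
            f"malformed expression TSV {path}: missing values on line(s) {bad_rows[:5]}"
        )
    df.index = [normalize_symbol(str(g)) for g in df.index]
    dup = df.index.duplicated(keep="first")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicated gene row(s) in {path}; keeping first occurrence",
            stacklevel=2,
        )
        df = df[~dup]
    sample_ids = [str(s) for s in df.columns]

    if isinstance(labels, (str, Path)):
        lab_df = pd.read_csv(labels, sep="\t", header=None, names=["sample", "label"],
                             dtype=str)
        label_map = dict(zip(lab_df["sample"], lab_df["label"]))
    else:
        label_map = dict(labels)
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    group_labels = [label_map[s].strip().lower() for s in sample_ids]
    expr = ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=sample_ids,
        values=df.to_numpy(dtype=float),
        group_labels=group_labels,
    )
    expr.require_two_groups()
    return expr


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for s, g in zip(expr.sample_ids, expr.group_labels):
                fh.write(f"{s}\t{g}\n")


def read_edge_list(path: str | Path, directed: bool, header: bool = False) -> EdgeList:
    """Read a two-column TSV edge list (headerless by default)."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            pairs.append((parts[0], parts[1]))
    return EdgeList.from_pairs(pairs, directed=directed)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges.edges):
            fh.write(f"{a}\t{b}\n")


def read_relevance_table(path: str | Path, header: bool = False) -> TextRelevanceTable:
    """Read a four-column TSV: disease, gene, relevance score, citation count."""
    records: list[TextRelevanceRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            records.append(
                TextRelevanceRecord(
                    disease_id=normalize_symbol(parts[0]),
                    gene_id=normalize_symbol(parts[1]),
                    relevance_score=float(parts[2]),
                    citation_count=int(parts[3]),
                )
            )
    return TextRelevanceTable(records=records)


def write_relevance_table(table: TextRelevanceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in table.records:
            fh.write(f"{r.disease_id}\t{r.gene_id}\t{r.relevance_score}\t{r.citation_count}\n")


# -- GMT signatures ---------------------------------------------------------
# One line per gene set: "<disease>__up|down|text" TAB description TAB genes...
# The description field records the signature source so write/read round-trips.

_GMT_SUFFIXES = ("up", "down", "text")


def write_signatures_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    seen: set[str] = set()
    lines: list[str] = []
    for sig in signatures:
        suffix_sets = [("up", sig.up_genes), ("down", sig.down_genes)]
        if sig.source == "text":
            suffix_sets = [("text", sig.up_genes)]
        for suffix, genes in suffix_sets:
            if not genes:
                continue  # empty sets omitted; re-read yields empty set
            name = f"{sig.disease_id}__{suffix}"
            if name in seen:
                raise ValueError(f"duplicate gene-set name {name!r}")
            seen.add(name)
            lines.append("\t".join([name, sig.source, *sorted(genes)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_signatures_gmt(path: str | Path) -> list[GeneSignature]:
    ups: dict[str, set[str]] = {}
    downs: dict[str, set[str]] = {}
    sources: dict[str, str] = {}
    order: list[str] = []
    seen_names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
            name, description = parts[0], parts[1]
            genes = {normalize_symbol(g) for g in parts[2:] if g.strip()}
            if name in seen_names:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen_names.add(name)
            if "__" not in name:
                raise ValueError(f"{path}:{lineno}: set name {name!r} lacks __up/__down/__text suffix")
            disease_id, suffix = name.rsplit("__", 1)
            if suffix not in _GMT_SUFFIXES:
                raise ValueError(f"{path}:{lineno}: unknown suffix {suffix!r}")
            if disease_id not in sources:
                order.append(disease_id)
                sources[disease_id] = description
                ups[disease_id] = set()
                downs[disease_id] = set()
            if suffix == "down":
                downs[disease_id] |= genes
            else:
                ups[disease_id] |= genes
    out: list[GeneSignature] = []
    for disease_id in order:
        out.append(
            GeneSignature(
                disease_id=disease_id,
                up_genes=ups[disease_id],
                down_genes=downs[disease_id],
                source=sources[disease_id],
            )
        )
    return out


# -- association and report tables -----------------------------------------

def write_associations(edges: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tmirna\tscore\n")
        for d, m, s in edges:
            fh.write(f"{d}\t{m}\t{s:.10g}\n")


def read_associations(path: str | Path) -> list[tuple[str, str, float]]:
    out: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("disease"):
            raise ValueError(f"{path}: expected header 'disease\\tmirna\\tscore'")
        for line in fh:
            if not line.strip():
                continue
            d, m, s = line.rstrip("\n").split("\t")
            out.append((normalize_symbol(d), normalize_symbol(m), float(s)))
    return out


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
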