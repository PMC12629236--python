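"""Reading count tables, taxonomy, trees and metadata; closure and CLR.

Microbiome count data carry only relative information: a row of counts
``w_i`` is normalized (after adding a pseudo-count to clear zeros) to a
composition ``x_i`` on the simplex, then mapped by the centered log-ratio
(CLR) transform ``z_ij = log(x_ij / gmean(x_i))`` onto the zero-sum
hyperplane where ordinary linear modelling applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .tree_groups import TaxonomicTree

__all__ = [
    "CountTable",
    "CompositionMatrix",
    "ClrMatrix",
    "ResponseData",
    "close_counts",
    "clr_transform",
    "read_counts",
    "read_taxonomy",
    "read_newick",
    "read_metadata",
]

DEFAULT_PSEUDO_COUNT = 0.5
DEFAULT_RANK_COLUMNS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")


@dataclass
class CountTable:
    """Samples-by-taxa matrix of non-negative integer sequencing counts."""

    samples: list[str]
    taxa: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, p = self.counts.shape
        if len(self.samples) != n or len(self.taxa) != p:
            raise ValueError("counts shape does not match sample/taxon labels")
        if len(set(self.taxa)) != p:
            raise ValueError("taxon identifiers must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]


@dataclass
class CompositionMatrix:
    """Rows on the open simplex: strictly positive, summing to one."""

    values: np.ndarray
    pseudo_count: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0):
            raise ValueError("compositions must be strictly positive")
        if np.max(np.abs(v.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("composition rows must sum to 1")
        self.values = v


@dataclass
class ClrMatrix:
    """CLR-transformed compositions; every row sums to zero."""

    values: np.ndarray
    geometric_means: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.max(np.abs(v.sum(axis=1))) > 1e-8:
            raise ValueError("CLR rows must sum to 0")
        self.values = v
        if self.geometric_means is None:
            self.geometric_means = np.ones(v.shape[0])


@dataclass
class ResponseData:
    """Numeric response with optional unpenalized covariates."""

    y: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if np.any(~np.isfinite(self.y)):
            raise ValueError("response contains missing or non-finite values")
        if self.covariates is not None:
            c = np.asarray(self.covariates, dtype=float)
            if c.ndim == 1:
                c = c[:, None]
            if c.shape[0] != self.y.shape[0]:
                raise ValueError("covariate rows must match response length")
            if np.any(~np.isfinite(c)):
                raise ValueError("covariates contain missing or non-finite values")
            self.covariates = c


def close_counts(counts: CountTable, pseudo_count: float = DEFAULT_PSEUDO_COUNT) -> CompositionMatrix:
    """Normalize counts to compositions after adding a pseudo-count to every cell.

    ``x_ij = (w_ij + c) / sum_l (w_il + c)``.  The pseudo-count (default
    0.5) is added to all entries, not only zeros, so the map is smooth in
    the counts; it must be positive whenever any count is zero.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    w = counts.counts.astype(float)
    if pseudo_count == 0 and np.any(w == 0):
        raise ValueError("zero counts present: a positive pseudo_count is required")
    shifted = w + pseudo_count
    row_sums = shifted.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("a sample has zero total count and pseudo_count is 0")
    return CompositionMatrix(values=shifted / row_sums, pseudo_count=pseudo_count)


def clr_transform(X: CompositionMatrix) -> ClrMatrix:
    """Centered log-ratio: log of each proportion over its row geometric mean."""
    v = X.values
    bad = np.argwhere(v <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"non-positive composition at row {i}, column {j}")
    logv = np.log(v)
    log_gmean = logv.mean(axis=1, keepdims=True)
    z = logv - log_gmean
    return ClrMatrix(values=z, geometric_means=np.exp(log_gmean).ravel())


def read_counts(path, transpose: bool = False, sep: str | None = None) -> CountTable:
    """Read a TSV/CSV count table: header of taxon ids, first column sample ids.

    ``transpose=True`` accepts taxa-in-rows files.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    if transpose:
        df = df.T
    counts = df.to_numpy()
    if not np.all(np.isfinite(counts)):
        raise ValueError("count table contains missing values")
    if np.any(counts != np.round(counts)):
        raise ValueError("count table contains non-integer values")
    return CountTable(
        samples=[str(s) for s in df.index],
        taxa=[str(t) for t in df.columns],
        counts=counts.astype(np.int64),
    )


def taxonomy_to_tree(taxonomy: pd.DataFrame, taxa: list[str],
                     rank_columns: tuple[str, ...] = DEFAULT_RANK_COLUMNS) -> TaxonomicTree:
    """Build a tree from a lineage table (one row per leaf taxon).

    Rank columns are ordered coarse to fine.  Missing/blank labels create
    distinct placeholder nodes per parent (never merged across families).
    Leaves are ordered as in ``taxa`` (the count-table column order).
    """
    ranks = [c for c in rank_columns if c in taxonomy.columns]
    if not ranks:
        raise ValueError(f"none of the rank columns {rank_columns} found in taxonomy")
    missing = [t for t in taxa if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa present in counts but absent in taxonomy: {missing[:5]}")
    if taxonomy.index.has_duplicates:
        dup = taxonomy.index[taxonomy.index.duplicated()].tolist()
        raise ValueError(f"duplicate leaf ids in taxonomy: {dup[:5]}")

    internal: dict[str, set[int]] = {"<root>": set(range(len(taxa)))}
    depth: dict[str, int] = {"<root>": 0}
    for j, taxon in enumerate(taxa):
        row = taxonomy.loc[taxon]
        prefix_parts: list[str] = []
        for d, rank in enumerate(ranks, start=1):
            label = row[rank]
            if pd.isna(label) or str(label).strip() == "":
                label = "<unranked>"  # placeholder scoped by the lineage prefix
            prefix_parts.append(str(label))
            key = ";".join(prefix_parts)
            internal.setdefault(key, set()).add(j)
            depth[key] = d
    # singleton "internal" nodes (unary lineage tails) coincide with their
    # leaf and would only duplicate its L1 penalty; drop them
    nodes = {k: frozenset(v) for k, v in internal.items() if len(v) > 1}
    if not nodes:
        raise ValueError("taxonomy yields no multi-leaf internal nodes")
    return TaxonomicTree(leaves=list(taxa), internal_nodes=nodes,
                         ranks={k: depth[k] for k in nodes})


def read_taxonomy(path, taxa: list[str],
                  rank_columns: tuple[str, ...] = DEFAULT_RANK_COLUMNS,
                  sep: str | None = None) -> TaxonomicTree:
    """Read a TSV/CSV taxonomy table (first column = taxon id) into a tree."""
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    df.index = df.index.map(str)
    return taxonomy_to_tree(df, taxa, rank_columns)


def newick_to_tree(newick: str, taxa: list[str] | None = None) -> TaxonomicTree:
    """Parse a Newick string; internal clades become groups, branch lengths ignored."""
    t = dendropy.Tree.get(data=newick, schema="newick")
    labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    if taxa is None:
        taxa = sorted(labels)
    if set(labels) != set(taxa):
        raise ValueError(
            f"Newick leaves {sorted(labels)[:5]}... do not match taxon ids"
        )
    index = {name: i for i, name in enumerate(taxa)}
    internal: dict[str, frozenset[int]] = {}
    ranks: dict[str, int] = {}
    counter = 0
    for node in t.preorder_node_iter():
        if node.is_leaf():
            continue
        members = frozenset(index[lf.taxon.label] for lf in node.leaf_iter())
        if len(members) < 2:  # unary clade duplicates its leaf
            continue
        label = node.label or f"node{counter}"
        counter += 1
        while label in internal:
            label = f"{label}_{counter}"
        internal[label] = members
        d = 0
        par = node.parent_node
        while par is not None:
            d += 1
            par = par.parent_node
        ranks[label] = d
    return TaxonomicTree(leaves=list(taxa), internal_nodes=internal, ranks=ranks)


def read_newick(path, taxa: list[str] | None = None) -> TaxonomicTree:
    """Read a Newick tree file; leaf labels must match the count-table taxa."""
    with open(path) as fh:
        return newick_to_tree(fh.read(), taxa)


def read_metadata(path, samples: list[str], response: str,
                  covariates: list[str] | None = None,
                  sep: str | None = None) -> ResponseData:
    """Read sample metadata keyed by sample id; extract response and covariates."""
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    df.index = df.index.map(str)
    missing = [s for s in samples if s not in df.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    df = df.loc[samples]
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not in metadata")
    cov = None
    if covariates:
        absent = [c for c in covariates if c not in df.columns]
        if absent:
            raise ValueError(f"covariate columns missing: {absent}")
        cov = df[covariates].to_numpy(dtype=float)
    return ResponseData(
        y=df[response].to_numpy(dtype=float),
        covariates=cov,
        covariate_names=list(covariates) if covariates else None,
    )
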