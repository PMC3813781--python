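"""Count-matrix containers, TSV I/O, filtering and RPKM normalization.

The pipeline starts from a gene-level read-count matrix (genes x samples)
with a sample design of two conditions (control vs treated) measured at
four ages. Counts are normalized to RPKM (reads per kilobase of exon model
per million mapped reads); "million mapped reads" is taken as the column
sum of assigned gene counts, which is the only depth measure available
downstream of counting and is proportional to the mapped-read total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("control", "treated")
AGES = (1, 5, 10, 20)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_counts",
    "drop_zero_genes",
    "filter_low_counts",
    "compute_rpkm",
    "log2_transform",
    "log2fc_profiles",
]


class FormatError(ValueError):
    """Input tables are malformed or inconsistent with each other."""


class NormalizationError(ValueError):
    """Normalization is undefined for this input (e.g. empty sample)."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts with gene lengths and sample design.

    Attributes
    ----------
    counts : DataFrame, genes x samples, non-negative integers.
    lengths : Series of gene lengths in bp, index matching ``counts``.
    design : DataFrame indexed by sample_id with columns
        ``condition`` (control/treated), ``age_days``, ``replicate_index``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise FormatError("count columns do not match design sample ids")
        if not self.lengths.index.equals(self.counts.index):
            raise FormatError("gene-length index does not match count matrix")
        if (self.lengths <= 0).any():
            raise FormatError("gene lengths must be strictly positive")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            arr = self.counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        missing = {c for c in ("condition", "age_days", "replicate_index")} - set(
            self.design.columns
        )
        if missing:
            raise FormatError(f"design is missing columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples(self, condition: str | None = None, age: int | None = None) -> list[str]:
        """Sample ids for a (condition, age) cell; either filter may be None."""
        mask = pd.Series(True, index=self.design.index)
        if condition is not None:
            if condition not in CONDITIONS:
                raise ValueError(f"unknown condition {condition!r}")
            mask &= self.design["condition"] == condition
        if age is not None:
            mask &= self.design["age_days"] == age
        return list(self.design.index[mask])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        gene_ids = pd.Index(gene_ids)
        return CountMatrix(
            self.counts.loc[gene_ids], self.lengths.loc[gene_ids], self.design
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            self.counts[sample_ids], self.lengths, self.design.loc[sample_ids]
        )

    def write(self, count_path, meta_path, length_path) -> None:
        """Write count/metadata/length TSVs that round-trip through read_counts."""
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(count_path, sep="\t")
        meta = self.design.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")
        lengths = self.lengths.to_frame("length_bp")
        lengths.index.name = "gene_id"
        lengths.to_csv(length_path, sep="\t")


@dataclass
class ExpressionMatrix:
    """RPKM expression values (genes x samples), optionally log2-transformed."""

    values: pd.DataFrame
    design: pd.DataFrame
    is_log2: bool = False
    pseudocount: float = 1.0

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples(self, condition: str | None = None, age: int | None = None) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        if condition is not None:
            mask &= self.design["condition"] == condition
        if age is not None:
            mask &= self.design["age_days"] == age
        return list(self.design.index[mask])

    def condition_age_means(self, condition: str) -> pd.DataFrame:
        """Per-gene mean expression at each age for one condition (genes x ages)."""
        cols = {}
        for age in sorted(self.design["age_days"].unique()):
            cols[age] = self.values[self.samples(condition, age)].mean(axis=1)
        return pd.DataFrame(cols)


def read_counts(count_path, meta_path, length_path) -> CountMatrix:
    """Read count, metadata and gene-length TSVs into an aligned CountMatrix.

    The count TSV has gene ids in the first column and sample ids in the
    header; metadata has one row per sample (sample_id, condition, age_days,
    replicate_index); lengths are a two-column table (gene_id, length_bp).
    """
    for p in (count_path, meta_path, length_path):
        if not Path(p).exists():
            raise FormatError(f"input file not found: {p}")
    counts = pd.read_csv(count_path, sep="\t", index_col=0)
    counts.columns = counts.columns.rename("sample_id")
    counts.index = counts.index.rename("gene_id")
    design = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    lengths_df = pd.read_csv(length_path, sep="\t", index_col="gene_id")
    missing = set(counts.columns) - set(design.index)
    if missing:
        raise FormatError(f"samples missing from metadata: {sorted(missing)}")
    design = design.loc[counts.columns]
    missing_genes = set(counts.index) - set(lengths_df.index)
    if missing_genes:
        raise FormatError(
            f"{len(missing_genes)} genes missing from length table"
        )
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise FormatError("non-integer values in count matrix")
    counts = counts.round().astype(np.int64)
    lengths = lengths_df["length_bp"].loc[counts.index].astype(float)
    return CountMatrix(counts, lengths, design)


def drop_zero_genes(cm: CountMatrix, condition: str) -> CountMatrix:
    """Drop genes whose counts are zero in every sample of ``condition``.

    Mirrors the standard pre-filter of discarding genes that show only
    zero-valued read counts in the condition under study; the returned
    matrix keeps all samples but only the genes expressed in that condition.
    """
    cols = cm.samples(condition=condition)
    if not cols:
        raise ValueError(f"condition {condition!r} not present in design")
    keep = cm.counts[cols].sum(axis=1) > 0
    return cm.subset_genes(cm.gene_ids[keep])


def filter_low_counts(cm: CountMatrix, min_count: int = 100) -> CountMatrix:
    """Keep only genes with count >= min_count in *every* sample.

    A gene with a low count (< min_count) in even one sample is excluded;
    the default threshold of 100 reads is the conventional cutoff for
    exact-test differential expression on deep bulk libraries.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    keep = (cm.counts >= min_count).all(axis=1)
    return cm.subset_genes(cm.gene_ids[keep])


def compute_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """RPKM = 1e9 * count / (gene length in bp * total counts in sample)."""
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise NormalizationError(f"zero total counts in samples: {bad}")
    rpkm = 1e9 * cm.counts.div(totals, axis=1).div(cm.lengths, axis=0)
    return ExpressionMatrix(rpkm, cm.design, is_log2=False)


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(RPKM + pseudocount); idempotence is not checked, do not stack."""
    if expr.is_log2:
        raise ValueError("expression matrix is already log2-transformed")
    vals = np.log2(expr.values + pseudocount)
    return ExpressionMatrix(vals, expr.design, is_log2=True, pseudocount=pseudocount)


def log2fc_profiles(
    expr: ExpressionMatrix,
    gene_subset=None,
    eps: float = 1.0,
    cluster_rows: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-age log2 fold change of treated vs control mean RPKM.

    Returns a genes x ages DataFrame of
    ``log2((mean treated + eps) / (mean control + eps))``; positive values
    mean up-regulation under treatment. With ``cluster_rows`` the rows are
    reordered by average-linkage hierarchical clustering on Euclidean
    distance of the fold-change profiles (heatmap-style view).
    """
    if expr.is_log2:
        raise ValueError("log2fc_profiles expects linear-scale RPKM")
    if gene_subset is not None:
        gene_subset = pd.Index(gene_subset)
        present = gene_subset.intersection(expr.gene_ids)
        if len(present) == 0:
            raise ValueError("gene subset is disjoint from the expression matrix")
        values = expr.values.loc[present]
    else:
        values = expr.values
    sub = ExpressionMatrix(values, expr.design)
    mean_t = sub.condition_age_means("treated")
    mean_c = sub.condition_age_means("control")
    fc = np.log2((mean_t + eps) / (mean_c + eps))
    if cluster_rows and len(fc) > 2:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import pdist

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            order = leaves_list(average(pdist(fc.to_numpy())))
        fc = fc.iloc[order]
    return fc
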