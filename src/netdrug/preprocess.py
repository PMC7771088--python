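"""Gene/drug filtering, imputation and sample alignment.

The preprocessing protocol mirrors how cell-line screens are typically
cleaned before network analysis:

1. drop genes with low mean expression or low variance (quantile cutoffs);
2. mean-impute genes that are numeric in strictly more than 90% of the
   cell lines, drop the rest;
3. drop drugs whose single most frequent response value covers strictly
   more than 80% of the cell lines (assay saturation / inactive drugs);
4. align the two tables on their shared cell lines.

All fractions are configurable through :class:`~netdrug.containers.FilterConfig`.
Gene and drug order is never changed except by deletion, so every filter
is idempotent.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .containers import ExpressionMatrix, FilterConfig, ResponseTable

__all__ = ["filter_genes", "impute_or_drop", "filter_drugs", "align", "preprocess"]


class EmptyAfterFilterError(ValueError):
    """Raised when a filtering step removes every gene or drug."""


def filter_genes(x: ExpressionMatrix, cfg: FilterConfig | None = None) -> ExpressionMatrix:
    """Remove genes with low mean expression or low variance.

    Means and variances are computed over non-missing entries.  A gene is
    dropped if its mean falls strictly below the ``min_expression_quantile``
    quantile of all gene means, or its variance strictly below the
    ``min_variance_quantile`` quantile of all gene variances.  Quantiles of
    0 keep everything.
    """
    cfg = cfg or FilterConfig()
    if x.n_genes == 0:
        raise EmptyAfterFilterError("no genes in input")
    means = np.nanmean(x.values, axis=1)
    variances = np.nanvar(x.values, axis=1, ddof=1)
    keep = np.ones(x.n_genes, dtype=bool)
    if cfg.min_expression_quantile > 0:
        keep &= means >= np.quantile(means, cfg.min_expression_quantile)
    if cfg.min_variance_quantile > 0:
        keep &= variances >= np.quantile(variances, cfg.min_variance_quantile)
    if not keep.any():
        raise EmptyAfterFilterError("all genes removed by expression/variance filter")
    return x.subset_genes(keep)


def impute_or_drop(x: ExpressionMatrix, cfg: FilterConfig | None = None) -> ExpressionMatrix:
    """Mean-impute mostly-numeric genes, drop the rest.

    A gene observed in strictly more than ``gene_numeric_fraction`` of the
    samples has each missing entry replaced with its mean over the numeric
    entries; any other gene containing a missing value is removed.  The
    output contains no missing entries, and the mean of each retained gene
    over its originally-numeric entries is unchanged.
    """
    cfg = cfg or FilterConfig()
    numeric = ~np.isnan(x.values)
    frac = numeric.mean(axis=1)
    keep = frac > cfg.gene_numeric_fraction  # strict: "more than"
    if not keep.any():
        raise EmptyAfterFilterError("all genes removed by missing-value rule")
    out = x.subset_genes(keep)
    vals = out.values.copy()
    miss = np.isnan(vals)
    if miss.any():
        gene_means = np.nanmean(vals, axis=1)
        rows, cols = np.nonzero(miss)
        vals[rows, cols] = gene_means[rows]
    return ExpressionMatrix(vals, out.gene_ids, out.sample_ids)


def filter_drugs(y: ResponseTable, cfg: FilterConfig | None = None) -> ResponseTable:
    """Remove drugs dominated by a single repeated response value.

    The mode is counted by exact equality of the stored floats (the rule
    targets literally duplicated assay values, not near-ties).  A drug is
    dropped when its modal count exceeds ``drug_mode_fraction * n`` strictly.
    """
    cfg = cfg or FilterConfig()
    if y.n_drugs == 0:
        raise EmptyAfterFilterError("no drugs in input")
    n = y.n_samples
    keep = np.ones(y.n_drugs, dtype=bool)
    for i in range(y.n_drugs):
        row = y.values[i]
        counts = Counter(row[~np.isnan(row)].tolist())
        mode_count = max(counts.values()) if counts else 0
        if mode_count > cfg.drug_mode_fraction * n:
            keep[i] = False
    if not keep.any():
        raise EmptyAfterFilterError("all drugs removed by mode filter")
    return y.subset_drugs(keep)


def align(x: ExpressionMatrix, y: ResponseTable) -> tuple[ExpressionMatrix, ResponseTable]:
    """Restrict both tables to their shared samples, in the expression matrix's order.

    Samples present in only one table are dropped; an empty intersection is
    an error.  Response columns are permuted so that ``sample_ids`` match
    the expression matrix exactly, value-per-sample preserved.
    """
    shared = set(x.sample_ids) & set(y.sample_ids)
    if not shared:
        raise ValueError("expression and response tables share no samples")
    x_keep = [j for j, s in enumerate(x.sample_ids) if s in shared]
    x2 = x.subset_samples(np.array(x_keep))
    y_pos = {s: j for j, s in enumerate(y.sample_ids)}
    y2 = y.subset_samples(np.array([y_pos[s] for s in x2.sample_ids]))
    return x2, y2


def preprocess(
    x: ExpressionMatrix, y: ResponseTable, cfg: FilterConfig | None = None
) -> tuple[ExpressionMatrix, ResponseTable]:
    """Full pipeline: gene filter -> imputation -> drug filter -> alignment."""
    cfg = cfg or FilterConfig()
    x = filter_genes(x, cfg)
    x = impute_or_drop(x, cfg)
    y = filter_drugs(y, cfg)
    return align(x, y)
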