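"""Core data containers.

Two aligned tables drive everything in this package: a gene-by-sample
expression matrix and a drug-by-sample response table (AUC or ED50 per
cell line).  Both are thin, validated wrappers around a float ndarray
plus identifier lists, convertible to/from :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ResponseTable", "FilterConfig"]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``.  Missing entries (NaN) are allowed until
    preprocessing removes or imputes them.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Restrict to genes flagged in a boolean mask or index array, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            self.values[keep], [self.gene_ids[i] for i in keep], list(self.sample_ids)
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            self.values[:, keep], list(self.gene_ids), [self.sample_ids[j] for j in keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)))


@dataclass
class ResponseTable:
    """Drug x sample response values (AUC or ED50), one row per drug."""

    values: np.ndarray
    drug_ids: list[str]
    sample_ids: list[str]
    metric: str = "AUC"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[None, :]
        self.drug_ids = _check_ids(self.drug_ids, "drug")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.metric not in ("AUC", "ED50"):
            raise ValueError(f"metric must be AUC or ED50, got {self.metric!r}")
        d, n = self.values.shape
        if d != len(self.drug_ids) or n != len(self.sample_ids):
            raise ValueError("shape inconsistent with drug/sample ids")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def response(self, drug_id: str) -> np.ndarray:
        """Length-n response vector for one drug."""
        return self.values[self.drug_ids.index(drug_id)]

    def subset_drugs(self, keep: np.ndarray) -> "ResponseTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ResponseTable(
            self.values[keep], [self.drug_ids[i] for i in keep], list(self.sample_ids), self.metric
        )

    def subset_samples(self, keep: np.ndarray) -> "ResponseTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ResponseTable(
            self.values[:, keep], list(self.drug_ids), [self.sample_ids[j] for j in keep], self.metric
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric: str = "AUC") -> "ResponseTable":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)), metric)


@dataclass
class FilterConfig:
    """Thresholds for the preprocessing rules.

    min_expression_quantile / min_variance_quantile
        Genes whose mean expression or variance falls below these quantiles
        of the gene-wise distributions are dropped.  The filtering rule is
        stated without explicit cutoffs in the source protocol, so both are
        exposed as quantiles with 0.2 defaults.
    gene_numeric_fraction
        A gene must have numeric values for strictly more than this fraction
        of samples to be mean-imputed; otherwise it is dropped.
    drug_mode_fraction
        A drug whose single most frequent response value covers strictly
        more than this fraction of cell lines is dropped.
    """

    min_expression_quantile: float = 0.2
    min_variance_quantile: float = 0.2
    gene_numeric_fraction: float = 0.90
    drug_mode_fraction: float = 0.80

    def __post_init__(self) -> None:
        for name in (
            "min_expression_quantile",
            "min_variance_quantile",
            "gene_numeric_fraction",
            "drug_mode_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
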