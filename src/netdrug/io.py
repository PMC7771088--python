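"""Delimited-text readers and writers.

Matrix dialect: first column holds gene (or drug) identifiers, the header
row holds sample identifiers, and empty cells or ``NA`` mark missing
values.  TSV by default; the delimiter is sniffed from the extension
(``.csv`` -> comma).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ResponseTable

_NA = ["NA", "NaN", "nan", ""]


def _sep(path: str) -> str:
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_expression(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0, na_values=_NA, keep_default_na=False)
    return ExpressionMatrix.from_frame(df)


def write_expression(x: ExpressionMatrix, path: str) -> None:
    x.to_frame().to_csv(path, sep=_sep(path), na_rep="NA")


def read_response(path: str, metric: str = "AUC") -> ResponseTable:
    df = pd.read_csv(path, sep=_sep(path), index_col=0, na_values=_NA, keep_default_na=False)
    return ResponseTable.from_frame(df, metric=metric)


def write_response(y: ResponseTable, path: str) -> None:
    y.to_frame().to_csv(path, sep=_sep(path), na_rep="NA")


def write_edge_list(A: np.ndarray, gene_ids: list[str], path: str) -> None:
    """Export the upper triangle of an adjacency as (gene_i, gene_j, weight) TSV."""
    rows = []
    m = len(gene_ids)
    iu, ju = np.triu_indices(m, k=1)
    for i, j in zip(iu, ju):
        rows.append((gene_ids[i], gene_ids[j], A[i, j]))
    pd.DataFrame(rows, columns=["gene_i", "gene_j", "weight"]).to_csv(path, sep="\t", index=False)


def write_selection(result, path: str) -> None:
    """Write a SelectionResult as rank/gene_id/score/method TSV."""
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(result.selected_gene_ids) + 1),
            "gene_id": result.selected_gene_ids,
            "score": result.scores,
            "method": result.method,
        }
    )
    df.to_csv(path, sep="\t", index=False)
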