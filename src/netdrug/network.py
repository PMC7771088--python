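"""Gene co-expression network construction and its normalized operators.

The adjacency is the absolute Pearson correlation between gene expression
profiles, with a zero diagonal.  From it we derive the operators used
downstream:

* ``S = D^{-1/2} A D^{-1/2}`` — symmetric-normalized adjacency
  (``D`` = diagonal of row/column sums of ``A``);
* ``L = I - S`` — normalized graph Laplacian, the smoothing operator of
  the network-propagation objective;
* ``P = D~^{-1/2} A~ D~^{-1/2}`` with ``A~ = A + I`` — the self-loop
  renormalized operator of the graph-convolution propagation rule.

``D~`` is taken as the column sums of ``A~`` (not of ``A``): using the
degrees of the self-loop-free graph would divide by zero for isolated
genes and break the operator's unit spectral bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix

__all__ = ["CoexpressionNetwork", "build_adjacency", "normalize", "gcn_operator"]


@dataclass
class CoexpressionNetwork:
    """Adjacency plus lazily-filled normalized operators over a fixed gene set."""

    A: np.ndarray
    gene_ids: list[str]
    S: np.ndarray | None = None
    L: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        m = self.A.shape[0]
        if self.A.shape != (m, m):
            raise ValueError("adjacency must be square")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length must match adjacency size")
        if not np.allclose(self.A, self.A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if (self.A < -1e-12).any() or (self.A > 1 + 1e-12).any():
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]


def build_adjacency(
    x: ExpressionMatrix, sparsify_below: float | None = None
) -> CoexpressionNetwork:
    """Absolute-Pearson-correlation adjacency with zero diagonal.

    Parameters
    ----------
    x
        Fully numeric expression matrix; every gene must have nonzero
        variance (correlation is undefined for constant profiles).
    sparsify_below
        Optional threshold: entries with ``|r|`` strictly below it are set
        to zero.  Off by default — the network is kept dense.
    """
    if x.has_missing():
        raise ValueError("expression matrix contains missing values; preprocess first")
    sd = x.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [x.gene_ids[i] for i in dead[:5]]
        raise ValueError(f"zero-variance gene(s), correlation undefined: {names}")
    A = np.abs(np.corrcoef(x.values))
    np.fill_diagonal(A, 0.0)
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)  # symmetrize away rounding noise
    if sparsify_below is not None:
        A[A < sparsify_below] = 0.0
    return CoexpressionNetwork(A, list(x.gene_ids))


def normalize(net: CoexpressionNetwork) -> CoexpressionNetwork:
    """Fill S = D^{-1/2} A D^{-1/2} and L = I - S in place, returning the network.

    Every gene must have strictly positive degree (row sum of A); an
    isolated gene has no defined normalized row.
    """
    deg = net.A.sum(axis=1)
    isolated = np.flatnonzero(deg <= 0)
    if isolated.size:
        names = [net.gene_ids[i] for i in isolated[:5]]
        raise ValueError(f"isolated gene(s) with zero degree: {names}")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    S = net.A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    S = (S + S.T) / 2.0
    net.S = S
    net.L = np.eye(net.n_genes) - S
    return net


def gcn_operator(net: CoexpressionNetwork) -> np.ndarray:
    """Self-loop renormalized propagation operator D~^{-1/2} (A + I) D~^{-1/2}.

    Always well defined: adding the identity guarantees degrees >= 1.  The
    result is symmetric with eigenvalues in [-1, 1].
    """
    A_tilde = net.A + np.eye(net.n_genes)
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=0))
    P = A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return (P + P.T) / 2.0
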