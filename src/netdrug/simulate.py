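"""Synthetic expression / drug-response generator with modular co-expression.

Emulates the structure the network methods assume: genes fall into latent
single-factor modules.  Gene *i* of module *j* is

    x_i = sqrt(rho) * t_j + sqrt(1 - rho) * eps_i,      t_j, eps_i ~ N(0, 1)

so every within-module pair has population correlation exactly ``rho``.
Background genes are independent standard normals.  Each drug's response
is driven by one module's latent factor:

    y = effect_size * t_causal + N(0, noise_sd^2)

giving a signal-to-noise ratio (variance ratio) of
``(effect_size / noise_sd)^2``.  Per-gene means/scales are randomized so
the expression filter has something to act on; missing entries are
injected completely at random at ``missing_rate``.  Everything is driven
by one seed, and the returned truth record is sufficient to recompute any
planted parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, ResponseTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate"]


@dataclass
class SyntheticConfig:
    """Parameters of the modular-expression simulator.

    Defaults mirror the study conditions of the evaluation protocol:
    a panel of a few hundred cell lines, 200 genes of which five modules
    of 10 carry structure, within-module correlation 0.8, and a causal
    effect at signal-to-noise 5 (effect 1.0, noise sd 1/sqrt(5)).
    """

    n_samples: int = 500
    n_genes: int = 200
    n_modules: int = 5
    module_size: int = 10
    within_module_corr: float = 0.8
    causal_module: int | list[int] = 0
    effect_size: float = 1.0
    noise_sd: float = 1.0 / np.sqrt(5.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit: n_modules * module_size > n_genes")
        if not 0.0 <= self.within_module_corr < 1.0:
            raise ValueError("within_module_corr must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for cm in self.causal_modules:
            if not 0 <= cm < self.n_modules:
                raise ValueError(f"causal_module {cm} out of range")

    @property
    def causal_modules(self) -> list[int]:
        cm = self.causal_module
        return [cm] if isinstance(cm, int) else list(cm)

    @property
    def snr(self) -> float:
        """Signal-to-noise variance ratio of each drug response."""
        return (self.effect_size / self.noise_sd) ** 2


@dataclass
class SyntheticTruth:
    """Planted ground truth: module membership and causal genes per drug."""

    module_genes: dict[int, list[str]]
    causal_genes: dict[str, list[str]]  # drug id -> gene ids of its causal module
    latents: np.ndarray  # n_modules x n_samples factor scores
    config: SyntheticConfig


def generate(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, ResponseTable, SyntheticTruth]:
    """Draw one synthetic panel; deterministic for a fixed config seed."""
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.n_genes, cfg.n_samples
    rho = cfg.within_module_corr

    latents = rng.standard_normal((cfg.n_modules, n))
    X = rng.standard_normal((m, n))  # background + idiosyncratic noise
    module_genes: dict[int, list[str]] = {}
    gene_ids = [f"G{i:04d}" for i in range(m)]
    for j in range(cfg.n_modules):
        rows = range(j * cfg.module_size, (j + 1) * cfg.module_size)
        X[list(rows)] = np.sqrt(rho) * latents[j] + np.sqrt(1 - rho) * X[list(rows)]
        module_genes[j] = [gene_ids[i] for i in rows]

    # per-gene location/scale so mean- and variance-filters are exercised;
    # affine per gene, so correlations are untouched
    offsets = rng.uniform(4.0, 8.0, size=m)
    scales = rng.uniform(0.5, 2.0, size=m)
    X = X * scales[:, None] + offsets[:, None]

    if cfg.missing_rate > 0:
        mask = rng.random((m, n)) < cfg.missing_rate
        X = X.copy()
        X[mask] = np.nan

    sample_ids = [f"CL{j:04d}" for j in range(n)]
    expr = ExpressionMatrix(X, gene_ids, sample_ids)

    drug_ids = [f"D{k:02d}" for k in range(len(cfg.causal_modules))]
    Y = np.empty((len(drug_ids), n))
    causal: dict[str, list[str]] = {}
    for k, cm in enumerate(cfg.causal_modules):
        Y[k] = cfg.effect_size * latents[cm] + cfg.noise_sd * rng.standard_normal(n)
        causal[drug_ids[k]] = module_genes[cm]
    resp = ResponseTable(Y, drug_ids, sample_ids, metric="AUC")

    truth = SyntheticTruth(
        module_genes=module_genes, causal_genes=causal, latents=latents, config=cfg
    )
    return expr, resp, truth
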