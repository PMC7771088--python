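"""Randomized split-and-score benchmark protocol.

For each of ``n_repeats`` random 70/30 splits (train size = floor(0.7 n),
the same split reused by every method), and for each drug:

1. the co-expression network is built on the *training* samples only;
2. per-gene scores are computed on the training partition — plain
   absolute correlation ``c`` and network-propagated ``f`` — and each
   selector keeps its top-k genes;
3. every prediction method is fitted on the selected training features
   and scored on the held-out samples by Pearson correlation between
   predicted and true response.

Test labels never reach network construction, selection, or fitting, so
poisoning them cannot change a selected gene set or a fitted model.
Per-cell failures are recorded and the run continues.  Aggregates follow
the benchmark-table layout: one grand mean per method over all
(drug, repeat) cells, and per-drug means; paired significance between
methods uses a two-sided Wilcoxon signed-rank over matched cells (paired
t-test available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import BASELINE_DEFAULTS, BaselineSpec, fit_predict
from .containers import ExpressionMatrix, ResponseTable
from .embedding import EmbedTrainConfig, FCHeadConfig, predict_from_embeddings, train_embeddings
from .gnn import GNNConfig, train_gnn
from .network import CoexpressionNetwork, build_adjacency, normalize
from .selection import initial_scores, propagate, select_top_k

__all__ = [
    "SplitPlan",
    "EvalReport",
    "make_splits",
    "score",
    "run_benchmark",
    "compare_methods",
]

logger = logging.getLogger(__name__)

GRAPH_METHODS = ("gnn", "embed")
ALL_METHODS = (*BASELINE_DEFAULTS, *GRAPH_METHODS)


@dataclass
class SplitPlan:
    repeat_index: int
    train_sample_ids: list[str]
    test_sample_ids: list[str]
    seed: int

    def indices(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        pos = {s: j for j, s in enumerate(sample_ids)}
        return (
            np.array([pos[s] for s in self.train_sample_ids]),
            np.array([pos[s] for s in self.test_sample_ids]),
        )


def make_splits(
    sample_ids: list[str], n_repeats: int, base_seed: int, train_fraction: float = 0.7
) -> list[SplitPlan]:
    """Deterministic list of 70/30 partitions; train size = floor(fraction * n)."""
    n = len(sample_ids)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_train = int(np.floor(train_fraction * n))
    plans = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([base_seed, rep])
        perm = rng.permutation(n)
        plans.append(
            SplitPlan(
                repeat_index=rep,
                train_sample_ids=[sample_ids[j] for j in perm[:n_train]],
                test_sample_ids=[sample_ids[j] for j in perm[n_train:]],
                seed=base_seed,
            )
        )
    return plans


def score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson r between truth and prediction; NaN if either side is constant."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 3:
        raise ValueError("score needs two equal-length vectors of length >= 3")
    if np.std(y_true) == 0:
        raise ValueError("true responses are constant; correlation undefined")
    if np.std(y_pred) == 0:
        logger.warning("constant predictions: correlation undefined, cell excluded")
        return float("nan")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


@dataclass
class EvalReport:
    """Long-format per-cell results plus aggregation helpers."""

    cells: pd.DataFrame  # columns: drug, method, selector, repeat, r, error

    def grand_means(self) -> pd.DataFrame:
        """Mean r per (method, selector) over all defined (drug, repeat) cells."""
        ok = self.cells.dropna(subset=["r"])
        out = ok.groupby(["method", "selector"], sort=True)["r"].agg(["mean", "std", "count"])
        return out.rename(columns={"mean": "mean_r", "std": "sd_r", "count": "n_cells"})

    def per_drug_means(self) -> pd.DataFrame:
        """Drug x (method, selector) table of mean r over repeats."""
        ok = self.cells.dropna(subset=["r"])
        return ok.pivot_table(index="drug", columns=["method", "selector"], values="r")

    def n_undefined(self) -> int:
        return int(self.cells["r"].isna().sum())


def _selected_rows(x: ExpressionMatrix, gene_ids: list[str]) -> list[int]:
    pos = {g: i for i, g in enumerate(x.gene_ids)}
    return [pos[g] for g in gene_ids]


def run_benchmark(
    x: ExpressionMatrix,
    y: ResponseTable,
    methods: list[str] | None = None,
    selectors: list[str] | None = None,
    n_repeats: int = 50,
    k_features: int = 100,
    base_seed: int = 13,
    alpha: float = 0.5,
    gnn_cfg: GNNConfig | None = None,
    embed_cfg: EmbedTrainConfig | None = None,
    fc_cfg: FCHeadConfig | None = None,
) -> EvalReport:
    """Execute the full comparative protocol on aligned, preprocessed inputs."""
    methods = list(methods or ALL_METHODS)
    selectors = list(selectors or ("network", "correlation"))
    for mth in methods:
        if mth not in ALL_METHODS:
            raise ValueError(f"unknown method {mth!r}")
    for sel in selectors:
        if sel not in ("network", "correlation"):
            raise ValueError(f"unknown selector {sel!r}")
    if x.sample_ids != y.sample_ids:
        raise ValueError("inputs are not aligned; call netdrug.preprocess.align first")
    k = min(k_features, x.n_genes)
    plans = make_splits(x.sample_ids, n_repeats, base_seed)
    rows = []

    for plan in plans:
        train_idx, test_idx = plan.indices(x.sample_ids)
        x_train = x.subset_samples(train_idx)
        net = normalize(build_adjacency(x_train))  # training samples only
        E_rep = None
        if "embed" in methods:
            # unsupervised: depends on the repeat's training network only
            E_rep, _ = train_embeddings(x, net, embed_cfg or EmbedTrainConfig(seed=plan.repeat_index))
        for d, drug in enumerate(y.drug_ids):
            y_d = y.values[d]
            y_train = y_d[train_idx]
            y_test = y_d[test_idx]
            c = initial_scores(x_train, y_train)
            f = propagate(net, c, alpha=alpha).f
            selections = {
                "network": select_top_k(f, x.gene_ids, k, method="network"),
                "correlation": select_top_k(c, x.gene_ids, k, method="correlation"),
            }
            for mth in methods:
                if mth in GRAPH_METHODS:
                    sel_label = "network"
                    try:
                        r = _run_graph_method(
                            mth, x, y_d, net, selections["network"], train_idx, test_idx,
                            y_test, plan, gnn_cfg, fc_cfg, E_rep,
                        )
                        err = ""
                    except Exception as exc:  # noqa: BLE001 — per-cell isolation
                        logger.warning("cell (%s, %s, rep %d) failed: %s", drug, mth, plan.repeat_index, exc)
                        r, err = float("nan"), str(exc)
                    rows.append((drug, mth, sel_label, plan.repeat_index, r, err))
                    continue
                for sel in selectors:
                    rows_sel = _selected_rows(x, selections[sel].selected_gene_ids)
                    X_tr = x.values[np.ix_(rows_sel, train_idx)].T
                    X_te = x.values[np.ix_(rows_sel, test_idx)].T
                    try:
                        spec = BaselineSpec(mth, seed=plan.repeat_index)
                        preds = fit_predict(spec, X_tr, y_train, X_te)
                        r, err = score(y_test, preds), ""
                    except Exception as exc:  # noqa: BLE001
                        logger.warning("cell (%s, %s/%s, rep %d) failed: %s", drug, mth, sel, plan.repeat_index, exc)
                        r, err = float("nan"), str(exc)
                    rows.append((drug, mth, sel, plan.repeat_index, r, err))

    cells = pd.DataFrame(rows, columns=["drug", "method", "selector", "repeat", "r", "error"])
    return EvalReport(cells=cells)


def _run_graph_method(
    mth, x, y_d, net, selection, train_idx, test_idx, y_test, plan,
    gnn_cfg, fc_cfg, E_rep,
) -> float:
    if mth == "gnn":
        rows_sel = _selected_rows(x, selection.selected_gene_ids)
        x_sel = x.subset_genes(np.array(rows_sel))
        sub = CoexpressionNetwork(
            net.A[np.ix_(rows_sel, rows_sel)], selection.selected_gene_ids
        )
        cfg = gnn_cfg or GNNConfig(seed=plan.repeat_index)
        _, preds = train_gnn(x_sel, y_d, sub, cfg, train_idx, test_idx)
        return score(y_test, preds)
    # embedding: unsupervised reconstruction (precomputed per repeat);
    # supervised selection + head strictly on the training partition
    preds = predict_from_embeddings(
        E_rep, x, y_d, train_idx, test_idx,
        k_features=min(100, x.n_genes), fc_cfg=fc_cfg or FCHeadConfig(seed=plan.repeat_index),
    )
    return score(y_test, preds)


def compare_methods(
    report: EvalReport,
    pair: tuple[tuple[str, str], tuple[str, str]],
    test: str = "wilcoxon",
) -> tuple[float, float]:
    """Paired two-sided test between two (method, selector) arms.

    Matches cells on (drug, repeat); returns ``(p_value, direction)`` where
    direction is the mean score difference (first arm minus second).
    """
    (m1, s1), (m2, s2) = pair
    c = report.cells
    a = c[(c.method == m1) & (c.selector == s1)].set_index(["drug", "repeat"])["r"]
    b = c[(c.method == m2) & (c.selector == s2)].set_index(["drug", "repeat"])["r"]
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 2:
        raise ValueError("fewer than 2 paired cells in common")
    diff = a.to_numpy() - b.to_numpy()
    direction = float(diff.mean())
    if np.allclose(diff, 0):
        return 1.0, direction
    if test == "wilcoxon":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return p, direction
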