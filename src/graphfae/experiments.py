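"""Experiment drivers: masking protocols, cross-validation, and reports.

Two evaluation protocols hide expression values from the models:

* **Experiment-split masking** (protocol A): experiments (columns) are split
  into input and target sets and genes (rows) into train/test folds; one
  model per target column predicts the held-out genes' values.  The graph
  over all genes and the input columns of all genes stay visible — the task
  is transductive — but target values of test genes never enter a loss.
* **Imputation masking** (protocol B): entries of the matrix are hidden
  uniformly at random, the test mask is the logical complement of the train
  mask within the eligible-entry set, and a single auto-encoder model
  reconstructs everything from the surviving entries.

Both use K-fold cross-validation; results accumulate in an
:class:`ExperimentReport` (a thin frame of one row per method/fold/metric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .baselines import BaselineKind, MLPAutoEncoder, fit_baseline, \
    predict_baseline
from .core_data import (FeatureMatrix, Graph, MaskMode, MaskPair, masked_mse)
from .gae import (GaeConfig, correlation_edge_scores, decode_adjacency,
                  evaluate_link_prediction, identity_features,
                  indirect_predict, split_edges, train_gae,
                  variance_explained)
from .mpnn import GFAEImputer, GfaeConfig, build_gfae, predict_gfae, train_gfae
from .synthetic import erdos_renyi_graph

logger = logging.getLogger("graphfae")

__all__ = [
    "InputSetting", "ExperimentReport", "kfold_indices",
    "make_experiment_masks", "make_imputation_masks",
    "run_structure_embedding_experiment", "run_feature_prediction_experiment",
    "run_imputation_experiment",
]

END_TO_END_METHODS = ("gcn", "sage", "graphconv", "featgraphconv")
INDIRECT_METHODS = ("lr_embedding", "rf_embedding")
BASELINE_METHODS = ("mlp", "lr", "rf")


class InputSetting(Enum):
    RANDOM_GRAPH = "random-graph"
    EXPR_RANDOM_GRAPH = "expr-random"
    GRAPH = "graph"
    EXPR_GRAPH = "expr-graph"
    EXPRESSION = "expression"

    @classmethod
    def coerce(cls, value):
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(f"unknown input setting {value!r}; choose from "
                             f"{[s.value for s in cls]}") from None


@dataclass
class ExperimentReport:
    """Tidy result table: one row per (method/setting, fold, metric)."""

    frame: pd.DataFrame

    REQUIRED = ("method", "fold", "metric", "value", "seed")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"report frame missing columns {missing}")

    def summary(self) -> pd.DataFrame:
        """Mean ± sd of each metric across folds, per method."""
        g = self.frame.groupby(["method", "metric"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"std": "sd", "count": "n"})

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))

    def to_json(self, path):
        self.frame.to_json(path, orient="records", indent=2)


# ---------------------------------------------------------------------------
# Masking

def kfold_indices(n: int, k: int, seed: int):
    """k disjoint index sets partitioning [0, n), sizes differing by ≤ 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [test for _, test in splitter.split(np.zeros(n))]


def make_experiment_masks(n_genes: int, n_experiments: int, gene_folds,
                          target_experiments):
    """Protocol-A masks: one MaskPair per (fold, target experiment).

    Input features are the non-target columns of every gene; the target
    column's values are split into train genes (outside the fold) and test
    genes (the fold).
    """
    targets = tuple(int(q) for q in target_experiments)
    if not targets:
        raise ValueError("need at least one target experiment")
    if set(targets) >= set(range(n_experiments)):
        raise ValueError("all columns are targets; no input features remain")
    input_cols = tuple(q for q in range(n_experiments) if q not in targets)
    out = []
    for fold_idx, test_rows in enumerate(gene_folds):
        test_rows = np.asarray(test_rows, dtype=np.int64)
        train_rows = np.setdiff1d(np.arange(n_genes), test_rows)
        for q in targets:
            tr = np.zeros((n_genes, n_experiments))
            te = np.zeros((n_genes, n_experiments))
            tr[train_rows, q] = 1.0
            te[test_rows, q] = 1.0
            out.append(MaskPair(train_mask=tr, test_mask=te,
                                mode=MaskMode.EXPERIMENT_SPLIT,
                                input_columns=input_cols,
                                target_columns=(q,)))
    return out


def make_imputation_masks(x, k: int, seed: int, nonzero_only: bool = False):
    """Protocol-B masks: eligible entries partitioned into k folds; per fold
    the test mask is the fold and the train mask its complement within the
    eligible set.  With ``nonzero_only`` zero entries stay train-visible in
    every fold and never appear in a test mask."""
    values = x.values if isinstance(x, FeatureMatrix) else np.asarray(x)
    if k < 2:
        raise ValueError("k must be >= 2")
    eligible = (values != 0) if nonzero_only else np.ones(values.shape, bool)
    flat = np.flatnonzero(eligible)
    if flat.size < k:
        raise ValueError(f"only {flat.size} eligible entries for k={k}")
    rng = np.random.default_rng(int(seed))
    rng.shuffle(flat)
    folds = np.array_split(flat, k)
    always_train = np.zeros(values.shape)
    if nonzero_only:
        always_train[~eligible] = 1.0
    out = []
    for fold in folds:
        te = np.zeros(values.shape)
        te.flat[fold] = 1.0
        tr = np.zeros(values.shape)
        tr.flat[flat] = 1.0
        tr.flat[fold] = 0.0
        out.append(MaskPair(train_mask=np.maximum(tr, always_train),
                            test_mask=te, mode=MaskMode.IMPUTATION))
    return out


# ---------------------------------------------------------------------------
# Experiment 1: structure embedding (link prediction + variance explained)

def _matched_er_graph(g: Graph, seed: int) -> Graph:
    n = g.n_nodes
    p = 2.0 * g.n_edges / (n * (n - 1)) if n > 1 else 0.0
    return erdos_renyi_graph(n, p, seed)


def run_structure_embedding_experiment(setting, g: Graph, x, cfg: GaeConfig,
                                       seed: int, n_folds: int = 3,
                                       val_frac: float = 0.05,
                                       test_frac: float = 0.10
                                       ) -> ExperimentReport:
    """Link-prediction and variance-explained metrics for one input setting.

    Each fold is an independent edge split (and, for the random settings, an
    independent matched-density Erdős–Rényi graph).  The EXPRESSION setting
    needs no training: absolute coexpression scores the held-out pairs.
    """
    setting = InputSetting.coerce(setting)
    xv = x.values if isinstance(x, FeatureMatrix) else np.asarray(x)
    rows = []
    for fold in range(n_folds):
        fold_seed = int(seed) + 1000 * fold
        if setting in (InputSetting.RANDOM_GRAPH,
                       InputSetting.EXPR_RANDOM_GRAPH):
            input_graph = _matched_er_graph(g, fold_seed + 7)
        else:
            input_graph = g
        split = split_edges(input_graph, val_frac, test_frac, fold_seed)
        if setting is InputSetting.EXPRESSION:
            pos = correlation_edge_scores(xv, split.test_pos)
            neg = correlation_edge_scores(xv, split.test_neg)
            auc, ap = evaluate_link_prediction(pos, neg)
            r2 = float("nan")
        else:
            if setting in (InputSetting.RANDOM_GRAPH, InputSetting.GRAPH):
                feats = identity_features(input_graph.n_nodes)
            else:
                feats = xv
            cfg_fold = GaeConfig(epochs=cfg.epochs,
                                 learning_rate=cfg.learning_rate,
                                 hidden1=cfg.hidden1, hidden2=cfg.hidden2,
                                 dropout=cfg.dropout, seed=fold_seed)
            z, _, _ = train_gae(feats, input_graph, split, cfg_fold)
            auc, ap = evaluate_link_prediction(
                decode_adjacency(z, split.test_pos),
                decode_adjacency(z, split.test_neg))
            r2 = variance_explained(z, xv)
        for metric, value in (("auc", auc), ("ap", ap),
                              ("variance_explained", r2)):
            rows.append({"method": setting.value, "fold": fold,
                         "metric": metric, "value": value, "seed": seed})
    return ExperimentReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Experiment 2: feature prediction under protocol A

def run_feature_prediction_experiment(g: Graph, x: FeatureMatrix, methods,
                                      use_features: bool = True,
                                      gae_cfg: GaeConfig | None = None,
                                      gfae_cfg: GfaeConfig | None = None,
                                      k: int = 3, n_targets: int | None = None,
                                      seed: int = 0) -> ExperimentReport:
    """Predict held-out genes' values in target experiments (protocol A).

    End-to-end methods train one GFAE per (fold, target column); indirect
    methods train one GAE and regress targets from the embedding; feature
    baselines regress target values from input-column features and are
    skipped when ``use_features`` is false.
    """
    gae_cfg = gae_cfg or GaeConfig()
    gfae_cfg = gfae_cfg or GfaeConfig()
    xv = x.values
    n, q_all = xv.shape
    if q_all < 2:
        raise ValueError("need at least 2 experiments (1 input + 1 target)")
    rng = np.random.default_rng(int(seed))
    if n_targets is None:
        n_targets = max(1, round(0.1 * q_all))
    targets = sorted(rng.choice(q_all, size=min(n_targets, q_all - 1),
                                replace=False).tolist())
    folds = kfold_indices(n, k, seed)
    masks = make_experiment_masks(n, q_all, folds, targets)
    input_cols = masks[0].input_columns
    x_in = xv[:, list(input_cols)]
    model_input = x_in if use_features else identity_features(n)

    # Indirect route: the embedding is unsupervised, so train the GAE once.
    embeddings = {}
    if any(m in INDIRECT_METHODS for m in methods):
        z, _, _ = train_gae(model_input, g, None,
                            GaeConfig(epochs=gae_cfg.epochs,
                                      learning_rate=gae_cfg.learning_rate,
                                      hidden1=gae_cfg.hidden1,
                                      hidden2=gae_cfg.hidden2,
                                      dropout=gae_cfg.dropout,
                                      seed=int(seed)))
        embeddings["z"] = z

    rows = []
    for pair in masks:
        q = pair.target_columns[0]
        fold = next(i for i, f in enumerate(folds)
                    if np.array_equal(np.sort(f),
                                      np.flatnonzero(pair.test_mask[:, q])))
        train_rows = np.flatnonzero(pair.train_mask[:, q])
        test_rows = np.flatnonzero(pair.test_mask[:, q])
        y = xv[:, q]
        for method in methods:
            if method in END_TO_END_METHODS:
                net = build_gfae(method, model_input.shape[1], 1,
                                 int(seed) + 31 * fold + q,
                                 gfae_cfg.hidden1, gfae_cfg.hidden2)
                tr_mask = pair.train_mask[:, [q]]
                net, _ = train_gfae(net, model_input, y[:, None], tr_mask, g,
                                    gfae_cfg)
                pred = predict_gfae(net, model_input, g)[:, 0]
                mse = float(np.mean((pred[test_rows] - y[test_rows]) ** 2))
            elif method in INDIRECT_METHODS:
                reg = "LR" if method.startswith("lr") else "RF"
                pred = indirect_predict(embeddings["z"], y[train_rows],
                                        train_rows, test_rows, reg,
                                        seed=int(seed))
                mse = float(np.mean((pred - y[test_rows]) ** 2))
            elif method in BASELINE_METHODS:
                if not use_features:
                    logger.info("skipping baseline %s (no input features)",
                                method)
                    continue
                model = fit_baseline(BaselineKind.coerce(method),
                                     x_in[train_rows], y[train_rows],
                                     seed=int(seed))
                pred = predict_baseline(model, x_in[test_rows])
                mse = float(np.mean((pred - y[test_rows]) ** 2))
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({"method": method, "fold": fold, "target": q,
                         "metric": "mse", "value": mse, "seed": seed})
    return ExperimentReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Experiment 3: imputation under protocol B

def _column_mean_impute(values, train_mask):
    col_sum = (values * train_mask).sum(axis=0)
    col_cnt = train_mask.sum(axis=0)
    grand = (values * train_mask).sum() / max(train_mask.sum(), 1.0)
    means = np.where(col_cnt > 0, col_sum / np.maximum(col_cnt, 1.0), grand)
    return np.broadcast_to(means, values.shape).copy()


def run_imputation_experiment(g: Graph | None, x: FeatureMatrix, methods,
                              k: int = 10, cfg: GfaeConfig | None = None,
                              seed: int = 0, nonzero_only: bool = False,
                              folds_to_run=None) -> ExperimentReport:
    """Reconstruct randomly hidden entries (protocol B).

    Per fold a single model per method is trained on the train-visible
    entries (test entries zeroed on input) and scored by MSE on the hidden
    entries.  Methods: the four message-passing layers, ``mlp`` (dense
    auto-encoder) and ``mean`` (column-mean fill).
    """
    cfg = cfg or GfaeConfig()
    xv = x.values
    masks = make_imputation_masks(x, k, seed, nonzero_only=nonzero_only)
    if folds_to_run is not None:
        masks = [masks[i] for i in folds_to_run]
    rows = []
    for fold, pair in enumerate(masks):
        for method in methods:
            if method in END_TO_END_METHODS:
                est = GFAEImputer(layer=method, epochs=cfg.epochs,
                                  learning_rate=cfg.learning_rate,
                                  hidden1=cfg.hidden1, hidden2=cfg.hidden2,
                                  seed=int(seed) + fold)
                imputed = est.fit_transform(xv, graph=g,
                                            observed_mask=pair.train_mask)
            elif method == "mlp":
                est = MLPAutoEncoder(epochs=cfg.epochs,
                                     learning_rate=cfg.learning_rate,
                                     hidden1=cfg.hidden1,
                                     hidden2=cfg.hidden2,
                                     seed=int(seed) + fold)
                imputed = est.fit_transform(xv,
                                            observed_mask=pair.train_mask)
            elif method == "mean":
                imputed = _column_mean_impute(xv, pair.train_mask)
            else:
                raise ValueError(f"unknown imputation method {method!r}")
            mse = masked_mse(imputed, xv, pair.test_mask)
            rows.append({"method": method, "fold": fold, "metric": "mse",
                         "value": mse, "seed": seed})
    return ExperimentReport(pd.DataFrame(rows))
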