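"""Feature-only predictors that ignore the network.

Row-wise regressors (multilayer perceptron, ordinary least squares, random
forest) map a gene's observed experiment values to its held-out target
value; the MLP auto-encoder reconstructs a partially observed matrix with
dense layers under the same masked loss as the graph models, but with no
message passing.  An optional MAGIC shim invokes the published external
imputation tool as a subprocess and is never a reimplementation.
"""

from __future__ import annotations

import shutil
import subprocess
from enum import Enum

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor

from .mpnn import GFAEImputer

__all__ = ["BaselineKind", "fit_baseline", "predict_baseline",
           "MLPAutoEncoder", "run_magic"]


class BaselineKind(Enum):
    MLP = "mlp"
    LR = "lr"
    RF = "rf"

    @classmethod
    def coerce(cls, value):
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(f"unknown baseline {value!r}; choose from "
                             f"{[k.value for k in cls]}") from None


def fit_baseline(kind, features, targets, seed: int = 0, mlp_max_iter=2000):
    """Fit a feature-only regressor.

    MLP: two ReLU hidden layers (64, 32) trained to squared error by Adam;
    LR: ordinary least squares; RF: 100-tree forest.  All seeded.
    """
    kind = BaselineKind.coerce(kind)
    features = np.asarray(features, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if features.shape[0] != targets.shape[0]:
        raise ValueError("feature and target row counts differ")
    if kind is BaselineKind.MLP:
        model = MLPRegressor(hidden_layer_sizes=(64, 32), activation="relu",
                             solver="adam", learning_rate_init=0.001,
                             max_iter=mlp_max_iter, random_state=int(seed))
    elif kind is BaselineKind.LR:
        model = LinearRegression()
    else:
        model = RandomForestRegressor(n_estimators=100, random_state=int(seed))
    model.fit(features, targets)
    return model


def predict_baseline(model, features) -> np.ndarray:
    """Row-wise predictions from a fitted baseline (deterministic)."""
    features = np.asarray(features, dtype=np.float64)
    return np.asarray(model.predict(features), dtype=np.float64)


class MLPAutoEncoder(GFAEImputer):
    """Dense auto-encoder for imputation: identical training contract to the
    graph models (input = masked matrix, loss on observed entries) with
    message passing removed — the graph-free control."""

    def __init__(self, epochs=2000, learning_rate=0.001, hidden1=64,
                 hidden2=32, seed=0):
        super().__init__(layer="dense", epochs=epochs,
                         learning_rate=learning_rate, hidden1=hidden1,
                         hidden2=hidden2, seed=seed)

    def fit(self, X, y=None, *, observed_mask=None, graph=None):
        if graph is not None:
            raise ValueError("MLPAutoEncoder does not use a graph")
        return super().fit(X, y, graph=None, observed_mask=observed_mask)


def run_magic(input_tsv, output_tsv, executable="magic", extra_args=()):
    """Invoke the external MAGIC imputation tool on an expression TSV.

    Requires the published implementation on PATH; raises if absent.
    Disabled by default everywhere — provided only as an integration point.
    """
    exe = shutil.which(executable)
    if exe is None:
        raise RuntimeError(
            f"external tool {executable!r} not found on PATH; install the "
            "published MAGIC implementation to use this wrapper")
    cmd = [exe, str(input_tsv), "-o", str(output_tsv), *extra_args]
    subprocess.run(cmd, check=True)
    return output_tsv
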