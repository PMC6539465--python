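"""Extreme learning machine regression with sine activation.

A single-hidden-layer feed-forward network in which the input-to-hidden
weights ω and biases are drawn at random and *kept fixed*; only the linear
output layer is trained, by solving the least-squares problem

    H β ≈ y,   H = sin(Z ωᵀ + bias),

where Z is the standardized feature matrix.  β comes from an SVD-based
pseudoinverse, so the residual is orthogonal to the column space of H, and
with as many hidden neurons as (distinct) training rows the network
interpolates noiseless data exactly.

Randomness comes from numpy's default PCG64 generator seeded explicitly, so a
model is bit-reproducible from ``(X, y, n_hidden, seed)``.  Weights and biases
are drawn as one uniform[−1, 1] block of shape ``(n_hidden, n_features + 1)``:
the first ``n_hidden`` neurons of a larger model therefore coincide with a
smaller model drawn from the same seed, which makes neuron-count sweeps use
*nested* random bases (training R² is then non-decreasing in neuron count).

Features are standardized to zero mean / unit variance inside ``fit`` (the
scaling is stored on the model) so the sine arguments are well scaled
regardless of descriptor magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = ["ELMModel", "SweepResult", "fit_elm", "predict_elm",
           "sweep_neurons", "auto_sweep"]


def _as_matrix(X, feature_names: Sequence[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [n for n in feature_names if n not in X.columns]
            if missing:
                raise KeyError(f"rows are missing model features: {missing}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


@dataclass
class ELMModel:
    """A trained extreme learning machine.

    ``input_weights`` has shape (n_hidden, n_features); ``biases`` one offset
    per hidden neuron; ``output_weights`` one coefficient per hidden neuron
    (plus ``output_bias`` when configured).  ``x_mean``/``x_scale`` store the
    feature standardization so prediction is self-contained.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    output_weights: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    n_hidden: int
    seed: int
    output_bias: float | None = None
    feature_names: list[str] | None = None
    activation: str = "sine"

    def hidden(self, X) -> np.ndarray:
        """The hidden-layer matrix H = sin(Z·ωᵀ + bias) for standardized Z."""
        Z = (_as_matrix(X, self.feature_names) - self.x_mean) / self.x_scale
        return np.sin(Z @ self.input_weights.T + self.biases)

    def predict(self, X) -> np.ndarray:
        H = self.hidden(X)
        out = H @ self.output_weights
        if self.output_bias is not None:
            out = out + self.output_bias
        return out

    def to_dict(self) -> dict:
        return {
            "activation": self.activation,
            "n_hidden": self.n_hidden,
            "seed": self.seed,
            "input_weights": self.input_weights.tolist(),
            "biases": self.biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d) -> "ELMModel":
        return cls(
            input_weights=np.asarray(d["input_weights"], dtype=float),
            biases=np.asarray(d["biases"], dtype=float),
            output_weights=np.asarray(d["output_weights"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            n_hidden=int(d["n_hidden"]),
            seed=int(d["seed"]),
            output_bias=d.get("output_bias"),
            feature_names=d.get("feature_names"),
            activation=d.get("activation", "sine"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), ensure_ascii=False) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ELMModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_elm(X, y, n_hidden: int, seed: int, *,
            include_output_bias: bool = True,
            rcond: float = 1e-10, ridge: float = 0.0) -> ELMModel:
    """Train an ELM with ``n_hidden`` sine neurons.

    Input weights and biases are uniform[−1, 1] from PCG64(``seed``) and the
    output layer is the minimum-norm least-squares solution of ``H β ≈ y``
    (SVD pseudoinverse with cutoff ``rcond``; optional ridge penalty solves
    ``(HᵀH + ridge·I) β = Hᵀ y`` instead).  ``n_hidden ≥ n_samples`` is the
    interpolation regime and only warns.

    An output bias (a constant column appended to H) is included by default:
    activity targets have a large mean relative to their spread, and a
    bias-free random sine basis represents that constant offset poorly at
    moderate neuron counts.  Set ``include_output_bias=False`` for the
    strictly bias-free output layer.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, f = Xm.shape
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if n_hidden >= n:
        warnings.warn(
            f"n_hidden={n_hidden} >= n_samples={n}: interpolation regime",
            stacklevel=2)
    x_mean = Xm.mean(axis=0)
    x_scale = Xm.std(axis=0)
    x_scale[x_scale == 0.0] = 1.0

    rng = np.random.default_rng(seed)
    block = rng.uniform(-1.0, 1.0, size=(n_hidden, f + 1))
    W, b = block[:, :f], block[:, f]

    Z = (Xm - x_mean) / x_scale
    H = np.sin(Z @ W.T + b)
    if include_output_bias:
        H = np.column_stack([H, np.ones(n)])
    if ridge > 0.0:
        G = H.T @ H + ridge * np.eye(H.shape[1])
        beta = np.linalg.solve(G, H.T @ y)
    else:
        beta = np.linalg.pinv(H, rcond=rcond) @ y
    out_bias = float(beta[-1]) if include_output_bias else None
    out_w = beta[:n_hidden]
    return ELMModel(input_weights=W, biases=b, output_weights=out_w,
                    x_mean=x_mean, x_scale=x_scale, n_hidden=n_hidden,
                    seed=seed, output_bias=out_bias,
                    feature_names=feature_names)


def predict_elm(model: ELMModel, X) -> np.ndarray:
    """Functional alias for :meth:`ELMModel.predict`."""
    return model.predict(X)


@dataclass
class SweepResult:
    """Train/test quality versus hidden-neuron count.

    ``curve`` has one row per count with columns ``n_hidden``, ``train_r2``,
    ``train_aard_pct``, ``test_r2``, ``test_aard_pct``; ``best_n`` minimizes
    the test AARD% (ties go to the smaller network).
    """

    curve: pd.DataFrame
    best_n: int

    @property
    def counts(self) -> list[int]:
        return self.curve["n_hidden"].astype(int).tolist()


def sweep_neurons(X_train, y_train, X_test, y_test,
                  counts: Sequence[int], seed: int, *,
                  criterion: str = "test_aard_pct", **fit_kwargs) -> SweepResult:
    """Fit one ELM per neuron count and score it on train and test data.

    All fits share ``seed``; because weight blocks are drawn nested, the
    hidden bases grow by inclusion and training R² is non-decreasing in the
    count.  ``best_n`` is the count minimizing ``criterion`` (default: test
    AARD%, the overfitting-sensitive quantity; configurable to avoid
    endorsing test-set selection).
    """
    from .metrics import PredictionSet, aard_pct, r_squared

    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    rows = []
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for k in counts:
            model = fit_elm(X_train, y_train, n_hidden=int(k), seed=seed,
                            **fit_kwargs)
            pred_tr = model.predict(X_train)
            pred_te = model.predict(X_test)
            rows.append({
                "n_hidden": int(k),
                "train_r2": r_squared(PredictionSet(y_train, pred_tr, "train")),
                "train_aard_pct": aard_pct(PredictionSet(y_train, pred_tr, "train")),
                "test_r2": r_squared(PredictionSet(y_test, pred_te, "test")),
                "test_aard_pct": aard_pct(PredictionSet(y_test, pred_te, "test")),
            })
    curve = pd.DataFrame(rows)
    if criterion.endswith("r2"):
        best = curve.loc[curve[criterion].idxmax()]
    else:
        best = curve.loc[curve[criterion].idxmin()]
    return SweepResult(curve=curve, best_n=int(best["n_hidden"]))


def auto_sweep(X_train, y_train, X_test, y_test, seed: int, *,
               coarse: Sequence[int] = tuple(range(5, 101, 5)),
               refine_radius: int = 4, **kwargs) -> SweepResult:
    """Two-stage neuron sweep: a coarse grid, then ±``refine_radius`` around
    the coarse optimum.  Counts above the training-set size are dropped."""
    n = len(X_train)
    coarse = [k for k in coarse if 1 <= k <= n]
    if not coarse:
        coarse = [max(1, n // 2)]
    first = sweep_neurons(X_train, y_train, X_test, y_test, coarse, seed, **kwargs)
    fine = [k for k in range(first.best_n - refine_radius,
                             first.best_n + refine_radius + 1)
            if 1 <= k <= n]
    all_counts = sorted(set(coarse) | set(fine))
    return sweep_neurons(X_train, y_train, X_test, y_test, all_counts, seed,
                         **kwargs)
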