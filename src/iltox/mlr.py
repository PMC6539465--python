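"""Multiple linear regression with stepwise descriptor selection.

The linear QSAR model is

    logEC50 = P0 + Σ_i C_i · x_i

with intercept ``P0`` and one coefficient per selected descriptor.
Descriptors are chosen by classic stepwise selection: at each round the
candidate whose partial-F (equivalently squared-t) p-value is smallest enters
if it clears ``p_enter``, then any included term whose p-value has drifted
above ``p_remove`` is dropped.  The selection trace records R², adjusted R²
and the regression standard error after every move.

:func:`published_model` returns the reported 11-descriptor model for
ionic-liquid toxicity toward acetylcholinesterase (8 cation ESP terms, 3
cation σ terms, intercept 2.712), shipped as a JSON asset.

Coefficients are for *unstandardized* descriptors unless you standardize the
table yourself; this module never rescales features implicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as scipy_qr

from .descriptors import TARGET_COLUMN, feature_columns

__all__ = [
    "CollinearityError",
    "LinearModel",
    "StepwiseConfig",
    "fit_ols",
    "predict_linear",
    "stepwise_select",
    "published_model",
]

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """The design matrix is rank deficient; the message names the columns."""


@dataclass
class LinearModel:
    """An intercept plus named linear coefficients.

    ``terms`` is an ordered sequence of ``(descriptor name, coefficient)``
    pairs; ``t_values`` optionally carries the per-term t statistic
    (coefficient / standard error).  ``fit_meta`` holds n, p and fit-quality
    numbers when the model came from :func:`fit_ols`.
    """

    intercept: float
    terms: list[tuple[str, float]]
    t_values: dict[str, float] | None = None
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("term names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.terms]

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(self.terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def predict(self, rows: pd.DataFrame | pd.Series | Mapping[str, float]
                ) -> np.ndarray | float:
        """Evaluate ``P0 + Σ C_i·feature_i``; missing features are an error."""
        if isinstance(rows, Mapping) and not isinstance(rows, pd.Series):
            rows = pd.Series(rows)
        if isinstance(rows, pd.Series):
            return float(self.predict(rows.to_frame().T)[0])
        missing = [n for n in self.names if n not in rows.columns]
        if missing:
            raise KeyError(f"rows are missing model features: {missing}")
        X = rows[self.names].to_numpy(dtype=float)
        coefs = np.array([c for _, c in self.terms])
        return self.intercept + X @ coefs

    def to_dict(self) -> dict:
        out = {
            "intercept": self.intercept,
            "terms": [
                {"name": n, "coef": c,
                 **({"t": self.t_values[n]} if self.t_values and n in self.t_values else {})}
                for n, c in self.terms
            ],
            "meta": self.fit_meta,
        }
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearModel":
        terms = [(t["name"], float(t["coef"])) for t in d["terms"]]
        t_values = {t["name"]: float(t["t"]) for t in d["terms"] if "t" in t}
        return cls(intercept=float(d["intercept"]), terms=terms,
                   t_values=t_values or None, fit_meta=dict(d.get("meta", {})))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         ensure_ascii=False) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def predict_linear(model: LinearModel, rows) -> np.ndarray | float:
    """Functional alias for :meth:`LinearModel.predict`."""
    return model.predict(rows)


def _design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def fit_ols(X: pd.DataFrame, y: Sequence[float] | pd.Series) -> LinearModel:
    """Ordinary least squares of ``y`` on the columns of ``X`` plus intercept.

    Returns the coefficient vector minimizing the squared error, with per-term
    t statistics (coefficient / standard error).  ``fit_meta`` records n, p,
    R², adjusted R², the regression standard error sqrt(SSE/(n−p−1)), SSE and
    per-term p-values.  A rank-deficient design raises
    :class:`CollinearityError` naming the dependent columns.
    """
    y = np.asarray(y, dtype=float)
    n, p = len(X), X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    A = _design(X)
    # pivoted QR both detects rank deficiency and names the dependent columns
    _, R, piv = scipy_qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    dependent = piv[np.sum(diag > tol):]
    if dependent.size:
        names = ["intercept" if j == 0 else X.columns[j - 1] for j in sorted(dependent)]
        raise CollinearityError(f"design matrix is rank deficient; "
                                f"collinear columns: {names}")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    dof = n - p - 1
    sigma2 = sse / dof
    XtX_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    names = list(X.columns)
    return LinearModel(
        intercept=float(beta[0]),
        terms=list(zip(names, map(float, beta[1:]))),
        t_values=dict(zip(names, map(float, tvals[1:]))),
        fit_meta={
            "n": n, "p": p, "r2": r2, "r2_adj": r2_adj,
            "std_error": float(np.sqrt(sigma2)), "sse": sse,
            "p_values": dict(zip(names, map(float, pvals[1:]))),
            "intercept_t": float(tvals[0]),
        },
    )


@dataclass(frozen=True)
class StepwiseConfig:
    """Entry/removal significance thresholds and an optional size cap.

    ``p_enter`` must not exceed ``p_remove`` (otherwise a term could be added
    and immediately dropped forever).  For large candidate pools a
    Bonferroni-style ``p_enter`` (e.g. 0.05 / number of candidate tests) keeps
    chance descriptors out; the defaults are the classic 0.05 / 0.10.
    """

    p_enter: float = 0.05
    p_remove: float = 0.10
    max_terms: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_enter <= self.p_remove < 1.0):
            raise ValueError("need 0 < p_enter <= p_remove < 1")
        if self.max_terms is not None and self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")


def stepwise_select(table: pd.DataFrame,
                    config: StepwiseConfig = StepwiseConfig(),
                    target: str = TARGET_COLUMN,
                    candidates: Sequence[str] | None = None,
                    ) -> tuple[LinearModel, pd.DataFrame]:
    """Forward/backward stepwise descriptor selection on a descriptor table.

    Forward move: fit each absent candidate alongside the current terms and
    admit the one with the smallest p-value if it is below ``p_enter`` (ties
    broken by column order).  Backward move: drop the included term with the
    largest p-value above ``p_remove``.  Moves alternate until neither
    applies or ``max_terms`` is reached.  Zero-variance candidates are
    excluded up front with a logged list.

    Returns the final fitted model and a trace frame with one row per move
    (step, action, term, r2, r2_adj, std_error).  If nothing ever enters, the
    model is intercept-only and a warning is logged.
    """
    if candidates is None:
        candidates = feature_columns(table)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate descriptors")
    y = table[target].to_numpy(dtype=float)
    n = len(table)

    variances = table[list(candidates)].var(axis=0, ddof=0)
    degenerate = [c for c in candidates if variances[c] == 0.0]
    if degenerate:
        logger.info("excluding %d zero-variance candidates: %s",
                    len(degenerate), degenerate[:10])
    pool = [c for c in candidates if c not in set(degenerate)]

    selected: list[str] = []
    trace_rows: list[dict] = []
    step = 0

    def record(action: str, term: str, model: LinearModel | None) -> None:
        meta = model.fit_meta if model else {}
        trace_rows.append({
            "step": step, "action": action, "term": term,
            "n_terms": len(selected),
            "r2": meta.get("r2", 0.0),
            "r2_adj": meta.get("r2_adj", 0.0),
            "std_error": meta.get("std_error", float(np.std(y, ddof=1))),
        })

    current: LinearModel | None = None
    while True:
        moved = False
        # forward
        if (config.max_terms is None or len(selected) < config.max_terms) \
                and len(selected) + 2 < n:
            best_name, best_p, best_model = None, np.inf, None
            for cand in pool:
                if cand in selected:
                    continue
                try:
                    m = fit_ols(table[selected + [cand]], y)
                except CollinearityError:
                    continue
                pval = m.fit_meta["p_values"][cand]
                if pval < best_p:  # strict: ties keep the earlier column
                    best_name, best_p, best_model = cand, pval, m
            if best_name is not None and best_p < config.p_enter:
                selected.append(best_name)
                current = best_model
                step += 1
                record("add", best_name, current)
                moved = True
        # backward
        if selected:
            m = current if current is not None and current.names == selected \
                else fit_ols(table[selected], y)
            pvals = m.fit_meta["p_values"]
            worst = max(selected, key=lambda c: pvals[c])
            if pvals[worst] > config.p_remove:
                selected.remove(worst)
                current = fit_ols(table[selected], y) if selected else None
                step += 1
                record("remove", worst, current)
                moved = True
            else:
                current = m
        if not moved:
            break

    trace = pd.DataFrame(trace_rows,
                         columns=["step", "action", "term", "n_terms",
                                  "r2", "r2_adj", "std_error"])
    if not selected:
        logger.warning("stepwise selection admitted no descriptors; "
                       "returning intercept-only model")
        return LinearModel(intercept=float(y.mean()), terms=[],
                           fit_meta={"n": n, "p": 0}), trace
    return current, trace


def published_model() -> LinearModel:
    """The reported 11-descriptor MLR toxicity model, as printed.

    Eight cation ESP surface-area terms and three cation σ-profile terms with
    intercept 2.712; per-term t values included.  ``S_σ-C0.013`` (coefficient
    0.537, t = 18.957) is the most influential descriptor: ILs with more
    hydrogen-bond-acceptor surface area are less toxic toward the enzyme.
    """
    with resources.files("iltox.data").joinpath("published_model.json").open(
            "r", encoding="utf-8") as fh:
        return LinearModel.from_dict(json.load(fh))
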