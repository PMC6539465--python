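"""Model-quality statistics and external-validation criteria.

For a prediction set of experimental values y^exp and calculated values y^cal
(N_p points, mean experimental value ȳ_m):

* R²        = [Σ(y^exp−ȳ_m)² − Σ(y^cal−y^exp)²] / Σ(y^exp−ȳ_m)²  (≡ 1 − SSE/SST)
* R²_adj    = 1 − (1−R²)(N_p−1)/(N_p−p−1) for a p-predictor model
* AARD%     = 100 · Σ|(y^cal−y^exp)/y^exp| / N_p
* RMSE      = sqrt(Σ(y^cal−y^exp)² / N_p)
* ARD%      = |100·(y^cal/y^exp − 1)| per sample
* k  = Σ y^exp y^cal / Σ(y^cal)²  and  k′ = Σ y^exp y^cal / Σ(y^exp)²
  — the through-origin regression slopes between the two value sets
* R0², R0′² — squared correlation coefficients of the through-origin
  regressions (calculated-vs-experimental and the converse)

A model with acceptable external predictivity must satisfy the
Golbraikh–Tropsha criteria: R² > 0.7; (R²−R0²)/R² < 0.1 with 0.85 < k < 1.15;
(R²−R0′²)/R² < 0.1 with 0.85 < k′ < 1.15; and |R0²−R0′²| < 0.3.

Samples with |y^exp| below 1e-12 would divide by zero in AARD%/ARD% and are
excluded from those two statistics with a logged count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "MetricSet",
    "TropshaResult",
    "split_train_test",
    "r_squared",
    "adjusted_r_squared",
    "aard_pct",
    "rmse",
    "ard_pct",
    "slopes_and_r0",
    "tropsha_check",
    "ard_histogram",
    "compute_metrics",
    "validation_report",
    "ARD_BIN_LABELS",
]

logger = logging.getLogger(__name__)

_ZERO_GUARD = 1e-12

#: ARD% report ranges, half-open: [0,1), [1,5), [5,10), [10,∞) percent.
ARD_BIN_EDGES = (0.0, 1.0, 5.0, 10.0, np.inf)
ARD_BIN_LABELS = ("0-1%", "1-5%", "5-10%", ">=10%")


@dataclass
class PredictionSet:
    """Paired experimental/calculated activity values for one data subset."""

    y_exp: np.ndarray
    y_cal: np.ndarray
    label: str = "total"

    def __post_init__(self) -> None:
        self.y_exp = np.asarray(self.y_exp, dtype=float)
        self.y_cal = np.asarray(self.y_cal, dtype=float)
        if self.y_exp.shape != self.y_cal.shape or self.y_exp.ndim != 1:
            raise ValueError("y_exp and y_cal must be equal-length 1-D arrays")
        if self.n < 2:
            raise ValueError("a prediction set needs at least 2 points")

    @property
    def n(self) -> int:
        return int(self.y_exp.size)

    @property
    def y_bar_m(self) -> float:
        """Mean experimental activity, the reference for R²."""
        return float(self.y_exp.mean())


def split_train_test(samples: pd.DataFrame | Sequence, fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random partition into train/test, train size = ⌈fraction·n⌉.

    The two parts are disjoint and exhaustive; 160 samples at fraction 0.8
    give the conventional 128/32 split.  ``fraction = 1.0`` returns an empty
    test set with a warning.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    df = samples if isinstance(samples, pd.DataFrame) else pd.DataFrame(samples)
    n = len(df)
    n_train = int(np.ceil(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    train = df.iloc[np.sort(perm[:n_train])]
    test = df.iloc[np.sort(perm[n_train:])]
    if len(test) == 0:
        warnings.warn(f"fraction {fraction}: test set is empty", stacklevel=2)
    return train, test


def r_squared(ps: PredictionSet) -> float:
    """Squared correlation coefficient, 1 − SSE/SST about the experimental mean."""
    sst = float(((ps.y_exp - ps.y_bar_m) ** 2).sum())
    sse = float(((ps.y_cal - ps.y_exp) ** 2).sum())
    return (sst - sse) / sst


def adjusted_r_squared(r2: float, n_p: int, p: int) -> float:
    """R² penalized for model size p: 1 − (1−R²)(N_p−1)/(N_p−p−1)."""
    if n_p - p - 1 <= 0:
        raise ValueError("need N_p > p + 1")
    return 1.0 - (1.0 - r2) * (n_p - 1) / (n_p - p - 1)


def _nonzero_exp(ps: PredictionSet) -> tuple[np.ndarray, np.ndarray]:
    keep = np.abs(ps.y_exp) >= _ZERO_GUARD
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: excluded %d sample(s) with |y_exp| < %g from "
                    "relative-deviation statistics", ps.label, dropped, _ZERO_GUARD)
    return ps.y_exp[keep], ps.y_cal[keep]


def aard_pct(ps: PredictionSet) -> float:
    """Average absolute relative deviation in percent."""
    y_exp, y_cal = _nonzero_exp(ps)
    return float(100.0 * np.abs((y_cal - y_exp) / y_exp).mean())


def rmse(ps: PredictionSet) -> float:
    """Root-mean-square error of calculated vs experimental values."""
    return float(np.sqrt(((ps.y_cal - ps.y_exp) ** 2).mean()))


def ard_pct(y_cal: Sequence[float] | float, y_exp: Sequence[float] | float
            ) -> np.ndarray | float:
    """Per-sample absolute relative deviation |100·(y_cal/y_exp − 1)|."""
    y_cal = np.asarray(y_cal, dtype=float)
    y_exp = np.asarray(y_exp, dtype=float)
    out = np.abs(100.0 * (y_cal / y_exp - 1.0))
    return float(out) if out.ndim == 0 else out


def slopes_and_r0(ps: PredictionSet,
                  mode: Literal["standard", "as_printed"] = "standard"
                  ) -> tuple[float, float, float, float]:
    """Through-origin slopes and correlations for external validation.

    Returns ``(k, k_prime, r0_sq, r0_prime_sq)`` with
    k = Σ y^exp y^cal / Σ(y^cal)² and k′ = Σ y^exp y^cal / Σ(y^exp)².

    ``mode="standard"`` computes R0² and R0′² in the usual
    Golbraikh–Tropsha way: R0² is the squared correlation of the
    through-origin regression predicting y^cal from y^exp (residuals about
    the line ŷ^cal = k′·y^exp, variance about the mean of y^cal), and R0′²
    the converse (ŷ^exp = k·y^cal).  ``mode="as_printed"`` instead evaluates
    the commonly reprinted closed forms literally, in which the numerator
    scales the *same* variable by the slope — e.g.
    R0² = 1 − Σ(y^cal − k·y^cal)²/Σ(y^cal − ȳ^cal)² — which collapses to a
    function of k alone; it is provided for comparison with sources that
    print those forms.
    """
    e, c = ps.y_exp, ps.y_cal
    sec = float((e * c).sum())
    k = sec / float((c * c).sum())
    k_prime = sec / float((e * e).sum())
    if mode == "standard":
        r0 = 1.0 - float(((c - k_prime * e) ** 2).sum()) / \
            float(((c - c.mean()) ** 2).sum())
        r0p = 1.0 - float(((e - k * c) ** 2).sum()) / \
            float(((e - e.mean()) ** 2).sum())
    elif mode == "as_printed":
        r0 = 1.0 - float(((c - k * c) ** 2).sum()) / \
            float(((c - c.mean()) ** 2).sum())
        r0p = 1.0 - float(((e - k * e) ** 2).sum()) / \
            float(((e - k_prime * e.mean()) ** 2).sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return k, k_prime, r0, r0p


@dataclass
class MetricSet:
    """The full statistic suite for one prediction set."""

    label: str
    n: int
    p: int
    r2: float
    r2_adjusted: float
    aard_pct: float
    rmse: float
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    y_bar_m: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "label", "n", "p", "r2", "r2_adjusted", "aard_pct", "rmse",
            "k", "k_prime", "r0_sq", "r0_prime_sq", "y_bar_m")}


def compute_metrics(ps: PredictionSet, p: int = 0,
                    mode: Literal["standard", "as_printed"] = "standard"
                    ) -> MetricSet:
    """Evaluate every statistic of the suite on one prediction set.

    ``p`` is the predictor count used by adjusted R².
    """
    r2 = r_squared(ps)
    k, kp, r0, r0p = slopes_and_r0(ps, mode=mode)
    # adjusted R² is undefined when the set has <= p + 1 points (e.g. a small
    # test set scored against a many-neuron model); report NaN there
    r2_adj = adjusted_r_squared(r2, ps.n, p) if ps.n > p + 1 else float("nan")
    return MetricSet(
        label=ps.label, n=ps.n, p=p, r2=r2,
        r2_adjusted=r2_adj,
        aard_pct=aard_pct(ps), rmse=rmse(ps),
        k=k, k_prime=kp, r0_sq=r0, r0_prime_sq=r0p,
        y_bar_m=ps.y_bar_m,
    )


@dataclass
class TropshaResult:
    """Outcome of the four external-validation criteria.

    ``passes`` maps criterion names to booleans; ``overall`` is true exactly
    when all four hold.  ``quantities`` carries the computed left-hand sides.
    """

    passes: dict[str, bool]
    quantities: dict[str, float]

    @property
    def overall(self) -> bool:
        return all(self.passes.values())

    def to_dict(self) -> dict:
        return {"passes": self.passes, "quantities": self.quantities,
                "overall": self.overall}


def tropsha_check(r2: float, k: float, k_prime: float,
                  r0_sq: float, r0_prime_sq: float) -> TropshaResult:
    """Apply the Golbraikh–Tropsha external-validation criteria.

    (i) R² > 0.7; (ii) (R²−R0²)/R² < 0.1 and 0.85 < k < 1.15;
    (iii) (R²−R0′²)/R² < 0.1 and 0.85 < k′ < 1.15; (iv) |R0²−R0′²| < 0.3.
    """
    q = {
        "r2": r2,
        "(r2-r0_sq)/r2": (r2 - r0_sq) / r2,
        "(r2-r0_prime_sq)/r2": (r2 - r0_prime_sq) / r2,
        "|r0_sq-r0_prime_sq|": abs(r0_sq - r0_prime_sq),
        "k": k,
        "k_prime": k_prime,
    }
    passes = {
        "r2_above_0.7": r2 > 0.7,
        "origin_fit_cal_vs_exp": q["(r2-r0_sq)/r2"] < 0.1 and 0.85 < k < 1.15,
        "origin_fit_exp_vs_cal": q["(r2-r0_prime_sq)/r2"] < 0.1 and 0.85 < k_prime < 1.15,
        "origin_correlations_close": q["|r0_sq-r0_prime_sq|"] < 0.3,
    }
    return TropshaResult(passes=passes, quantities=q)


def ard_histogram(ps: PredictionSet) -> pd.DataFrame:
    """Distribution of per-sample ARD% over the four conventional ranges.

    Ranges are half-open: [0,1), [1,5), [5,10), [10,∞) percent.  Percentages
    (of the samples with non-zero experimental value) are rounded to two
    decimals and sum to 100 up to rounding.
    """
    y_exp, y_cal = _nonzero_exp(ps)
    ards = ard_pct(y_cal, y_exp)
    counts = [int(((ards >= lo) & (ards < hi)).sum())
              for lo, hi in zip(ARD_BIN_EDGES[:-1], ARD_BIN_EDGES[1:])]
    total = max(sum(counts), 1)
    return pd.DataFrame({
        "range": list(ARD_BIN_LABELS),
        "count": counts,
        "percent": [round(100.0 * c / total, 2) for c in counts],
    })


def validation_report(model, train: pd.DataFrame, test: pd.DataFrame,
                      target: str = "logEC50", p: int | None = None) -> dict:
    """Full train/test/total evaluation of any model with ``.predict``.

    Produces the metric suite for the training set, the test set and their
    union, the external-validation criteria on the test set, and the ARD%
    histogram over all samples, as one JSON-ready dictionary.  ``p`` (the
    predictor count for adjusted R²) defaults to the model's term/neuron
    count when discoverable.
    """
    if p is None:
        p = getattr(model, "n_terms", None) or getattr(model, "n_hidden", 0)
    sets = {}
    preds = {}
    for label, frame in (("train", train), ("test", test)):
        y_exp = frame[target].to_numpy(dtype=float)
        y_cal = np.asarray(model.predict(frame), dtype=float)
        preds[label] = (y_exp, y_cal)
        sets[label] = PredictionSet(y_exp, y_cal, label)
    total_exp = np.concatenate([preds["train"][0], preds["test"][0]])
    total_cal = np.concatenate([preds["train"][1], preds["test"][1]])
    sets["total"] = PredictionSet(total_exp, total_cal, "total")

    metrics = {lab: compute_metrics(ps, p=p).to_dict()
               for lab, ps in sets.items()}
    m_test = metrics["test"]
    tropsha = tropsha_check(m_test["r2"], m_test["k"], m_test["k_prime"],
                            m_test["r0_sq"], m_test["r0_prime_sq"])
    return {
        "schema": "iltox.validation_report/1",
        "n": {lab: sets[lab].n for lab in sets},
        "metrics": metrics,
        "tropsha_test": tropsha.to_dict(),
        "ard_histogram_total": ard_histogram(sets["total"]).to_dict("records"),
    }
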