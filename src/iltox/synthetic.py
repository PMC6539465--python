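"""Seeded generators for surfaces, ESP point sets and QSAR benchmark tables.

Every generator records its own ground truth so downstream code can be tested
end to end without quantum-chemistry outputs:

* :func:`gen_surface` — a COSMO-like segment set whose σ values come from a
  three-component Gaussian mixture (hydrogen-bond donor / non-polar /
  acceptor mass is controllable); the truth records per-region area.
* :func:`gen_esp_surface` — an ESP point set on the cation ([0, 150) kcal/mol)
  or anion ([−150, 0)) range; the truth records per-bin area computed by an
  independent linear scan.
* :func:`gen_qsar_dataset` — a descriptor table whose activity is an exact
  linear model plus Gaussian noise; the true model is returned for recovery
  assertions.  The default mirrors the reference study's shape: 160 ionic
  liquids, 11 informative descriptors carrying the published coefficients
  (intercept 2.712), the remaining 709 grid descriptors as decoys.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), so
every generator is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import TARGET_COLUMN, classify_sigma_region, descriptor_names
from .mlr import LinearModel, published_model
from .surfaces import ESPSurfacePoints, SurfaceSegmentSet

__all__ = [
    "SurfaceGenSpec",
    "ESPGenSpec",
    "QSARGenSpec",
    "gen_surface",
    "gen_esp_surface",
    "gen_qsar_dataset",
]


@dataclass(frozen=True)
class SurfaceGenSpec:
    """Recipe for a synthetic COSMO-style segment set.

    σ values are drawn from a Gaussian mixture whose three components emulate
    the hydrogen-bond donor, non-polar and acceptor surface mass of an ion.
    Segment areas Dirichlet-partition ``total_area`` so they are positive and
    sum exactly to it.  The defaults give a mid-polarity ion of realistic
    size (~300 Å²) with most mass in the non-polar band.
    """

    n_segments: int = 500
    total_area: float = 300.0
    mixture_means: tuple[float, ...] = (-0.012, 0.0, 0.012)
    mixture_sds: tuple[float, ...] = (0.004, 0.004, 0.004)
    mixture_weights: tuple[float, ...] = (0.2, 0.6, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.total_area <= 0:
            raise ValueError("need n_segments >= 1 and total_area > 0")
        if not (len(self.mixture_means) == len(self.mixture_sds)
                == len(self.mixture_weights)):
            raise ValueError("mixture parameter tuples must share a length")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def gen_surface(spec: SurfaceGenSpec, ion_id: str = "synthetic-ion"
                ) -> tuple[SurfaceSegmentSet, dict]:
    """Draw a segment set and record its ground truth.

    The truth dictionary holds the exact total area, the area mass per σ
    region (classified segment-wise, not bin-wise) and the mixture component
    of every segment.
    """
    rng = np.random.default_rng(spec.seed)
    areas = rng.dirichlet(np.ones(spec.n_segments)) * spec.total_area
    comp = rng.choice(len(spec.mixture_weights), size=spec.n_segments,
                      p=np.asarray(spec.mixture_weights))
    sigmas = rng.normal(np.asarray(spec.mixture_means)[comp],
                        np.asarray(spec.mixture_sds)[comp])
    surface = SurfaceSegmentSet(ion_id=ion_id, areas=areas, sigmas=sigmas)
    region_mass = {"HB_donor": 0.0, "non_polar": 0.0, "HB_acceptor": 0.0}
    for a, s in zip(areas, sigmas):
        region_mass[classify_sigma_region(float(s))] += float(a)
    truth = {
        "total_area": float(spec.total_area),
        "region_mass": region_mass,
        "components": comp.tolist(),
    }
    return surface, truth


@dataclass(frozen=True)
class ESPGenSpec:
    """Recipe for a synthetic ESP point set.

    Points are drawn uniformly over the role's ESP range (cation [0, 150),
    anion [−150, 0) kcal/mol); areas Dirichlet-partition ``total_area``.
    ``bin_step`` is only used to record the per-bin truth.
    """

    n_points: int = 500
    total_area: float = 300.0
    bin_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.total_area <= 0 or self.bin_step <= 0:
            raise ValueError("need n_points >= 1, total_area > 0, bin_step > 0")


def gen_esp_surface(spec: ESPGenSpec, role: str, ion_id: str = "synthetic-ion"
                    ) -> tuple[ESPSurfacePoints, dict]:
    """Draw an ESP point set for one ion role and record per-bin truth.

    The truth's ``bin_mass`` is computed by an explicit per-point scan
    (independent of the histogramming code under test).
    """
    if role == "cation":
        low, high = 0.0, 150.0
    elif role == "anion":
        low, high = -150.0, 0.0
    else:
        raise ValueError(f"role must be 'cation' or 'anion', got {role!r}")
    rng = np.random.default_rng(spec.seed)
    areas = rng.dirichlet(np.ones(spec.n_points)) * spec.total_area
    esps = rng.uniform(low, high, size=spec.n_points)
    points = ESPSurfacePoints(ion_id=ion_id, role=role, areas=areas, esps=esps)
    n_bins = int(round((high - low) / spec.bin_step))
    bin_mass = [0.0] * n_bins
    for a, v in zip(areas, esps):
        j = int((v - low) // spec.bin_step)
        bin_mass[min(j, n_bins - 1)] += float(a)
    truth = {"total_area": float(spec.total_area), "bin_mass": bin_mass,
             "low": low, "high": high, "step": spec.bin_step}
    return points, truth


@dataclass(frozen=True)
class QSARGenSpec:
    """Recipe for a descriptor table with a known linear ground truth.

    ``n_informative`` descriptors carry non-zero true coefficients
    (``coefficients``; defaults to the published model's values, truncated or
    cycled to length), ``n_decoy`` descriptors are pure noise features with
    true coefficient exactly 0.  Feature names are taken from the real
    descriptor grids so tables look like genuine featurized data.  The
    activity is

        logEC50 = intercept + Σ c_i·x_i + ε,  ε ~ N(0, noise_sd²);

    with ``relative_noise=True`` the noise SD is ``noise_sd`` times the
    standard deviation of the noiseless activity.  Features are half-normal
    (non-negative, like bin areas) with scale ``feature_scale`` by default,
    or standard normal with ``feature_dist="normal"``.
    """

    n_samples: int = 160
    n_informative: int = 11
    n_decoy: int = 709
    intercept: float = 2.712
    coefficients: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    relative_noise: bool = False
    feature_dist: str = "halfnormal"
    feature_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_informative < 1 or self.n_decoy < 0:
            raise ValueError("invalid dataset shape")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.feature_dist not in ("halfnormal", "normal"):
            raise ValueError("feature_dist must be 'halfnormal' or 'normal'")


def _truth_names_and_coefs(spec: QSARGenSpec) -> tuple[list[str], np.ndarray,
                                                       list[str]]:
    pub = published_model()
    pub_names = pub.names
    all_names = descriptor_names()
    if spec.n_informative <= len(pub_names):
        informative = pub_names[: spec.n_informative]
    else:
        extra = [n for n in all_names if n not in pub_names]
        informative = pub_names + extra[: spec.n_informative - len(pub_names)]
    decoy_pool = [n for n in all_names if n not in set(informative)]
    if spec.n_decoy > len(decoy_pool):
        decoy_pool = decoy_pool + [f"decoy_{i:04d}"
                                   for i in range(spec.n_decoy - len(decoy_pool))]
    decoys = decoy_pool[: spec.n_decoy]
    if spec.coefficients is not None:
        if len(spec.coefficients) != spec.n_informative:
            raise ValueError("coefficients length must equal n_informative")
        coefs = np.asarray(spec.coefficients, dtype=float)
    else:
        base = np.array([pub.coefficients.get(n, 0.3) for n in informative])
        coefs = base
    return informative, coefs, decoys


def gen_qsar_dataset(spec: QSARGenSpec) -> tuple[pd.DataFrame, LinearModel]:
    """Generate (descriptor table, true model).

    The table has the informative columns first, then the decoys, then the
    ``logEC50`` target.  The returned :class:`~iltox.mlr.LinearModel` is the
    exact generating model (decoy coefficients are identically zero and do
    not appear among its terms); its ``fit_meta`` records the noise SD used
    and the names of the informative and decoy columns.
    """
    informative, coefs, decoys = _truth_names_and_coefs(spec)
    rng = np.random.default_rng(spec.seed)
    n_feat = spec.n_informative + spec.n_decoy
    if spec.feature_dist == "halfnormal":
        X = np.abs(rng.normal(0.0, spec.feature_scale,
                              size=(spec.n_samples, n_feat)))
    else:
        X = rng.normal(0.0, spec.feature_scale, size=(spec.n_samples, n_feat))
    signal = spec.intercept + X[:, : spec.n_informative] @ coefs
    noise_sd = spec.noise_sd
    if spec.relative_noise:
        noise_sd = spec.noise_sd * float(np.std(signal))
    y = signal + rng.normal(0.0, noise_sd, size=spec.n_samples)

    columns = informative + decoys
    table = pd.DataFrame(X, columns=columns)
    table[TARGET_COLUMN] = y
    table.index = [f"IL{i + 1:04d}" for i in range(spec.n_samples)]
    table.index.name = "il_id"

    truth = LinearModel(
        intercept=float(spec.intercept),
        terms=list(zip(informative, map(float, coefs))),
        fit_meta={"noise_sd": float(noise_sd), "informative": informative,
                  "decoys_are_zero": True, "n_decoy": spec.n_decoy,
                  "seed": spec.seed},
    )
    return table, truth
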