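"""Histogram descriptors: σ-profiles (S_σ) and ESP surface areas (S_EP).

Each ion's surface is binned on a fixed grid and the total segment area per
bin becomes one named descriptor.  Two grids are used:

* σ-profile: screening charge density from −0.03 to 0.03 e/Å² in 0.001-wide
  bins (60 bins per ion).
* ESP: electrostatic potential in 0.5 kcal/mol bins; cations span 0–150
  kcal/mol and anions −150–0 kcal/mol (300 bins each).

Descriptor naming follows the field's convention: ``S_EP-C88.75`` is the
cation surface area with ESP in [88.5, 89.0) — ESP bins are labelled by their
midpoint.  σ bins are labelled by their *left edge* (``S_σ-C0.013`` is the
cation area with σ in [0.013, 0.014)): midpoints of a 0.001-wide grid anchored
at −0.03 end in x.xxx5 and cannot produce the conventional three-decimal
labels, so left-edge labelling is used and documented.

Bins are half-open [left, right); a value exactly on the top edge of the grid
is assigned to the last bin.  Area falling outside the grid is never silently
dropped — it is accumulated as a spill count/area on the profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .surfaces import ESPSurfacePoints, SurfaceSegmentSet

__all__ = [
    "SIGMA_LOW",
    "SIGMA_HIGH",
    "SIGMA_STEP",
    "ESP_STEP",
    "NON_POLAR_SIGMA_BOUND",
    "TARGET_COLUMN",
    "BinGrid",
    "Profile",
    "DegenerateProfileError",
    "DescriptorAssemblyError",
    "sigma_grid",
    "esp_grid",
    "compute_profile",
    "classify_sigma_region",
    "descriptor_names",
    "assemble_descriptor_row",
    "build_descriptor_table",
    "feature_columns",
]

logger = logging.getLogger(__name__)

SIGMA_LOW = -0.03    # e/Å²
SIGMA_HIGH = 0.03
SIGMA_STEP = 0.001
ESP_STEP = 0.5       # kcal/mol

#: |σ| bound of the non-polar region (e/Å²), inclusive on both sides.
NON_POLAR_SIGMA_BOUND = 0.0082

#: Name of the experimental-activity column carried alongside the features.
TARGET_COLUMN = "logEC50"

_ROLE_LETTER = {"cation": "C", "anion": "A"}


class DegenerateProfileError(ValueError):
    """Every surface element fell outside the grid."""


class DescriptorAssemblyError(KeyError):
    """A required profile or ion is missing when assembling descriptors."""


@dataclass(frozen=True)
class BinGrid:
    """A uniform half-open binning of one descriptor axis.

    ``label_style`` selects how bins are named: ``"center"`` labels a bin by
    its midpoint (ESP convention), ``"left"`` by its left edge (σ convention).
    ``decimals`` is the precision used when formatting labels.
    """

    low: float
    high: float
    step: float
    label_style: Literal["center", "left"]
    decimals: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = (self.high - self.low) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(high - low) must be an integer multiple of step")

    @property
    def n_bins(self) -> int:
        return int(round((self.high - self.low) / self.step))

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_bins + 1)

    @property
    def left_edges(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def labels(self) -> list[str]:
        anchor = self.centers if self.label_style == "center" else self.left_edges
        # round before formatting so -0.0000 never appears
        return [f"{round(v, self.decimals) + 0.0:.{self.decimals}f}" for v in anchor]

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        """Half-open bin assignment; the top edge maps into the last bin.

        Out-of-grid values get index −1.
        """
        values = np.asarray(values, dtype=float)
        j = (values - self.low) / self.step
        idx = np.floor(j).astype(int)
        # values within 1e-9 bins of their right edge are float noise on an
        # exact edge (e.g. 0.013 on the 0.001 grid); snap them up
        idx[j - idx > 1.0 - 1e-9] += 1
        idx = np.minimum(idx, self.n_bins - 1)  # top edge joins the last bin
        idx[(values < self.low) | (values > self.high)] = -1
        return idx


def sigma_grid() -> BinGrid:
    """The σ-profile grid: [−0.03, 0.03) e/Å² in 0.001 steps, 60 bins."""
    return BinGrid(SIGMA_LOW, SIGMA_HIGH, SIGMA_STEP, label_style="left", decimals=3)


def esp_grid(role: str) -> BinGrid:
    """The ESP grid for one ion role, 0.5 kcal/mol steps, 300 bins.

    Cations span [0, 150) kcal/mol, anions [−150, 0).
    """
    if role == "cation":
        return BinGrid(0.0, 150.0, ESP_STEP, label_style="center", decimals=2)
    if role == "anion":
        return BinGrid(-150.0, 0.0, ESP_STEP, label_style="center", decimals=2)
    raise ValueError(f"role must be 'cation' or 'anion', got {role!r}")


@dataclass
class Profile:
    """Binned surface areas of one ion on one grid.

    ``bin_areas[i]`` is the total surface area (Å²) whose value fell in bin
    ``i``.  Spill (area outside the grid) is kept separately so that total
    input area is always accounted for: ``bin_areas.sum() + spill_area`` equals
    the surface's total area.
    """

    ion_id: str
    kind: Literal["sigma", "esp"]
    grid: BinGrid
    bin_areas: np.ndarray
    spill_area: float = 0.0
    spill_count: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return self.grid.centers

    @property
    def total_area(self) -> float:
        return float(self.bin_areas.sum())


def compute_profile(surface: SurfaceSegmentSet | ESPSurfacePoints,
                    grid: BinGrid,
                    on_degenerate: Literal["raise", "warn"] = "raise") -> Profile:
    """Histogram a surface onto ``grid``, conserving area.

    Each element's area is added to the bin whose half-open interval contains
    its value; a value equal to the grid's top edge lands in the last bin.
    Out-of-grid area is accumulated as spill, never dropped.  If *every*
    element is out of grid the profile is degenerate: raise (default) or warn
    per ``on_degenerate``.
    """
    kind = "sigma" if isinstance(surface, SurfaceSegmentSet) else "esp"
    values = surface.values
    areas = surface.areas
    idx = grid.bin_index(values)
    in_grid = idx >= 0
    bin_areas = np.bincount(idx[in_grid], weights=areas[in_grid],
                            minlength=grid.n_bins).astype(float)
    spill_area = float(areas[~in_grid].sum())
    spill_count = int((~in_grid).sum())
    if not in_grid.any():
        msg = (f"{surface.ion_id}: all {len(values)} surface elements fall "
               f"outside the [{grid.low}, {grid.high}] grid")
        if on_degenerate == "raise":
            raise DegenerateProfileError(msg)
        logger.warning(msg)
    return Profile(ion_id=surface.ion_id, kind=kind, grid=grid,
                   bin_areas=bin_areas, spill_area=spill_area,
                   spill_count=spill_count)


def classify_sigma_region(sigma: float) -> str:
    """Assign a screening charge density to its chemical surface region.

    σ < −0.0082 e/Å² is the hydrogen-bond donor region, σ > 0.0082 the HB
    acceptor region, and the closed band in between is non-polar.  Exactly one
    label applies to any σ.
    """
    if sigma < -NON_POLAR_SIGMA_BOUND:
        return "HB_donor"
    if sigma > NON_POLAR_SIGMA_BOUND:
        return "HB_acceptor"
    return "non_polar"


def _block_names(kind: str, role: str, grid: BinGrid) -> list[str]:
    prefix = "S_EP-" if kind == "esp" else "S_σ-"
    letter = _ROLE_LETTER[role]
    return [f"{prefix}{letter}{lab}" for lab in grid.labels]


def descriptor_names() -> list[str]:
    """All 720 descriptor names in canonical column order.

    Order: cation ESP (300), anion ESP (300), cation σ (60), anion σ (60),
    each block by ascending bin position.
    """
    return (
        _block_names("esp", "cation", esp_grid("cation"))
        + _block_names("esp", "anion", esp_grid("anion"))
        + _block_names("sigma", "cation", sigma_grid())
        + _block_names("sigma", "anion", sigma_grid())
    )


def assemble_descriptor_row(cation: Mapping[str, Profile],
                            anion: Mapping[str, Profile]) -> pd.Series:
    """Concatenate one IL's four profiles into a named descriptor vector.

    ``cation`` and ``anion`` each map ``"esp"`` and ``"sigma"`` to a
    :class:`Profile`.  The result has 720 entries in the canonical order
    (cation ESP, anion ESP, cation σ, anion σ).  Missing profiles raise
    :class:`DescriptorAssemblyError` naming the ion role and profile kind.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for role, profiles, kind in (("cation", cation, "esp"),
                                 ("anion", anion, "esp"),
                                 ("cation", cation, "sigma"),
                                 ("anion", anion, "sigma")):
        try:
            prof = profiles[kind]
        except KeyError:
            raise DescriptorAssemblyError(
                f"missing {kind} profile for the {role}"
            ) from None
        expected = esp_grid(role) if kind == "esp" else sigma_grid()
        if prof.grid != expected:
            raise DescriptorAssemblyError(
                f"{role} {kind} profile is on the wrong grid"
            )
        blocks.append(prof.bin_areas)
        names.extend(_block_names(kind, role, prof.grid))
    return pd.Series(np.concatenate(blocks), index=names, dtype=float)


def build_descriptor_table(samples: pd.DataFrame,
                           profiles: Mapping[str, Mapping[str, Profile]]
                           ) -> pd.DataFrame:
    """Build the samples × descriptors table for a set of ionic liquids.

    ``samples`` needs columns ``il_id``, ``cation_id``, ``anion_id`` and
    ``logEC50``; ``profiles`` maps each ion id to its ``{"esp", "sigma"}``
    profiles.  Returns one row per IL (indexed by ``il_id``) with the 720
    named features followed by the ``logEC50`` target column.  ILs sharing an
    ion get identical feature blocks for it.
    """
    required = {"il_id", "cation_id", "anion_id", TARGET_COLUMN}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table is missing columns: {sorted(missing)}")
    rows = []
    for rec in samples.itertuples(index=False):
        for ion, role in ((rec.cation_id, "cation"), (rec.anion_id, "anion")):
            if ion not in profiles:
                raise DescriptorAssemblyError(
                    f"sample {rec.il_id}: no profiles for {role} {ion!r}"
                )
        row = assemble_descriptor_row(profiles[rec.cation_id],
                                      profiles[rec.anion_id])
        row[TARGET_COLUMN] = getattr(rec, TARGET_COLUMN)
        row.name = rec.il_id
        rows.append(row)
    table = pd.DataFrame(rows)
    table.index.name = "il_id"
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The descriptor columns of a table (everything except the target)."""
    return [c for c in table.columns if c != TARGET_COLUMN]
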