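"""Molecular surface containers and file readers.

Two kinds of per-ion surface data feed the descriptor pipeline:

* COSMO-style *segment* listings: each surface segment has an area (Å²) and a
  screening charge density σ (e/Å²).  Histogramming these over σ gives the
  σ-profile descriptors.
* Electrostatic-potential (ESP) *surface point* listings: each surface patch
  has an area (Å²) and an ESP value (kcal/mol).  Histogramming these gives the
  ESP surface-area descriptors.

The on-disk dialect is a plain two-column text table (area, value), whitespace-
or comma-delimited, with ``#`` comments and blank lines ignored.  Files
produced by quantum-chemistry post-processors often carry extra columns; the
``area_col``/``value_col`` arguments map those onto the two fields we need.
All areas are Å², ESP in kcal/mol, σ in e/Å²; unit conversion is the caller's
job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SurfaceParseError",
    "EmptyInputError",
    "SurfaceSegment",
    "SurfaceSegmentSet",
    "ESPSurfacePoint",
    "ESPSurfacePoints",
    "parse_segment_file",
    "parse_esp_file",
    "write_segment_file",
    "write_esp_file",
]


class SurfaceParseError(ValueError):
    """A surface file line failed to parse; the message names the line."""


class EmptyInputError(ValueError):
    """A surface file or surface container holds no records."""


@dataclass(frozen=True)
class SurfaceSegment:
    """One COSMO surface segment: area in Å², screening charge density in e/Å²."""

    area: float
    sigma: float


@dataclass(frozen=True)
class ESPSurfacePoint:
    """One ESP surface patch: area in Å², electrostatic potential in kcal/mol."""

    area: float
    esp: float


def _validate_surface_arrays(ion_id: str, areas: np.ndarray, values: np.ndarray,
                             value_name: str) -> tuple[np.ndarray, np.ndarray]:
    areas = np.asarray(areas, dtype=float)
    values = np.asarray(values, dtype=float)
    if areas.ndim != 1 or values.ndim != 1 or areas.shape != values.shape:
        raise ValueError(
            f"{ion_id}: areas and {value_name} must be equal-length 1-D arrays"
        )
    if areas.size == 0:
        raise EmptyInputError(f"{ion_id}: surface holds no records")
    if not np.all(np.isfinite(areas)) or not np.all(np.isfinite(values)):
        raise ValueError(f"{ion_id}: non-finite area or {value_name} value")
    if np.any(areas <= 0):
        bad = int(np.argmax(areas <= 0))
        raise ValueError(
            f"{ion_id}: record {bad} has non-positive area {areas[bad]!r}"
        )
    return areas, values


@dataclass
class SurfaceSegmentSet:
    """An ion's COSMO surface as parallel (area, σ) arrays, in file order."""

    ion_id: str
    areas: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.areas, self.sigmas = _validate_surface_arrays(
            self.ion_id, self.areas, self.sigmas, "sigmas"
        )

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def values(self) -> np.ndarray:
        return self.sigmas

    def __len__(self) -> int:
        return int(self.areas.size)

    def __iter__(self) -> Iterator[SurfaceSegment]:
        for a, s in zip(self.areas, self.sigmas):
            yield SurfaceSegment(float(a), float(s))


@dataclass
class ESPSurfacePoints:
    """An ion's ESP-mapped surface as parallel (area, ESP) arrays.

    ``role`` records whether the ion is the cation or the anion; cations live
    on the positive ESP grid and anions on the negative one, and the grid (not
    the parser) enforces the range.
    """

    ion_id: str
    role: str
    areas: np.ndarray
    esps: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ("cation", "anion"):
            raise ValueError(f"role must be 'cation' or 'anion', got {self.role!r}")
        self.areas, self.esps = _validate_surface_arrays(
            self.ion_id, self.areas, self.esps, "esps"
        )

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def values(self) -> np.ndarray:
        return self.esps

    def __len__(self) -> int:
        return int(self.areas.size)

    def __iter__(self) -> Iterator[ESPSurfacePoint]:
        for a, e in zip(self.areas, self.esps):
            yield ESPSurfacePoint(float(a), float(e))


def _read_two_columns(path: str | Path, area_col: int, value_col: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    areas: list[float] = []
    values: list[float] = []
    needed = max(area_col, value_col) + 1
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < needed:
                raise SurfaceParseError(
                    f"{path.name}:{lineno}: expected at least {needed} columns, "
                    f"got {len(fields)}"
                )
            try:
                a = float(fields[area_col])
                v = float(fields[value_col])
            except ValueError as exc:
                raise SurfaceParseError(
                    f"{path.name}:{lineno}: non-numeric field ({exc})"
                ) from None
            areas.append(a)
            values.append(v)
    if not areas:
        raise EmptyInputError(f"{path.name}: no data records found")
    return np.asarray(areas), np.asarray(values)


def parse_segment_file(path: str | Path, ion_id: str | None = None,
                       area_col: int = 0, value_col: int = 1) -> SurfaceSegmentSet:
    """Read a COSMO-style segment listing into a :class:`SurfaceSegmentSet`.

    Records are returned in file order and the set's total area is the sum of
    the record areas.  Malformed lines raise :class:`SurfaceParseError` naming
    the offending line; an empty file raises :class:`EmptyInputError`.
    """
    areas, sigmas = _read_two_columns(path, area_col, value_col)
    if ion_id is None:
        ion_id = Path(path).stem
    return SurfaceSegmentSet(ion_id=ion_id, areas=areas, sigmas=sigmas)


def parse_esp_file(path: str | Path, role: str, ion_id: str | None = None,
                   area_col: int = 0, value_col: int = 1) -> ESPSurfacePoints:
    """Read an ESP surface-point listing into :class:`ESPSurfacePoints`.

    ``role`` must be ``"cation"`` or ``"anion"``.  Values outside the role's
    ESP grid are accepted here and counted as spill when profiled.
    """
    areas, esps = _read_two_columns(path, area_col, value_col)
    if ion_id is None:
        ion_id = Path(path).stem
    return ESPSurfacePoints(ion_id=ion_id, role=role, areas=areas, esps=esps)


def _write_two_columns(path: str | Path, areas: Sequence[float],
                       values: Sequence[float], header: str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        for a, v in zip(areas, values):
            fh.write(f"{float(a)!r} {float(v)!r}\n")


def write_segment_file(surface: SurfaceSegmentSet, path: str | Path) -> None:
    """Write a segment set in the dialect :func:`parse_segment_file` reads.

    Values are written with ``repr`` so a round trip is lossless.
    """
    _write_two_columns(path, surface.areas, surface.sigmas,
                       f"ion={surface.ion_id} columns: area[A^2] sigma[e/A^2]")


def write_esp_file(points: ESPSurfacePoints, path: str | Path) -> None:
    """Write an ESP point set in the dialect :func:`parse_esp_file` reads."""
    _write_two_columns(path, points.areas, points.esps,
                       f"ion={points.ion_id} role={points.role} "
                       "columns: area[A^2] esp[kcal/mol]")
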