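"""Pasture-name point densities and density-based regionalization.

Pasture names carry the word root (etymon) of the language group that
coined them — Germanic, Slavic or Romance.  Because place names are laid
down early in a colonization process, the spatial density of each etymon
class maps the corresponding group's former settlement area.  A density
surface counts, for every grid cell center, the class points inside a
circular neighborhood (default radius 10 km) divided by the disc area;
municipalities are then assigned to the former-Romance region (A) or the
former-Slavic region (B) by comparing the Romance and Slavic surfaces at
their locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PastureNamePoint", "DensityGrid", "RegionMap",
    "point_density", "etymon_composition", "classify_regions",
    "read_pasture_points", "write_pasture_points",
]

ETYMON_CLASSES = ("Germanic", "Slavic", "Romance")


@dataclass(frozen=True)
class PastureNamePoint:
    x: float
    y: float
    etymon_class: str

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if self.etymon_class not in ETYMON_CLASSES:
            raise ValueError(f"etymon_class must be one of {ETYMON_CLASSES}")


@dataclass(frozen=True)
class DensityGrid:
    """Point density (per km^2) on a regular grid of cell centers."""

    origin: tuple[float, float]   # center of cell [0, 0]
    cell_km: float
    radius_km: float
    density: np.ndarray           # (ny, nx), row i = y index
    etymon_class: str | None = None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.density.shape
        xs = self.origin[0] + np.arange(nx) * self.cell_km
        ys = self.origin[1] + np.arange(ny) * self.cell_km
        return xs, ys

    def value_at(self, x: float, y: float) -> float:
        """Density of the cell containing (x, y); outside the grid is an error."""
        xs, ys = self.cell_centers()
        ix = int(round((x - self.origin[0]) / self.cell_km))
        iy = int(round((y - self.origin[1]) / self.cell_km))
        ny, nx = self.density.shape
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise ValueError(f"location ({x}, {y}) lies outside the density grid")
        return float(self.density[iy, ix])


def point_density(points: Sequence[PastureNamePoint], cell_km: float = 1.0,
                  radius_km: float = 10.0,
                  bounds: tuple[float, float, float, float] | None = None,
                  etymon_class: str | None = None) -> DensityGrid:
    """Density surface: per cell center, class points within the closed
    disc of ``radius_km`` divided by the disc area.

    ``bounds`` (xmin, ymin, xmax, ymax) fixes the grid extent; by default
    the points' bounding box expanded by the radius.  Points exactly at
    distance ``radius_km`` are counted (closed disc).
    """
    if radius_km <= 0 or cell_km <= 0:
        raise ValueError("radius and cell size must be positive")
    if etymon_class is not None:
        points = [p for p in points if p.etymon_class == etymon_class]
    if bounds is None:
        if points:
            px = np.array([p.x for p in points])
            py = np.array([p.y for p in points])
            bounds = (px.min() - radius_km, py.min() - radius_km,
                      px.max() + radius_km, py.max() + radius_km)
        else:
            bounds = (0.0, 0.0, cell_km, cell_km)
    xmin, ymin, xmax, ymax = bounds
    nx = max(1, int(np.floor((xmax - xmin) / cell_km)) + 1)
    ny = max(1, int(np.floor((ymax - ymin) / cell_km)) + 1)
    xs = xmin + np.arange(nx) * cell_km
    ys = ymin + np.arange(ny) * cell_km
    density = np.zeros((ny, nx))
    area = np.pi * radius_km ** 2
    if points:
        px = np.array([p.x for p in points])
        py = np.array([p.y for p in points])
        # distances cell-center x point, vectorized over the grid rows
        for iy, yc in enumerate(ys):
            d2 = (px[None, :] - xs[:, None]) ** 2 + (py[None, :] - yc) ** 2
            density[iy] = np.sum(d2 <= radius_km ** 2 + 1e-9, axis=1) / area
    return DensityGrid(origin=(float(xs[0]), float(ys[0])), cell_km=cell_km,
                       radius_km=radius_km, density=density,
                       etymon_class=etymon_class)


def etymon_composition(points: Sequence[PastureNamePoint]
                       ) -> dict[str, tuple[int, float]]:
    """Counts and proportions per etymon class (proportions sum to 1)."""
    if not points:
        raise ValueError("need at least one point")
    n = len(points)
    out = {}
    for cls in ETYMON_CLASSES:
        c = sum(p.etymon_class == cls for p in points)
        out[cls] = (c, c / n)
    return out


@dataclass(frozen=True)
class RegionMap:
    """Municipality -> region A/B assignment."""

    region: dict[str, str]            # municipality -> "A" | "B"
    unresolved: tuple[str, ...]
    provenance: dict[str, str]        # municipality -> "density-derived"|"fixed-table"


def classify_regions(romance: DensityGrid, slavic: DensityGrid,
                     municipalities: Mapping[str, tuple[float, float]],
                     margin: float = 0.0,
                     fallback: Mapping[str, str] | None = None) -> RegionMap:
    """Assign municipalities to region A (Romance) or B (Slavic).

    A municipality is A when the Romance density at its location exceeds
    the Slavic density by more than ``margin`` (per km^2), B for the
    reverse; ties or sub-margin contrasts use the fixed-table fallback
    when provided and are flagged unresolved otherwise.
    """
    if (romance.cell_km, romance.radius_km, romance.origin,
            romance.density.shape) != (slavic.cell_km, slavic.radius_km,
                                       slavic.origin, slavic.density.shape):
        raise ValueError("Romance and Slavic grids must share geometry")
    region: dict[str, str] = {}
    provenance: dict[str, str] = {}
    unresolved: list[str] = []
    for key, (x, y) in sorted(municipalities.items()):
        diff = romance.value_at(x, y) - slavic.value_at(x, y)
        if diff > margin:
            region[key] = "A"
            provenance[key] = "density-derived"
        elif diff < -margin:
            region[key] = "B"
            provenance[key] = "density-derived"
        elif fallback is not None and key in fallback:
            region[key] = fallback[key]
            provenance[key] = "fixed-table"
        else:
            unresolved.append(key)
    return RegionMap(region=region, unresolved=tuple(unresolved),
                     provenance=provenance)


def read_pasture_points(path) -> list[PastureNamePoint]:
    """3-column delimited file: x_km, y_km, etymon_class."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"x_km", "y_km", "etymon_class"}
    if not required <= set(df.columns):
        raise ValueError(f"pasture point file needs columns {sorted(required)}")
    return [PastureNamePoint(float(r.x_km), float(r.y_km), r.etymon_class)
            for r in df.itertuples()]


def write_pasture_points(points: Sequence[PastureNamePoint], path) -> None:
    pd.DataFrame(
        {"x_km": [p.x for p in points], "y_km": [p.y for p in points],
         "etymon_class": [p.etymon_class for p in points]}
    ).to_csv(path, sep="\t", index=False)
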