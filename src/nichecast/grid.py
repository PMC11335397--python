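"""Equal-area study grid, depth strata, water-mass volumes and foraging masks.

The study domain is a pre-projected equal-area grid of square cells
(default 20 x 20 km), divided vertically into three depth strata
(0-20, 20-50 and 50-200 m).  Each (cell, stratum) parallelepiped is a
*water mass* -- the atomic accounting unit for zooplankton biomass and
predator accessibility.  Stratum volumes are truncated at the seafloor so
shelf cells carry no phantom deep-water volume; a seafloor depth of 0 m
marks land.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

M_PER_KM = 1000.0
#: Default depth strata (top, bottom) in metres.
DEFAULT_STRATA: tuple[tuple[float, float], ...] = ((0.0, 20.0), (20.0, 50.0), (50.0, 200.0))
#: Default foraging radius around little auk colonies, km.
DEFAULT_FORAGING_RADIUS_KM = 150.0
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """Horizontal/vertical geometry of the study domain.

    Coordinates are projected equal-area kilometres; ``(i, j)`` indexes are
    row-major ``(y, x)`` with 0-based origin at the lower-left corner.
    """

    nx: int
    ny: int
    cell_side_km: float = 20.0
    strata: tuple[tuple[float, float], ...] = DEFAULT_STRATA
    origin_km: tuple[float, float] = (0.0, 0.0)
    projection: str = "equal-area-km"

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise InputError(f"grid must have at least one cell, got nx={self.nx}, ny={self.ny}")
        if self.cell_side_km <= 0:
            raise InputError("cell_side_km must be positive")
        strata = tuple((float(t), float(b)) for t, b in self.strata)
        if not strata:
            raise InputError("at least one depth stratum is required")
        prev_bottom = None
        for top, bottom in strata:
            if top < 0 or bottom <= top:
                raise InputError(f"malformed stratum ({top}, {bottom})")
            if prev_bottom is not None and not math.isclose(top, prev_bottom):
                raise InputError("strata must be contiguous and increasing")
            prev_bottom = bottom
        object.__setattr__(self, "strata", strata)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_side_km ** 2

    @property
    def cell_area_m2(self) -> float:
        return self.cell_area_km2 * M_PER_KM ** 2

    @property
    def domain_area_km2(self) -> float:
        return self.nx * self.ny * self.cell_area_km2

    @property
    def stratum_thickness_m(self) -> np.ndarray:
        return np.array([b - t for t, b in self.strata])

    @property
    def max_depth_m(self) -> float:
        return self.strata[-1][1]

    @property
    def extent_km(self) -> tuple[float, float]:
        """(x extent, y extent) of the domain in km."""
        return (self.nx * self.cell_side_km, self.ny * self.cell_side_km)

    def cell_centres_km(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(xc, yc)`` arrays of shape ``(ny, nx)`` in projected km."""
        x = self.origin_km[0] + (np.arange(self.nx) + 0.5) * self.cell_side_km
        y = self.origin_km[1] + (np.arange(self.ny) + 0.5) * self.cell_side_km
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class WaterMass:
    """One grid cell x depth stratum parallelepiped."""

    i: int  # row (y) index
    j: int  # column (x) index
    k: int  # stratum index, 0-based
    volume_m3: float
    region: int = 0
    is_land: bool = False


@dataclass
class WaterMassGrid:
    """Vectorised container for all water masses of a domain.

    ``volume_m3`` has shape ``(ny, nx, n_strata)``; land columns (seafloor
    depth 0) have zero volume in every stratum.
    """

    grid: GridSpec
    seafloor_depth_m: np.ndarray
    volume_m3: np.ndarray
    is_land: np.ndarray
    region_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.region_id is None:
            self.region_id = np.zeros((self.grid.ny, self.grid.nx), dtype=int)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.grid.ny, self.grid.nx, self.grid.n_strata)

    @property
    def n_water_masses(self) -> int:
        return int(np.prod(self.shape))

    @property
    def total_volume_m3(self) -> float:
        return float(self.volume_m3.sum())

    def water_masses(self) -> Iterator[WaterMass]:
        ny, nx, nk = self.shape
        for i in range(ny):
            for j in range(nx):
                land = bool(self.is_land[i, j])
                region = int(self.region_id[i, j])
                for k in range(nk):
                    yield WaterMass(i, j, k, float(self.volume_m3[i, j, k]), region, land)


def build_water_masses(
    grid: GridSpec,
    bathymetry: np.ndarray,
    region_id: np.ndarray | None = None,
) -> WaterMassGrid:
    """Build all water masses, truncating stratum volumes at the seafloor.

    Parameters
    ----------
    grid
        Domain geometry.
    bathymetry
        Seafloor depth in metres, shape ``(ny, nx)``; 0 marks land.

    The volume of water mass ``(i, j, k)`` is ``cell_area * max(0,
    min(stratum_bottom, seafloor) - stratum_top)``.
    """
    bathy = np.asarray(bathymetry, dtype=float)
    if bathy.shape != (grid.ny, grid.nx):
        raise InputError(
            f"bathymetry shape {bathy.shape} does not match grid ({grid.ny}, {grid.nx})"
        )
    if np.any(bathy < 0):
        raise InputError("seafloor depths must be >= 0 (0 marks land)")
    if region_id is not None:
        region_id = np.asarray(region_id)
        if region_id.shape != bathy.shape:
            raise InputError("region_id shape does not match grid")

    thickness = np.empty((grid.ny, grid.nx, grid.n_strata))
    for k, (top, bottom) in enumerate(grid.strata):
        thickness[:, :, k] = np.clip(np.minimum(bottom, bathy) - top, 0.0, None)
    volume = grid.cell_area_m2 * thickness
    return WaterMassGrid(
        grid=grid,
        seafloor_depth_m=bathy,
        volume_m3=volume,
        is_land=bathy == 0,
        region_id=region_id,
    )


@dataclass(frozen=True)
class ForagingMask:
    """Set of grid cells a predator can reach, as a boolean raster."""

    species: str
    cells: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=bool)
        if cells.shape != (self.grid.ny, self.grid.nx):
            raise InputError("mask shape does not match grid")
        object.__setattr__(self, "cells", cells)

    @property
    def area_km2(self) -> float:
        return float(self.cells.sum()) * self.grid.cell_area_km2

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    def issubset(self, other: "ForagingMask") -> bool:
        return bool(np.all(other.cells | ~self.cells))


def _validate_colonies(colonies: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    if colonies is None or len(colonies) == 0:
        raise InputError("colony table is empty")
    missing = [c for c in columns if c not in colonies.columns]
    if missing:
        raise InputError(f"colony table is missing columns {missing}")
    return colonies


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def auk_foraging_mask(
    grid: GridSpec,
    colonies: pd.DataFrame,
    radius_km: float = DEFAULT_FORAGING_RADIUS_KM,
    is_land: np.ndarray | None = None,
    geo: bool = False,
    cell_lon: np.ndarray | None = None,
    cell_lat: np.ndarray | None = None,
) -> ForagingMask:
    """Breeding-season foraging mask: union of discs around colonies.

    A cell belongs to the mask iff its centre lies within ``radius_km`` of at
    least one colony (cell-centre rule); land cells are excluded.  In
    projected mode the colony table carries ``x_km, y_km``; with ``geo=True``
    it carries ``lon, lat`` and distances are great-circle against
    caller-supplied cell-centre coordinates.
    """
    if radius_km <= 0:
        raise InputError("radius_km must be positive")
    if geo:
        colonies = _validate_colonies(colonies, ("lon", "lat"))
        if cell_lon is None or cell_lat is None:
            raise InputError("geo mode requires cell-centre lon/lat rasters")
        inside = np.zeros((grid.ny, grid.nx), dtype=bool)
        for lon, lat in zip(colonies["lon"], colonies["lat"]):
            inside |= haversine_km(cell_lon, cell_lat, lon, lat) <= radius_km
    else:
        colonies = _validate_colonies(colonies, ("x_km", "y_km"))
        xc, yc = grid.cell_centres_km()
        inside = np.zeros((grid.ny, grid.nx), dtype=bool)
        r2 = radius_km ** 2
        for x, y in zip(colonies["x_km"], colonies["y_km"]):
            inside |= (xc - x) ** 2 + (yc - y) ** 2 <= r2
    if is_land is not None:
        inside &= ~np.asarray(is_land, dtype=bool)
    return ForagingMask(species="little_auk", cells=inside, grid=grid)


def whale_foraging_mask(grid: GridSpec, is_land: np.ndarray | None = None) -> ForagingMask:
    """Whole-domain foraging mask (the pre-whaling summer range), minus land."""
    cells = np.ones((grid.ny, grid.nx), dtype=bool)
    if is_land is not None:
        cells &= ~np.asarray(is_land, dtype=bool)
    return ForagingMask(species="bowhead", cells=cells, grid=grid)
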