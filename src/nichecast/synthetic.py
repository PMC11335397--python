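"""Synthetic Arctic fixture generator.

Produces self-contained inputs with the statistical structure the model
needs: an island-dotted equal-area domain with shelf bathymetry, three
contiguous pseudo-regions, a spatially autocorrelated log-Gaussian column
copepod-biomass field rescaled to a prescribed sea-cell mean, per-block
standard deviations of that field, and coastal breeding colonies.

Everything is a pure function of ``(seed, parameters)``.  The geography is
deliberately schematic: compact islands act as colony substrate and shelf
anchor; it is not a reconstruction of any real coastline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .grid import GridSpec, DEFAULT_FORAGING_RADIUS_KM

REGION_NAMES = {1: "west_sector", 2: "central_sector", 3: "east_sector"}


@dataclass(frozen=True)
class ShelfProfile:
    """Seafloor depth as a function of distance-to-land d (km):
    ``depth = base + slope*d + curve*d**exponent``, noised multiplicatively
    and capped at ``max_depth_m``."""

    base_m: float = 8.0
    slope_m_per_km: float = 2.2
    curve: float = 0.004
    exponent: float = 2.4
    max_depth_m: float = 3500.0
    noise_sd_log: float = 0.2


@dataclass
class SyntheticDomain:
    """Generated geography: grid, bathymetry, land, regions, coastline."""

    grid: GridSpec
    seafloor_depth_m: np.ndarray
    is_land: np.ndarray
    region_id: np.ndarray
    region_names: dict[int, str] = field(default_factory=lambda: dict(REGION_NAMES))

    @property
    def coast_cells(self) -> np.ndarray:
        """Boolean raster of sea cells 4-adjacent to land."""
        land = self.is_land
        neighbour_land = np.zeros_like(land)
        neighbour_land[1:, :] |= land[:-1, :]
        neighbour_land[:-1, :] |= land[1:, :]
        neighbour_land[:, 1:] |= land[:, :-1]
        neighbour_land[:, :-1] |= land[:, 1:]
        return neighbour_land & ~land


@dataclass
class BiomassClimatology:
    """Per-cell mean column biomass (g m^-2) with coarse-block dispersion.

    ``block_sd_gm2``/``block_mean_gm2`` are computed over sea cells of
    ``block_size_cells`` x ``block_size_cells`` blocks (default 5 cells =
    100 km, standing in for a one-degree aggregation scale).
    """

    grid: GridSpec
    mean_gm2: np.ndarray
    block_mean_gm2: np.ndarray
    block_sd_gm2: np.ndarray
    block_size_cells: int

    def __post_init__(self) -> None:
        if np.any(self.mean_gm2 < 0) or np.any(self.block_sd_gm2 < 0):
            raise InputError("biomass means and SDs must be non-negative")


def _place_islands(
    rng: np.random.Generator,
    grid: GridSpec,
    n_islands: int,
    target_land_cells: int,
    margin_km: float,
) -> np.ndarray:
    """Compact circular islands on a jittered lattice, well inside the domain."""
    land = np.zeros((grid.ny, grid.nx), dtype=bool)
    if n_islands == 0 or target_land_cells == 0:
        return land
    per_island = target_land_cells / n_islands
    r_cells = np.sqrt(per_island / np.pi)
    ext_x, ext_y = grid.extent_km
    inner_x = ext_x - 2 * margin_km
    inner_y = ext_y - 2 * margin_km
    if inner_x <= 0 or inner_y <= 0:
        raise InputError("domain too small for the requested island margin")
    g = int(np.ceil(np.sqrt(n_islands)))
    sx, sy = inner_x / g, inner_y / g
    centres = []
    for a in range(g):
        for b in range(g):
            cx = margin_km + (a + 0.5) * sx
            cy = margin_km + (b + 0.5) * sy
            centres.append((cx, cy))
    order = rng.permutation(len(centres))[:n_islands]
    xc, yc = grid.cell_centres_km()
    for idx in order:
        cx, cy = centres[idx]
        cx += rng.uniform(-0.08, 0.08) * sx
        cy += rng.uniform(-0.08, 0.08) * sy
        d2 = (xc - cx) ** 2 + (yc - cy) ** 2
        land |= d2 <= (r_cells * grid.cell_side_km) ** 2
    return land


def generate_domain(
    seed: int,
    nx: int = 76,
    ny: int = 76,
    cell_side_km: float = 20.0,
    land_fraction: float = 0.02,
    n_islands: int = 8,
    margin_km: float = 200.0,
    shelf_profile: ShelfProfile | None = None,
    foraging_radius_km: float = DEFAULT_FORAGING_RADIUS_KM,
) -> SyntheticDomain:
    """Generate the schematic study geography.

    The default 76 x 76 grid of 400 km^2 cells covers 2 310 400 km^2.  Land
    is ``n_islands`` compact islands totalling ``land_fraction`` of the
    cells, placed at least ``margin_km`` from the domain boundary so colony
    foraging discs are not clipped at the edge.  Bathymetry deepens away
    from land along ``shelf_profile``; three contiguous pseudo-regions
    (west/central/east bands) support regional reporting.
    """
    if not 0 <= land_fraction < 0.5:
        raise InputError("land_fraction must be in [0, 0.5)")
    grid = GridSpec(nx=nx, ny=ny, cell_side_km=cell_side_km)
    ext_x, ext_y = grid.extent_km
    if min(ext_x, ext_y) < 2 * foraging_radius_km:
        raise InputError(
            f"domain extent {min(ext_x, ext_y):.0f} km cannot hold a "
            f"{foraging_radius_km:.0f} km foraging buffer"
        )
    shelf = shelf_profile or ShelfProfile()
    rng = np.random.default_rng(seed)

    target_land = int(round(land_fraction * nx * ny))
    land = _place_islands(rng, grid, n_islands if target_land else 0, target_land, margin_km)

    # distance (km) from each sea cell to the nearest land cell
    if land.any():
        dist_cells = ndimage.distance_transform_edt(~land)
    else:
        # no land: uniform deep basin anchored mid-domain
        dist_cells = np.full((ny, nx), max(nx, ny) / 4.0)
    dist_km = dist_cells * cell_side_km
    depth = shelf.base_m + shelf.slope_m_per_km * dist_km + shelf.curve * dist_km ** shelf.exponent
    depth = depth * np.exp(rng.normal(0.0, shelf.noise_sd_log, size=depth.shape))
    depth = np.clip(depth, 5.0, shelf.max_depth_m)
    depth[land] = 0.0

    region = np.ones((ny, nx), dtype=int)
    thirds = np.linspace(0, nx, 4).astype(int)
    region[:, thirds[1]:thirds[2]] = 2
    region[:, thirds[2]:] = 3

    return SyntheticDomain(
        grid=grid, seafloor_depth_m=depth, is_land=land, region_id=region
    )


def generate_biomass_field(
    domain: SyntheticDomain,
    seed: int,
    mean_density_gm2: float = 33.2,
    cv_spatial: float = 0.8,
    correlation_length_km: float = 200.0,
    block_size_cells: int = 5,
) -> BiomassClimatology:
    """Spatially autocorrelated log-Gaussian column-biomass climatology.

    A Gaussian random field (white noise smoothed at ``correlation_length_km``
    and re-standardised) is exponentiated to a lognormal surface with spatial
    coefficient of variation ``cv_spatial``, then rescaled so the sea-cell
    mean equals ``mean_density_gm2`` exactly.  ``cv_spatial=0`` yields a
    uniform field.  Per-block means/SDs summarise within-block dispersion of
    sea cells and drive the Monte Carlo biomass perturbations.
    """
    grid = domain.grid
    if mean_density_gm2 <= 0:
        raise InputError("mean_density_gm2 must be positive")
    if cv_spatial < 0:
        raise InputError("cv_spatial must be >= 0")
    if correlation_length_km < grid.cell_side_km:
        raise InputError("correlation_length_km must be >= cell side")
    sea = ~domain.is_land
    if not sea.any():
        raise InputError("domain has no sea cells")

    rng = np.random.default_rng(seed)
    if cv_spatial == 0:
        fld = np.full((grid.ny, grid.nx), mean_density_gm2)
    else:
        z = rng.standard_normal((grid.ny, grid.nx))
        sigma_cells = correlation_length_km / (2.0 * grid.cell_side_km)
        z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="wrap")
        z = (z - z.mean()) / z.std()
        sigma_log = np.sqrt(np.log1p(cv_spatial ** 2))
        fld = np.exp(sigma_log * z - 0.5 * sigma_log ** 2) * mean_density_gm2
        fld *= mean_density_gm2 / fld[sea].mean()  # exact sea-cell mean
    fld = fld.copy()
    fld[~sea] = 0.0

    nb_y = int(np.ceil(grid.ny / block_size_cells))
    nb_x = int(np.ceil(grid.nx / block_size_cells))
    block_mean = np.zeros((nb_y, nb_x))
    block_sd = np.zeros((nb_y, nb_x))
    for bi in range(nb_y):
        for bj in range(nb_x):
            sl = (
                slice(bi * block_size_cells, (bi + 1) * block_size_cells),
                slice(bj * block_size_cells, (bj + 1) * block_size_cells),
            )
            vals = fld[sl][sea[sl]]
            if vals.size:
                block_mean[bi, bj] = vals.mean()
            if vals.size >= 2 and np.ptp(vals) > 0:
                block_sd[bi, bj] = vals.std(ddof=1)
    return BiomassClimatology(
        grid=grid,
        mean_gm2=fld,
        block_mean_gm2=block_mean,
        block_sd_gm2=block_sd,
        block_size_cells=block_size_cells,
    )


def generate_colonies(
    domain: SyntheticDomain,
    seed: int,
    n_colonies: int = 8,
    total_pairs: float = 4.8e6,
) -> pd.DataFrame:
    """Place breeding colonies on coastal sea cells.

    Colonies are spread by greedy farthest-point sampling over the coastline
    (so multi-island domains get one colony per island before doubling up)
    and the total number of breeding pairs is split by a Dirichlet draw,
    rounded to integers that sum to ``total_pairs`` exactly.
    """
    if n_colonies < 1:
        raise InputError("n_colonies must be >= 1")
    coast = np.argwhere(domain.coast_cells)
    if coast.size == 0:
        raise InputError("domain has no coastline; cannot place colonies")
    if n_colonies > len(coast):
        raise InputError(f"n_colonies={n_colonies} exceeds {len(coast)} coastline cells")

    rng = np.random.default_rng(seed)
    xc, yc = domain.grid.cell_centres_km()
    pts = np.column_stack([xc[coast[:, 0], coast[:, 1]], yc[coast[:, 0], coast[:, 1]]])
    chosen = [int(rng.integers(len(pts)))]
    while len(chosen) < n_colonies:
        d2 = np.min(
            ((pts[:, None, :] - pts[chosen][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        d2[chosen] = -1.0
        chosen.append(int(np.argmax(d2)))

    total = int(round(total_pairs))
    weights = rng.dirichlet(np.full(n_colonies, 4.0))
    pairs = np.floor(weights * total).astype(int)
    pairs[0] += total - pairs.sum()
    return pd.DataFrame(
        {
            "x_km": pts[chosen, 0],
            "y_km": pts[chosen, 1],
            "pairs": pairs,
        }
    )
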