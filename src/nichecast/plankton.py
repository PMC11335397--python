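"""Seasonal mesozooplankton production and its two-component patch structure.

Column copepod biomass (g m^-2) is converted to the mesozooplankton biomass
produced over the predators' shared season as a separable product of an
annual production-to-biomass (P/B) ratio, the fraction of annual secondary
production falling in the season, and a copepod-to-total-mesozooplankton
scaling.  Column production is then split across depth strata and, within
each water mass, partitioned into dense patches and a diffuse background
described by two patchiness intensity parameters:

* ``phi`` -- fraction of the water-mass volume occupied by patches;
* ``p``   -- fraction of the water-mass biomass concentrated in patches.

Patch density is ``p*B/(phi*V)`` and background density
``(1-p)*B/((1-phi)*V)``, so biomass is conserved exactly by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .grid import WaterMassGrid

GRAMS_PER_MEGATONNE = 1e12


@dataclass(frozen=True)
class ProductionParams:
    """Scaling from standing copepod biomass to in-season mesozooplankton production."""

    pb_ratio: float = 3.8
    season_fraction: float = 0.43
    copepod_to_meso: float = 1.0

    def __post_init__(self) -> None:
        if self.pb_ratio <= 0 or self.season_fraction <= 0 or self.copepod_to_meso <= 0:
            raise InputError("production parameters must be positive")
        if self.season_fraction > 1:
            raise InputError("season_fraction must be <= 1")

    @property
    def scale(self) -> float:
        return self.pb_ratio * self.season_fraction * self.copepod_to_meso


@dataclass
class StratifiedField:
    """Seasonal production per water mass, g, shape ``(ny, nx, n_strata)``."""

    biomass_g: np.ndarray
    fractions: np.ndarray

    @property
    def total_g(self) -> float:
        return float(self.biomass_g.sum())


@dataclass
class PatchStructure:
    """Patch/background partition of every water mass.

    All arrays share shape ``(ny, nx, n_strata)``.  Densities are zero on
    zero-volume water masses.
    """

    biomass_g: np.ndarray
    phi: np.ndarray
    p: np.ndarray
    d_patch_gm3: np.ndarray
    d_bg_gm3: np.ndarray

    @property
    def patch_biomass_g(self) -> np.ndarray:
        return self.p * self.biomass_g

    @property
    def total_g(self) -> float:
        return float(self.biomass_g.sum())


@dataclass(frozen=True)
class FieldSummary:
    """Domain-level diagnostics of the simulated prey field."""

    total_production_g: float
    patch_volume_fraction: float
    patch_biomass_g: float
    patch_biomass_fraction: float
    mean_patch_density_by_stratum_gm3: tuple[float, ...]
    mean_column_density_gm2: float
    mean_volumetric_density_gm3: float


def biomass_to_production(
    column_biomass_gm2: np.ndarray, params: ProductionParams
) -> np.ndarray:
    """Convert column biomass to seasonal column production (g m^-2).

    ``P = B * pb_ratio * season_fraction * copepod_to_meso``, elementwise.
    """
    biomass = np.asarray(column_biomass_gm2, dtype=float)
    if np.any(biomass < 0):
        raise InputError("column biomass must be non-negative")
    return biomass * params.scale


def stratify(
    production_gm2: np.ndarray,
    fractions,
    wm: WaterMassGrid,
) -> StratifiedField:
    """Distribute column production over depth strata.

    ``B[i, j, k] = P[i, j] * cell_area * f_k``, with the fractions
    renormalised over the strata of non-zero volume where bathymetry
    truncates the column (biomass is never assigned to sediment).
    """
    production = np.asarray(production_gm2, dtype=float)
    grid = wm.grid
    if production.shape != (grid.ny, grid.nx):
        raise InputError("production field shape does not match grid")
    f = np.asarray(fractions, dtype=float)
    if f.shape != (grid.n_strata,):
        raise InputError(f"expected {grid.n_strata} stratum fractions, got shape {f.shape}")
    if np.any(f < 0):
        raise InputError("stratum fractions must be >= 0")
    if abs(f.sum() - 1.0) > 1e-9:
        raise InputError("stratum fractions must sum to 1")

    wet = wm.volume_m3 > 0
    f_eff = f[None, None, :] * wet
    norm = f_eff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(norm[:, :, None] > 0, f_eff / norm[:, :, None], 0.0)
    column_g = production * grid.cell_area_m2
    return StratifiedField(biomass_g=column_g[:, :, None] * share, fractions=f)


def apply_patchiness(
    strat: StratifiedField,
    phi,
    p,
    wm: WaterMassGrid,
) -> PatchStructure:
    """Partition each water mass into patches and background.

    ``phi`` and ``p`` may be scalars or per-water-mass arrays; they must lie
    in (0, 1) and (0, 1] respectively wherever the water mass has volume.
    """
    shape = wm.shape
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), shape).copy()
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), shape).copy()
    wet = wm.volume_m3 > 0
    if np.any((phi_arr[wet] <= 0) | (phi_arr[wet] >= 1)):
        raise InputError("patch volume fraction phi must lie in (0, 1)")
    if np.any((p_arr[wet] <= 0) | (p_arr[wet] > 1)):
        raise InputError("patch biomass fraction p must lie in (0, 1]")
    if strat.biomass_g.shape != shape:
        raise InputError("stratified field shape does not match water masses")

    d_patch = np.zeros(shape)
    d_bg = np.zeros(shape)
    vol = wm.volume_m3
    d_patch[wet] = p_arr[wet] * strat.biomass_g[wet] / (phi_arr[wet] * vol[wet])
    bg_vol = (1.0 - phi_arr[wet]) * vol[wet]
    d_bg[wet] = (1.0 - p_arr[wet]) * strat.biomass_g[wet] / bg_vol
    return PatchStructure(
        biomass_g=strat.biomass_g.copy(),
        phi=phi_arr,
        p=p_arr,
        d_patch_gm3=d_patch,
        d_bg_gm3=d_bg,
    )


def summarize_field(patch: PatchStructure, wm: WaterMassGrid) -> FieldSummary:
    """Domain totals and shares of the patch-structured prey field."""
    vol = wm.volume_m3
    total_vol = vol.sum()
    total_b = patch.biomass_g.sum()
    patch_vol = (patch.phi * vol)[vol > 0].sum()
    patch_b = (patch.p * patch.biomass_g).sum()

    per_stratum = []
    for k in range(wm.grid.n_strata):
        pv = (patch.phi[:, :, k] * vol[:, :, k])[vol[:, :, k] > 0].sum()
        pb = (patch.p[:, :, k] * patch.biomass_g[:, :, k]).sum()
        per_stratum.append(float(pb / pv) if pv > 0 else 0.0)

    sea = ~wm.is_land
    area_m2 = sea.sum() * wm.grid.cell_area_m2
    return FieldSummary(
        total_production_g=float(total_b),
        patch_volume_fraction=float(patch_vol / total_vol) if total_vol > 0 else 0.0,
        patch_biomass_g=float(patch_b),
        patch_biomass_fraction=float(patch_b / total_b) if total_b > 0 else 0.0,
        mean_patch_density_by_stratum_gm3=tuple(per_stratum),
        mean_column_density_gm2=float(total_b / area_m2) if area_m2 > 0 else 0.0,
        mean_volumetric_density_gm3=float(total_b / total_vol) if total_vol > 0 else 0.0,
    )
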