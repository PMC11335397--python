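"""Trophic niches, accessible biomass, consumption and niche overlap.

A predator's trophic niche is the set of water masses satisfying three
criteria: the cell lies in its foraging area, the stratum is within its
foraging depth, and the patch density meets its minimum profitable density
threshold.  Accessibility is all-or-nothing at the water-mass level: where
the criteria pass, the whole patch biomass ``p*B`` of the water mass is
accessible (background biomass never is).

From the two accessibility fields follow the shared biomass ``Qs``, the
overlap degrees ``W = Qs/Qa`` (share of the auk niche covered by whales)
and ``Y = Qs/Qb`` (share of the whale niche covered by auks), demand-capped
consumption, and a decomposition of the niche discrepancy ``Qb - Qs`` by
first failing criterion in the fixed order geography -> depth -> threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .grid import ForagingMask, WaterMassGrid
from .plankton import PatchStructure


@dataclass(frozen=True)
class PredatorNiche:
    """One species' trophic niche plus its bioenergetic demand.

    ``strata`` are 1-based indices into the grid's depth strata.  Population
    counts individuals (for little auks: breeders, i.e. 2 x pairs).
    """

    species: str
    mask: ForagingMask
    strata: tuple[int, ...]
    threshold_gm3: float
    population: float
    ration_g_day: float
    season_days: int = 92

    def __post_init__(self) -> None:
        strata = tuple(sorted(int(s) for s in self.strata))
        if not strata or any(s < 1 for s in strata):
            raise InputError("strata must be non-empty 1-based indices")
        object.__setattr__(self, "strata", strata)
        if self.threshold_gm3 <= 0:
            raise InputError("density threshold must be positive")
        if self.population < 0:
            raise InputError("population must be >= 0")
        if self.ration_g_day <= 0:
            raise InputError("daily ration must be positive")
        if self.season_days <= 0:
            raise InputError("season length must be positive")

    @property
    def demand_g(self) -> float:
        """Seasonal biomass demand N * r * n, grams."""
        return self.population * self.ration_g_day * self.season_days


@dataclass
class AccessibilityResult:
    """Per-water-mass accessible biomass and its totals."""

    species: str
    accessible_g: np.ndarray
    total_g: float
    by_stratum_g: tuple[float, ...]
    by_region_g: dict[int, float]


@dataclass(frozen=True)
class ConsumptionResult:
    """Demand-capped seasonal consumption against an accessible stock Q."""

    demand_g: float
    consumed_g: float
    fraction: float
    insufficient: bool


@dataclass(frozen=True)
class OverlapResult:
    """Shared biomass and the two overlap degrees."""

    qs_g: float
    qa_g: float
    qb_g: float
    w: float
    y: float


@dataclass(frozen=True)
class DiscrepancyShares:
    """Attribution of the whale-only biomass Qb - Qs to the first failing
    little-auk criterion, in fixed order geography -> depth -> threshold."""

    geography: float
    depth: float
    threshold: float
    total_g: float
    valid: bool


def accessible_biomass(
    patch: PatchStructure, niche: PredatorNiche, wm: WaterMassGrid
) -> AccessibilityResult:
    """Total patch biomass within the predator's niche (Qa or Qb).

    A water mass contributes its whole patch biomass iff its cell is in the
    foraging mask, its stratum is an allowed foraging depth, and its patch
    density is at or above the species threshold (inclusive comparison).
    """
    grid = wm.grid
    if patch.biomass_g.shape != wm.shape:
        raise InputError("patch structure shape does not match water masses")
    if niche.mask.cells.shape != (grid.ny, grid.nx):
        raise InputError("foraging mask shape does not match water masses")
    if any(s > grid.n_strata for s in niche.strata):
        raise InputError("niche references a stratum outside the grid")

    stratum_ok = np.zeros(grid.n_strata, dtype=bool)
    stratum_ok[[s - 1 for s in niche.strata]] = True
    ok = (
        niche.mask.cells[:, :, None]
        & stratum_ok[None, None, :]
        & (patch.d_patch_gm3 >= niche.threshold_gm3)
    )
    accessible = np.where(ok, patch.p * patch.biomass_g, 0.0)
    by_stratum = tuple(float(accessible[:, :, k].sum()) for k in range(grid.n_strata))
    by_region: dict[int, float] = {}
    for rid in np.unique(wm.region_id):
        sel = wm.region_id == int(rid)
        by_region[int(rid)] = float(accessible[sel, :].sum())
    return AccessibilityResult(
        species=niche.species,
        accessible_g=accessible,
        total_g=float(accessible.sum()),
        by_stratum_g=by_stratum,
        by_region_g=by_region,
    )


def shared_biomass(acc_a: AccessibilityResult, acc_b: AccessibilityResult) -> float:
    """Qs: biomass common to both niches, sum over water masses of the
    elementwise minimum of the two accessibility fields."""
    if acc_a.accessible_g.shape != acc_b.accessible_g.shape:
        raise InputError("accessibility fields are on different grids")
    return float(np.minimum(acc_a.accessible_g, acc_b.accessible_g).sum())


def overlap(acc_auk: AccessibilityResult, acc_whale: AccessibilityResult) -> OverlapResult:
    """Qs, W = Qs/Qa and Y = Qs/Qb (nan where the denominator is zero)."""
    qs = shared_biomass(acc_auk, acc_whale)
    qa = acc_auk.total_g
    qb = acc_whale.total_g
    return OverlapResult(
        qs_g=qs,
        qa_g=qa,
        qb_g=qb,
        w=qs / qa if qa > 0 else float("nan"),
        y=qs / qb if qb > 0 else float("nan"),
    )


def consumption(niche: PredatorNiche, q_g: float) -> ConsumptionResult:
    """Seasonal consumption C = min(N*r*n, Q); flags demand exceeding stock."""
    if q_g < 0:
        raise InputError("accessible biomass must be >= 0")
    demand = niche.demand_g
    consumed = min(demand, q_g)
    return ConsumptionResult(
        demand_g=demand,
        consumed_g=consumed,
        fraction=consumed / q_g if q_g > 0 else 0.0,
        insufficient=demand > q_g,
    )


def decompose_discrepancy(
    patch: PatchStructure,
    wm: WaterMassGrid,
    whale_niche: PredatorNiche,
    auk_niche: PredatorNiche,
    acc_whale: AccessibilityResult,
    acc_auk: AccessibilityResult,
) -> DiscrepancyShares:
    """Attribute each whale-accessible, auk-inaccessible water mass's biomass
    to the first little-auk criterion it fails (geography, then depth, then
    density threshold); shares are normalised by Qb - Qs."""
    whale_only = (acc_whale.accessible_g > 0) & (acc_auk.accessible_g <= 0)
    total = float(acc_whale.accessible_g[whale_only].sum())
    if total <= 0:
        return DiscrepancyShares(0.0, 0.0, 0.0, 0.0, valid=False)

    grid = wm.grid
    out_of_area = ~auk_niche.mask.cells[:, :, None] & whale_only
    stratum_ok = np.zeros(grid.n_strata, dtype=bool)
    stratum_ok[[s - 1 for s in auk_niche.strata]] = True
    wrong_depth = ~out_of_area & ~stratum_ok[None, None, :] & whale_only
    below_threshold = (
        ~out_of_area
        & stratum_ok[None, None, :]
        & (patch.d_patch_gm3 < auk_niche.threshold_gm3)
        & whale_only
    )
    biomass = acc_whale.accessible_g
    geo = float(biomass[out_of_area].sum())
    dep = float(biomass[wrong_depth].sum())
    thr = float(biomass[below_threshold].sum())
    return DiscrepancyShares(
        geography=geo / total,
        depth=dep / total,
        threshold=thr / total,
        total_g=total,
        valid=True,
    )
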