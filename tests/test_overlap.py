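"""Accessibility criteria, overlap, consumption and discrepancy attribution."""
import numpy as np
import pandas as pd
import pytest

import nichecast as nc
from nichecast.errors import InputError
from oracles import brute_force_accessible, brute_force_shared


def _flat_wm(nx=3, ny=3, depth=500.0):
    grid = nc.GridSpec(nx=nx, ny=ny)
    return nc.build_water_masses(grid, np.full((ny, nx), depth))


def _patch_from_biomass(biomass_g, phi, p, wm):
    strat = nc.StratifiedField(biomass_g=np.asarray(biomass_g, float), fractions=None)
    return nc.apply_patchiness(strat, phi, p, wm)


def _niche(wm, cells=None, strata=(1, 2, 3), threshold=9.4, population=1.0, ration=1.0,
           species="x"):
    grid = wm.grid
    if cells is None:
        cells = ~wm.is_land
    mask = nc.ForagingMask(species=species, cells=cells, grid=grid)
    return nc.PredatorNiche(
        species=species, mask=mask, strata=strata, threshold_gm3=threshold,
        population=population, ration_g_day=ration,
    )


def test_threshold_separates_predators():
    """A patch at 10 g/m^3 is accessible at threshold 9.4 but not at 13.7."""
    grid = nc.GridSpec(nx=1, ny=1, strata=((0.0, 20.0),))
    wm = nc.build_water_masses(grid, np.array([[20.0]]))
    # choose B so that d_patch = p*B/(phi*V) = 10.0 with patch biomass 1000 t
    phi, p = 0.084, 0.415
    b = 10.0 * phi * 8e9 / p
    patch = _patch_from_biomass(np.full((1, 1, 1), b), phi, p, wm)
    assert patch.d_patch_gm3[0, 0, 0] == pytest.approx(10.0)
    whale = _niche(wm, strata=(1,), threshold=9.4)
    auk = _niche(wm, strata=(1,), threshold=13.7)
    assert nc.accessible_biomass(patch, whale, wm).total_g == pytest.approx(p * b)
    assert nc.accessible_biomass(patch, auk, wm).total_g == 0.0


def test_vanishing_threshold_recovers_all_patch_biomass(small_inputs):
    wm = small_inputs.wm
    production = nc.biomass_to_production(small_inputs.clim.mean_gm2, nc.ProductionParams())
    strat = nc.stratify(production, (0.45, 0.35, 0.20), wm)
    patch = nc.apply_patchiness(strat, 0.084, 0.415, wm)
    niche = _niche(wm, threshold=1e-12)
    acc = nc.accessible_biomass(patch, niche, wm)
    assert acc.total_g == pytest.approx((patch.p * patch.biomass_g).sum(), rel=1e-12)
    assert sum(acc.by_stratum_g) == pytest.approx(acc.total_g, rel=1e-12)
    assert sum(acc.by_region_g.values()) == pytest.approx(acc.total_g, rel=1e-12)


def test_disallowed_stratum_is_never_accessible():
    wm = _flat_wm(1, 1)
    biomass = np.zeros((1, 1, 3))
    biomass[0, 0, 2] = 1e12  # all biomass in stratum 3
    patch = _patch_from_biomass(biomass, 0.084, 0.415, wm)
    auk = _niche(wm, strata=(1,), threshold=1e-9)
    assert nc.accessible_biomass(patch, auk, wm).total_g == 0.0


def test_oracle_equivalence_randomised():
    """Vectorised accessibility/overlap match the brute-force loop exactly."""
    rng = np.random.default_rng(12345)
    for case in range(60):
        ny, nx = rng.integers(1, 6, size=2)
        depth = rng.uniform(0, 300, size=(ny, nx))
        depth[rng.random((ny, nx)) < 0.2] = 0.0
        grid = nc.GridSpec(nx=int(nx), ny=int(ny))
        wm = nc.build_water_masses(grid, depth)
        biomass = rng.uniform(0, 1e12, size=wm.shape) * (wm.volume_m3 > 0)
        phi = rng.uniform(0.01, 0.5, size=wm.shape)
        p = rng.uniform(0.05, 1.0, size=wm.shape)
        patch = _patch_from_biomass(biomass, phi, p, wm)
        cells_a = ~wm.is_land & (rng.random((ny, nx)) < 0.7)
        niche_a = _niche(wm, cells=cells_a, strata=(1,), threshold=rng.uniform(0.1, 20))
        niche_b = _niche(wm, strata=(1, 2, 3), threshold=rng.uniform(0.1, 20))
        acc_a = nc.accessible_biomass(patch, niche_a, wm)
        acc_b = nc.accessible_biomass(patch, niche_b, wm)
        assert acc_a.total_g == pytest.approx(brute_force_accessible(patch, niche_a, wm), rel=1e-12)
        assert acc_b.total_g == pytest.approx(brute_force_accessible(patch, niche_b, wm), rel=1e-12)
        assert nc.shared_biomass(acc_a, acc_b) == pytest.approx(
            brute_force_shared(patch, niche_a, niche_b, wm), rel=1e-12
        )


def test_shared_biomass_set_semantics():
    """A accesses {1,2} worth (5,7), B accesses {2,3} worth (7,9) -> Qs=7."""
    wm = _flat_wm(3, 1)
    acc_a = nc.AccessibilityResult("a", np.array([[[5.0, 0, 0], [7.0, 0, 0], [0, 0, 0]]]),
                                   12.0, (12.0, 0, 0), {0: 12.0})
    acc_b = nc.AccessibilityResult("b", np.array([[[0.0, 0, 0], [7.0, 0, 0], [9.0, 0, 0]]]),
                                   16.0, (16.0, 0, 0), {0: 16.0})
    assert nc.shared_biomass(acc_a, acc_b) == 7.0


def test_identical_niches_fully_overlap(small_inputs):
    wm = small_inputs.wm
    production = nc.biomass_to_production(small_inputs.clim.mean_gm2, nc.ProductionParams())
    strat = nc.stratify(production, (0.45, 0.35, 0.20), wm)
    patch = nc.apply_patchiness(strat, 0.084, 0.415, wm)
    niche = _niche(wm, threshold=3.0)
    acc = nc.accessible_biomass(patch, niche, wm)
    ov = nc.overlap(acc, acc)
    assert ov.qs_g == ov.qa_g == ov.qb_g
    assert ov.w == 1.0 and ov.y == 1.0


def test_disjoint_masks_share_nothing():
    wm = _flat_wm(4, 1)
    biomass = np.full(wm.shape, 1e12)
    patch = _patch_from_biomass(biomass, 0.084, 0.415, wm)
    left = np.zeros((1, 4), dtype=bool); left[0, :2] = True
    right = ~left
    acc_l = nc.accessible_biomass(patch, _niche(wm, cells=left, threshold=1e-9), wm)
    acc_r = nc.accessible_biomass(patch, _niche(wm, cells=right, threshold=1e-9), wm)
    assert nc.shared_biomass(acc_l, acc_r) == 0.0


def test_overlap_invariants_w_qa_equals_y_qb(small_inputs):
    wm = small_inputs.wm
    production = nc.biomass_to_production(small_inputs.clim.mean_gm2, nc.ProductionParams())
    strat = nc.stratify(production, (0.45, 0.35, 0.20), wm)
    patch = nc.apply_patchiness(strat, 0.084, 0.415, wm)
    auk = _niche(wm, cells=small_inputs.auk_mask.cells, strata=(1,), threshold=13.7)
    whale = _niche(wm, strata=(1, 2, 3), threshold=9.4)
    acc_a = nc.accessible_biomass(patch, auk, wm)
    acc_w = nc.accessible_biomass(patch, whale, wm)
    ov = nc.overlap(acc_a, acc_w)
    assert ov.qs_g <= min(ov.qa_g, ov.qb_g) + 1e-9
    assert ov.w * ov.qa_g == pytest.approx(ov.y * ov.qb_g, rel=1e-12)
    # symmetry of the shared amount
    assert nc.shared_biomass(acc_a, acc_w) == nc.shared_biomass(acc_w, acc_a)


def test_q_monotone_in_threshold_and_mask(small_inputs):
    wm = small_inputs.wm
    production = nc.biomass_to_production(small_inputs.clim.mean_gm2, nc.ProductionParams())
    strat = nc.stratify(production, (0.45, 0.35, 0.20), wm)
    patch = nc.apply_patchiness(strat, 0.084, 0.415, wm)
    qs = [
        nc.accessible_biomass(patch, _niche(wm, threshold=t), wm).total_g
        for t in (0.5, 2.0, 5.0, 9.4, 13.7, 30.0)
    ]
    assert np.all(np.diff(qs) <= 0)
    small_mask = small_inputs.auk_mask.cells
    q_small = nc.accessible_biomass(patch, _niche(wm, cells=small_mask, threshold=9.4), wm).total_g
    q_full = nc.accessible_biomass(patch, _niche(wm, threshold=9.4), wm).total_g
    assert q_small <= q_full


def test_consumption_demand_cap_and_worked_example():
    wm = _flat_wm(1, 1)
    whale = _niche(wm, population=50_000, ration=1.413e6)
    cons = nc.consumption(whale, 18.7e12)
    assert cons.demand_g == pytest.approx(6.4998e12)
    assert cons.consumed_g == pytest.approx(6.4998e12)
    assert cons.fraction == pytest.approx(0.3476, abs=2e-4)
    assert not cons.insufficient

    zero = nc.consumption(_niche(wm, population=0, ration=1.0), 1e12)
    assert zero.consumed_g == 0.0

    capped = nc.consumption(whale, 1e12)
    assert capped.consumed_g == 1e12 and capped.insufficient
    assert 0 <= capped.fraction <= 1


def test_decompose_discrepancy_constructed_split():
    """Three whale-only masses engineered to give shares (0.83, 0.09, 0.08)."""
    wm = _flat_wm(3, 1)
    phi, p = 0.084, 1.0  # p=1 so accessible biomass equals total biomass
    v = wm.volume_m3
    biomass = np.zeros(wm.shape)
    # mass A: stratum 1, dense, outside auk area -> geography, 83 t
    biomass[0, 0, 0] = 83e6
    # mass B: stratum 2 inside auk area -> depth, 9 t
    biomass[0, 1, 1] = 9e6
    # mass C: stratum 1 inside auk area, density between thresholds -> threshold, 8 t
    biomass[0, 2, 0] = 8e6
    patch = _patch_from_biomass(biomass, phi, p, wm)
    # engineer densities: scale phi per water mass so d_patch straddles the thresholds
    d = patch.d_patch_gm3
    assert d[0, 0, 0] > 0 and d[0, 1, 1] > 0 and d[0, 2, 0] > 0
    phi_arr = np.full(wm.shape, 0.5)
    phi_arr[0, 0, 0] = biomass[0, 0, 0] / (20.0 * v[0, 0, 0])  # d = 20 g/m^3
    phi_arr[0, 1, 1] = biomass[0, 1, 1] / (20.0 * v[0, 1, 1])
    phi_arr[0, 2, 0] = biomass[0, 2, 0] / (11.0 * v[0, 2, 0])  # between 9.4 and 13.7
    patch = _patch_from_biomass(biomass, phi_arr, p, wm)
    auk_cells = np.array([[False, True, True]])
    auk = _niche(wm, cells=auk_cells, strata=(1,), threshold=13.7, species="auk")
    whale = _niche(wm, strata=(1, 2, 3), threshold=9.4, species="whale")
    acc_w = nc.accessible_biomass(patch, whale, wm)
    acc_a = nc.accessible_biomass(patch, auk, wm)
    assert acc_w.total_g == pytest.approx(100e6)
    assert acc_a.total_g == 0.0
    shares = nc.decompose_discrepancy(patch, wm, whale, auk, acc_w, acc_a)
    assert shares.valid
    assert (shares.geography, shares.depth, shares.threshold) == pytest.approx(
        (0.83, 0.09, 0.08), rel=1e-12
    )


def test_decompose_discrepancy_all_geography():
    wm = _flat_wm(2, 1)
    biomass = np.full(wm.shape, 1e12)
    patch = _patch_from_biomass(biomass, 0.084, 0.415, wm)
    auk_cells = np.zeros((1, 2), dtype=bool)  # auk excluded everywhere
    auk = _niche(wm, cells=auk_cells, strata=(1,), threshold=13.7)
    whale = _niche(wm, threshold=1e-9)
    acc_w = nc.accessible_biomass(patch, whale, wm)
    acc_a = nc.accessible_biomass(patch, auk, wm)
    shares = nc.decompose_discrepancy(patch, wm, whale, auk, acc_w, acc_a)
    assert (shares.geography, shares.depth, shares.threshold) == (1.0, 0.0, 0.0)
    assert shares.geography + shares.depth + shares.threshold == pytest.approx(1.0, abs=1e-9)


def test_decompose_discrepancy_no_discrepancy_flagged():
    wm = _flat_wm(1, 1)
    biomass = np.full(wm.shape, 1e12)
    patch = _patch_from_biomass(biomass, 0.084, 0.415, wm)
    niche = _niche(wm, threshold=1e-9)
    acc = nc.accessible_biomass(patch, niche, wm)
    shares = nc.decompose_discrepancy(patch, wm, niche, niche, acc, acc)
    assert not shares.valid


def test_niche_validation():
    wm = _flat_wm(1, 1)
    with pytest.raises(InputError):
        _niche(wm, strata=())
    with pytest.raises(InputError):
        _niche(wm, threshold=0.0)
    with pytest.raises(InputError):
        _niche(wm, population=-1)
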