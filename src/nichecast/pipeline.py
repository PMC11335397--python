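"""Pipeline orchestration: fixtures -> simulation inputs -> runs -> reports."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import RunConfig, default_ledger
from .grid import auk_foraging_mask, build_water_masses, whale_foraging_mask
from .io import read_fixture
from .montecarlo import (
    MCRecord,
    MCSummary,
    SimulationInputs,
    mean_draw,
    run_iteration,
)
from .plankton import GRAMS_PER_MEGATONNE
from .synthetic import (
    BiomassClimatology,
    SyntheticDomain,
    generate_biomass_field,
    generate_colonies,
    generate_domain,
)


def generate_fixture(
    config: RunConfig, seed: int
) -> tuple[SyntheticDomain, BiomassClimatology, pd.DataFrame]:
    """Generate the synthetic domain, biomass climatology and colonies."""
    syn = config.synthetic
    domain = generate_domain(
        seed=seed,
        nx=config.grid.nx,
        ny=config.grid.ny,
        cell_side_km=config.grid.cell_side_km,
        land_fraction=syn.land_fraction,
        n_islands=syn.n_islands,
        margin_km=syn.margin_km,
        foraging_radius_km=config.niches.foraging_radius_km,
    )
    clim = generate_biomass_field(
        domain,
        seed=seed + 1,
        mean_density_gm2=syn.mean_density_gm2,
        cv_spatial=syn.cv_spatial,
        correlation_length_km=syn.correlation_length_km,
        block_size_cells=syn.block_size_cells,
    )
    colonies = generate_colonies(
        domain, seed=seed + 2, n_colonies=syn.n_colonies, total_pairs=syn.total_pairs
    )
    return domain, clim, colonies


def build_inputs(
    config: RunConfig,
    domain: SyntheticDomain,
    clim: BiomassClimatology,
    colonies: pd.DataFrame,
) -> SimulationInputs:
    """Assemble water masses and foraging masks into frozen simulation inputs."""
    wm = build_water_masses(domain.grid, domain.seafloor_depth_m, domain.region_id)
    whale_mask = whale_foraging_mask(domain.grid, domain.is_land)
    auk_mask = auk_foraging_mask(
        domain.grid,
        colonies,
        radius_km=config.niches.foraging_radius_km,
        is_land=domain.is_land,
    )
    return SimulationInputs(
        wm=wm,
        clim=clim,
        auk_mask=auk_mask,
        whale_mask=whale_mask,
        auk_strata=tuple(config.niches.little_auk.strata),
        whale_strata=tuple(config.niches.bowhead.strata),
        season_days=config.niches.season_days,
    )


def prepare_synthetic_inputs(config: RunConfig, seed: int) -> SimulationInputs:
    """Generate a fixture and wrap it as simulation inputs in one step."""
    domain, clim, colonies = generate_fixture(config, seed)
    return build_inputs(config, domain, clim, colonies)


def prepare_inputs_from_dir(config: RunConfig, fixture_dir: str | Path) -> SimulationInputs:
    """Load a fixture directory and wrap it as simulation inputs."""
    domain, clim, colonies = read_fixture(fixture_dir)
    return build_inputs(config, domain, clim, colonies)


def deterministic_run(config: RunConfig, inputs: SimulationInputs) -> MCRecord:
    """Single run with every ledger parameter at its point value."""
    ledger = default_ledger(config)
    return run_iteration(mean_draw(ledger, inputs), inputs)


_MT_KEYS = {
    "b_total_g": "B_Mt",
    "patch_biomass_g": "patch_biomass_Mt",
    "qa_g": "Qa_Mt",
    "qb_g": "Qb_Mt",
    "qs_g": "Qs_Mt",
    "cb17_g": "Cb17_Mt",
    "cb21_g": "Cb21_Mt",
    "ca21_g": "Ca21_Mt",
    "release_g": "release_Mt",
    "qb_s1_g": "Qb_stratum1_Mt",
    "qb_s2_g": "Qb_stratum2_Mt",
    "qb_s3_g": "Qb_stratum3_Mt",
}
_PCT_KEYS = {
    "patch_volume_frac": "patch_volume_pct",
    "patch_biomass_frac": "patch_biomass_pct",
    "w": "W_pct",
    "y": "Y_pct",
    "za": "Za_pct",
    "consumed_frac_b17": "whale_consumed_frac_17_pct",
    "consumed_frac_b21": "whale_consumed_frac_21_pct",
    "consumed_frac_a21": "auk_consumed_frac_21_pct",
    "share_geography": "discrepancy_geography_pct",
    "share_depth": "discrepancy_depth_pct",
    "share_threshold": "discrepancy_threshold_pct",
}


def humanize_outputs(outputs: dict[str, float]) -> dict[str, float]:
    """Convert a raw gram-scale output dict to reporting units (Mt, %, pairs)."""
    out: dict[str, float] = {}
    for key, val in outputs.items():
        if key in _MT_KEYS:
            out[_MT_KEYS[key]] = val / GRAMS_PER_MEGATONNE
        elif key in _PCT_KEYS:
            out[_PCT_KEYS[key]] = val * 100.0
        elif key == "na17_pairs":
            out["Na17_Mpairs"] = val / 1e6
        else:
            out[key] = val
    return out


def report_deterministic(record: MCRecord) -> str:
    """Human-readable one-value-per-quantity report of a deterministic run."""
    lines = ["Deterministic (all-means) run", "-" * 33]
    if not record.valid:
        lines.append(f"RUN INVALID: {record.reason}")
    for key, val in humanize_outputs(record.outputs).items():
        lines.append(f"{key:32s} {val:,.4g}")
    return "\n".join(lines)


def report_mc(summary: MCSummary) -> str:
    """Human-readable table of means and 95% prediction intervals."""
    lines = [
        f"Monte Carlo summary  (seed={summary.seed}, n={summary.n_iter}, "
        f"retained={summary.n_retained}, discarded={summary.discard_fraction:.1%})",
        "-" * 72,
        f"{'output':32s} {'mean':>12s} {'2.5%':>12s} {'97.5%':>12s}",
    ]
    for name, row in summary.table.iterrows():
        lines.append(
            f"{name:32s} {row['mean']:>12.4g} {row['p2_5']:>12.4g} {row['p97_5']:>12.4g}"
        )
    if summary.reason_counts:
        lines.append("discard reasons: " + ", ".join(
            f"{k}={v}" for k, v in sorted(summary.reason_counts.items())
        ))
    return "\n".join(lines)
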