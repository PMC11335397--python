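"""Fixture and result file I/O.

Gridded fields travel as NetCDF (classic format via the scipy backend, so no
compiled NetCDF4 library is required) with dimensions ``(y, x)`` for cell
fields and ``(yb, xb)`` for block aggregates; colonies as CSV with header
``x_km,y_km,pairs``; summaries as JSON.  Every file carries the generating
seed and package version in its metadata.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .errors import InputError
from .grid import GridSpec
from .synthetic import BiomassClimatology, SyntheticDomain, REGION_NAMES

DOMAIN_FILE = "domain.nc"
COLONIES_FILE = "colonies.csv"


def write_fixture(
    out_dir: str | Path,
    domain: SyntheticDomain,
    clim: BiomassClimatology,
    colonies: pd.DataFrame,
    seed: int,
) -> Path:
    """Write a complete synthetic fixture (NetCDF + colonies CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = domain.grid
    ds = xr.Dataset(
        data_vars={
            "seafloor_depth_m": (("y", "x"), domain.seafloor_depth_m),
            "region_id": (("y", "x"), domain.region_id.astype(np.int32)),
            "biomass_mean_gm2": (("y", "x"), clim.mean_gm2),
            "biomass_block_mean_gm2": (("yb", "xb"), clim.block_mean_gm2),
            "biomass_block_sd_gm2": (("yb", "xb"), clim.block_sd_gm2),
        },
        attrs={
            "cell_side_km": grid.cell_side_km,
            "strata_bounds_m": [b for pair in grid.strata for b in pair],
            "block_size_cells": clim.block_size_cells,
            "seed": seed,
            "version": __version__,
            "region_names": json.dumps(domain.region_names),
        },
    )
    ds.to_netcdf(out / DOMAIN_FILE, engine="scipy")
    colonies.to_csv(out / COLONIES_FILE, index=False)
    return out


def read_fixture(fixture_dir: str | Path) -> tuple[SyntheticDomain, BiomassClimatology, pd.DataFrame]:
    """Load a fixture directory written by :func:`write_fixture`."""
    fixture_dir = Path(fixture_dir)
    nc = fixture_dir / DOMAIN_FILE
    csv = fixture_dir / COLONIES_FILE
    if not nc.exists() or not csv.exists():
        raise InputError(f"fixture directory {fixture_dir} is missing {DOMAIN_FILE} or {COLONIES_FILE}")
    with xr.open_dataset(nc, engine="scipy") as ds:
        ds = ds.load()
    bounds = list(ds.attrs["strata_bounds_m"])
    strata = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))
    depth = ds["seafloor_depth_m"].to_numpy()
    grid = GridSpec(
        nx=depth.shape[1],
        ny=depth.shape[0],
        cell_side_km=float(ds.attrs["cell_side_km"]),
        strata=strata,
    )
    try:
        region_names = {int(k): v for k, v in json.loads(ds.attrs["region_names"]).items()}
    except (KeyError, ValueError):
        region_names = dict(REGION_NAMES)
    domain = SyntheticDomain(
        grid=grid,
        seafloor_depth_m=depth,
        is_land=depth == 0,
        region_id=ds["region_id"].to_numpy().astype(int),
        region_names=region_names,
    )
    clim = BiomassClimatology(
        grid=grid,
        mean_gm2=ds["biomass_mean_gm2"].to_numpy(),
        block_mean_gm2=ds["biomass_block_mean_gm2"].to_numpy(),
        block_sd_gm2=ds["biomass_block_sd_gm2"].to_numpy(),
        block_size_cells=int(ds.attrs["block_size_cells"]),
    )
    colonies = pd.read_csv(csv)
    for col in ("x_km", "y_km", "pairs"):
        if col not in colonies.columns:
            raise InputError(f"colonies.csv is missing column {col!r}")
    return domain, clim, colonies


def write_json(data: dict, path: str | Path, seed: int | None = None) -> None:
    """Write a JSON result file stamped with version (and seed if given)."""
    payload = dict(data)
    payload.setdefault("version", __version__)
    if seed is not None:
        payload.setdefault("seed", seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
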