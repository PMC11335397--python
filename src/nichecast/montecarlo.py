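"""Monte Carlo uncertainty propagation and ANOVA sensitivity analysis.

Each iteration draws the full parameter ledger (global scalars once,
patchiness intensities independently per water mass, biomass once per
coarse block), reruns the prey-field -> niche-overlap -> backcast chain,
and is screened out as unrealistic when a predator's seasonal demand
exceeds the biomass accessible to it, or when the backcast arithmetic turns
pathological (competitive share outside [0, 1], negative abundance).
Summaries (mean and 2.5/97.5 empirical percentiles) are computed over
retained iterations only.

Reproducibility: a master seed spawns one independent substream per
iteration via ``numpy``'s ``SeedSequence``, so results are identical for a
fixed ``(seed, ledger, fixtures)`` triple regardless of execution order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from . import __version__
from .backcast import BackcastInputs, backcast_na17, competitive_share
from .config import ParameterSpec
from .errors import AllIterationsDiscardedError, InputError
from .grid import ForagingMask, WaterMassGrid
from .overlap import (
    PredatorNiche,
    accessible_biomass,
    consumption,
    decompose_discrepancy,
    overlap,
)
from .plankton import (
    ProductionParams,
    apply_patchiness,
    biomass_to_production,
    stratify,
    summarize_field,
)
from .synthetic import BiomassClimatology

#: column order of per-iteration sampled globals in the records table
GLOBAL_PARAM_COLUMNS = [
    "na21_pairs", "nb17", "nb21",
    "threshold_bowhead_gm3", "threshold_auk_gm3",
    "ration_bowhead_g_day", "ration_auk_g_day",
    "pb_ratio", "season_fraction", "copepod_to_meso",
    "stratum_f1", "stratum_f2", "stratum_f3",
]
FIELD_SUMMARY_COLUMNS = ["phi_mean", "p_mean", "biomass_mean_gm2"]
OUTPUT_COLUMNS = [
    "b_total_g", "patch_volume_frac", "patch_biomass_g", "patch_biomass_frac",
    "qa_g", "qb_g", "qs_g", "w", "y",
    "qb_s1_g", "qb_s2_g", "qb_s3_g",
    "demand_b17_g", "cb17_g", "consumed_frac_b17",
    "demand_b21_g", "cb21_g", "consumed_frac_b21",
    "demand_a21_g", "ca21_g", "consumed_frac_a21",
    "release_g", "za", "na17_pairs",
    "share_geography", "share_depth", "share_threshold",
]


@dataclass
class SimulationInputs:
    """Frozen fixtures one simulation runs against."""

    wm: WaterMassGrid
    clim: BiomassClimatology
    auk_mask: ForagingMask
    whale_mask: ForagingMask
    auk_strata: tuple[int, ...]
    whale_strata: tuple[int, ...]
    season_days: int = 92


@dataclass
class ParameterDraw:
    """One iteration's sampled parameters."""

    globals: dict[str, float]
    phi: np.ndarray
    p: np.ndarray
    biomass_gm2: np.ndarray

    def stratum_fractions(self) -> np.ndarray:
        f = np.array(
            [self.globals["stratum_f1"], self.globals["stratum_f2"], self.globals["stratum_f3"]]
        )
        s = f.sum()
        if s <= 0:
            raise InputError("drawn stratum fractions sum to zero")
        return f / s


@dataclass
class MCRecord:
    """Outputs and sampled parameters of one iteration."""

    iteration: int
    params: dict[str, float]
    outputs: dict[str, float]
    valid: bool
    reason: str | None = None

    def row(self) -> dict:
        row = {"iteration": self.iteration, "valid": self.valid, "reason": self.reason or ""}
        row.update(self.params)
        for k in OUTPUT_COLUMNS:
            row[k] = self.outputs.get(k, np.nan)
        return row


@dataclass
class MCSummary:
    """Percentile summary over retained iterations."""

    table: pd.DataFrame  # index: output name; columns: mean, p2_5, p97_5
    n_iter: int
    n_retained: int
    reason_counts: dict[str, int]
    seed: int

    @property
    def discard_fraction(self) -> float:
        return 1.0 - self.n_retained / self.n_iter

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "n_retained": self.n_retained,
            "discard_fraction": self.discard_fraction,
            "reason_counts": dict(sorted(self.reason_counts.items())),
            "outputs": {
                name: {
                    "mean": row["mean"], "p2_5": row["p2_5"], "p97_5": row["p97_5"]
                }
                for name, row in self.table.iterrows()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


@dataclass
class MCResult:
    records: pd.DataFrame
    summary: MCSummary


def _block_perturbed_biomass(
    clim: BiomassClimatology, spec: ParameterSpec, rng: np.random.Generator, sea: np.ndarray
) -> np.ndarray:
    """Redraw each coarse block's mean biomass as Normal(mean, SD) truncated
    at zero and rescale the block's cells proportionally.

    The ledger entry's ``mean``/``sd`` act as multipliers on the per-block
    climatological mean and SD, so ``sd = 0`` reproduces the climatology.
    """
    fld = clim.mean_gm2.copy()
    if spec.dist == "fixed" or spec.sd == 0:
        return fld
    bs = clim.block_size_cells
    nb_y, nb_x = clim.block_mean_gm2.shape
    for bi in range(nb_y):
        for bj in range(nb_x):
            mu = clim.block_mean_gm2[bi, bj] * spec.mean
            sd = clim.block_sd_gm2[bi, bj] * spec.sd
            if mu <= 0 or sd == 0:
                continue
            draw = rng.normal(mu, sd)
            for _ in range(1000):
                if draw >= 0:
                    break
                draw = rng.normal(mu, sd)
            else:
                draw = 0.0
            sl = (slice(bi * bs, (bi + 1) * bs), slice(bj * bs, (bj + 1) * bs))
            fld[sl] *= draw / mu
    fld[~sea] = 0.0
    return fld


def sample_parameters(
    ledger: dict[str, ParameterSpec],
    rng: np.random.Generator,
    inputs: SimulationInputs,
) -> ParameterDraw:
    """Draw one iteration's parameters from the ledger."""
    shape = inputs.wm.shape
    sea = ~inputs.wm.is_land
    globals_ = {
        name: ledger[name].sample(rng) for name in GLOBAL_PARAM_COLUMNS
    }
    globals_["season_days"] = ledger["season_days"].point_value
    phi = ledger["phi"].sample(rng, size=shape)
    p = ledger["p"].sample(rng, size=shape)
    biomass = _block_perturbed_biomass(inputs.clim, ledger["biomass_block"], rng, sea)
    return ParameterDraw(
        globals=globals_,
        phi=np.asarray(phi, dtype=float),
        p=np.asarray(p, dtype=float),
        biomass_gm2=biomass,
    )


def mean_draw(ledger: dict[str, ParameterSpec], inputs: SimulationInputs) -> ParameterDraw:
    """All-means (point-value) draw: the deterministic scenario."""
    shape = inputs.wm.shape
    globals_ = {name: ledger[name].point_value for name in GLOBAL_PARAM_COLUMNS}
    globals_["season_days"] = ledger["season_days"].point_value
    return ParameterDraw(
        globals=globals_,
        phi=np.full(shape, ledger["phi"].point_value),
        p=np.full(shape, ledger["p"].point_value),
        biomass_gm2=inputs.clim.mean_gm2.copy(),
    )


def run_iteration(
    draw: ParameterDraw, inputs: SimulationInputs, iteration: int = 0
) -> MCRecord:
    """Run the full model chain for one parameter draw.

    Module errors and the screening rules produce a discarded record with a
    reason, never a crash.
    """
    g = draw.globals
    params_row = {k: g[k] for k in GLOBAL_PARAM_COLUMNS}
    sea = ~inputs.wm.is_land
    params_row["phi_mean"] = float(draw.phi.mean())
    params_row["p_mean"] = float(draw.p.mean())
    params_row["biomass_mean_gm2"] = float(draw.biomass_gm2[sea].mean()) if sea.any() else 0.0
    outputs: dict[str, float] = {}

    def record(valid: bool, reason: str | None = None) -> MCRecord:
        return MCRecord(iteration, params_row, outputs, valid, reason)

    try:
        prod_params = ProductionParams(
            pb_ratio=g["pb_ratio"],
            season_fraction=g["season_fraction"],
            copepod_to_meso=g["copepod_to_meso"],
        )
        production = biomass_to_production(draw.biomass_gm2, prod_params)
        strat = stratify(production, draw.stratum_fractions(), inputs.wm)
        patch = apply_patchiness(strat, draw.phi, draw.p, inputs.wm)
        summary = summarize_field(patch, inputs.wm)
        outputs["b_total_g"] = summary.total_production_g
        outputs["patch_volume_frac"] = summary.patch_volume_fraction
        outputs["patch_biomass_g"] = summary.patch_biomass_g
        outputs["patch_biomass_frac"] = summary.patch_biomass_fraction

        season = int(round(g["season_days"]))
        auk_niche = PredatorNiche(
            species="little_auk",
            mask=inputs.auk_mask,
            strata=inputs.auk_strata,
            threshold_gm3=g["threshold_auk_gm3"],
            population=2.0 * g["na21_pairs"],  # breeders
            ration_g_day=g["ration_auk_g_day"],
            season_days=season,
        )
        whale17 = PredatorNiche(
            species="bowhead_17c",
            mask=inputs.whale_mask,
            strata=inputs.whale_strata,
            threshold_gm3=g["threshold_bowhead_gm3"],
            population=g["nb17"],
            ration_g_day=g["ration_bowhead_g_day"],
            season_days=season,
        )
        whale21 = PredatorNiche(
            species="bowhead_21c",
            mask=inputs.whale_mask,
            strata=inputs.whale_strata,
            threshold_gm3=g["threshold_bowhead_gm3"],
            population=g["nb21"],
            ration_g_day=g["ration_bowhead_g_day"],
            season_days=season,
        )

        acc_auk = accessible_biomass(patch, auk_niche, inputs.wm)
        acc_whale = accessible_biomass(patch, whale17, inputs.wm)
        ov = overlap(acc_auk, acc_whale)
        outputs.update(
            qa_g=ov.qa_g, qb_g=ov.qb_g, qs_g=ov.qs_g, w=ov.w, y=ov.y,
            qb_s1_g=acc_whale.by_stratum_g[0],
            qb_s2_g=acc_whale.by_stratum_g[1] if len(acc_whale.by_stratum_g) > 1 else 0.0,
            qb_s3_g=acc_whale.by_stratum_g[2] if len(acc_whale.by_stratum_g) > 2 else 0.0,
        )
        shares = decompose_discrepancy(patch, inputs.wm, whale17, auk_niche, acc_whale, acc_auk)
        if shares.valid:
            outputs.update(
                share_geography=shares.geography,
                share_depth=shares.depth,
                share_threshold=shares.threshold,
            )

        cons_b17 = consumption(whale17, ov.qb_g)
        cons_b21 = consumption(whale21, ov.qb_g)
        cons_a21 = consumption(auk_niche, ov.qa_g)
        outputs.update(
            demand_b17_g=cons_b17.demand_g, cb17_g=cons_b17.consumed_g,
            consumed_frac_b17=cons_b17.fraction,
            demand_b21_g=cons_b21.demand_g, cb21_g=cons_b21.consumed_g,
            consumed_frac_b21=cons_b21.fraction,
            demand_a21_g=cons_a21.demand_g, ca21_g=cons_a21.consumed_g,
            consumed_frac_a21=cons_a21.fraction,
        )
        if cons_b17.insufficient:
            return record(False, "insufficient_bowhead_17")
        if cons_b21.insufficient:
            return record(False, "insufficient_bowhead_21")
        if cons_a21.insufficient:
            return record(False, "insufficient_auk_21")

        za = competitive_share(cons_a21.consumed_g, ov.qa_g, cons_b21.consumed_g, ov.y)
        outputs["za"] = za
        if not np.isfinite(za) or not 0 <= za <= 1:
            return record(False, "invalid_za")
        bc_inputs = BackcastInputs(
            na21_pairs=g["na21_pairs"],
            ca21=cons_a21.consumed_g,
            cb17=cons_b17.consumed_g,
            cb21=cons_b21.consumed_g,
            qa=ov.qa_g,
            y=ov.y,
        )
        bc = backcast_na17(bc_inputs, za)
        outputs["release_g"] = bc.release
        outputs["na17_pairs"] = bc.na17_pairs
        if not bc.valid:
            return record(False, "negative_na17")
        return record(True)
    except Exception as exc:  # unrealistic draw, not a crash
        return record(False, f"error:{type(exc).__name__}:{exc}")


def summarize_records(records: pd.DataFrame, seed: int) -> MCSummary:
    """Mean and 2.5/97.5 percentiles of every output over retained records."""
    retained = records[records["valid"]]
    if retained.empty:
        counts = records["reason"].value_counts().to_dict()
        raise AllIterationsDiscardedError(
            f"all {len(records)} iterations were discarded; reasons: {counts}"
        )
    rows = {}
    for col in OUTPUT_COLUMNS:
        vals = retained[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        rows[col] = {
            "mean": float(vals.mean()),
            "p2_5": float(np.percentile(vals, 2.5)),
            "p97_5": float(np.percentile(vals, 97.5)),
        }
    reasons = (
        records.loc[~records["valid"], "reason"].value_counts().to_dict()
    )
    return MCSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        n_iter=len(records),
        n_retained=len(retained),
        reason_counts={str(k): int(v) for k, v in reasons.items()},
        seed=seed,
    )


def run_mc(
    inputs: SimulationInputs,
    ledger: dict[str, ParameterSpec],
    n_iter: int,
    seed: int,
    records_path: str | Path | None = None,
) -> MCResult:
    """Run ``n_iter`` independent iterations and summarise retained ones."""
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_iter)
    rows = []
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        draw = sample_parameters(ledger, rng, inputs)
        rows.append(run_iteration(draw, inputs, iteration=it).row())
    records = pd.DataFrame(rows)
    if records_path is not None:
        records.to_csv(records_path, index=False)
    summary = summarize_records(records, seed=seed)
    return MCResult(records=records, summary=summary)


@dataclass
class SensitivityResult:
    """Variance shares of the backcast abundance by ledger parameter."""

    shares: pd.Series
    residual: float
    dropped: list[str] = field(default_factory=list)
    response: str = "na17_pairs"


def anova_sensitivity(
    records: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    response: str = "na17_pairs",
    min_records: int = 50,
) -> SensitivityResult:
    """Main-effects ANOVA variance decomposition of a Monte Carlo output.

    Fits an ordinary least-squares model of the response on the sampled
    parameter values of retained iterations (per-water-mass fields enter
    through their iteration means) and reports each parameter's sequential
    (type I) sum of squares as a share of the total.  Draws are independent,
    so the sequential shares are effectively order-free; the unexplained
    share is reported as the residual.
    """
    if parameters is None:
        parameters = [
            c for c in GLOBAL_PARAM_COLUMNS + FIELD_SUMMARY_COLUMNS if c in records.columns
        ]
    if "valid" in records.columns:
        records = records[records["valid"]]
    records = records.dropna(subset=[response])
    if len(records) < min_records:
        raise InputError(
            f"need at least {min_records} retained records for the ANOVA, got {len(records)}"
        )
    dropped = [p for p in parameters if records[p].nunique() <= 1]
    kept = [p for p in parameters if p not in dropped]
    if not kept:
        raise InputError("no varying parameters to decompose")

    df = records[kept + [response]].reset_index(drop=True)
    model = ols(f"{response} ~ {' + '.join(kept)}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    total_ss = table["sum_sq"].sum()
    shares = (table["sum_sq"] / total_ss).drop("Residual")
    if dropped:
        shares = pd.concat([shares, pd.Series({p: 0.0 for p in dropped})])
    shares = shares.sort_values(ascending=False)
    residual = float(table.loc["Residual", "sum_sq"] / total_ss)
    return SensitivityResult(shares=shares, residual=residual, dropped=dropped, response=response)
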