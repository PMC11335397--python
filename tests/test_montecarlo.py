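"""Monte Carlo machinery: sampling, screening, determinism and ANOVA."""
import numpy as np
import pandas as pd
import pytest

import nichecast as nc
from nichecast.config import ParameterSpec
from nichecast.errors import AllIterationsDiscardedError, InputError
from nichecast.montecarlo import summarize_records


def _zero_sd_ledger(config):
    ledger = nc.default_ledger(config)
    return {
        name: spec.model_copy(update={"sd": 0.0}) for name, spec in ledger.items()
    }


def test_parameter_spec_validation():
    with pytest.raises(ValueError):
        ParameterSpec(name="x", dist="normal", mean=0.0, sd=-1.0)
    with pytest.raises(ValueError):
        ParameterSpec(name="x", dist="fixed", mean=1.0, sd=0.5)
    with pytest.raises(ValueError):
        ParameterSpec(name="x", dist="normal", mean=5.0, sd=1.0, lower=10.0, upper=2.0)


def test_normal_draw_quantiles():
    """~95% of Normal(9.4, 1) draws fall in [7.44, 11.36]."""
    spec = ParameterSpec(name="threshold", dist="normal", mean=9.4, sd=1.0)
    rng = np.random.default_rng(0)
    draws = spec.sample(rng, size=10_000)
    inside = np.mean((draws >= 9.4 - 1.96) & (draws <= 9.4 + 1.96))
    assert inside == pytest.approx(0.95, abs=0.01)


def test_truncation_respected():
    spec = ParameterSpec(name="frac", dist="normal", mean=0.9, sd=0.3, lower=0.0, upper=1.0)
    draws = spec.sample(np.random.default_rng(1), size=5000)
    assert draws.min() >= 0.0 and draws.max() <= 1.0


def test_lognormal_median_and_interval():
    spec = ParameterSpec(name="thr", dist="lognormal", mean=13.7, sd=0.267, lower=0.0)
    draws = spec.sample(np.random.default_rng(2), size=20_000)
    assert np.median(draws) == pytest.approx(13.7, rel=0.02)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    assert lo == pytest.approx(8.1, rel=0.05)
    assert hi == pytest.approx(23.1, rel=0.05)


def test_sample_determinism(small_config, small_inputs):
    ledger = nc.default_ledger(small_config)
    a = nc.sample_parameters(ledger, np.random.default_rng(42), small_inputs)
    b = nc.sample_parameters(ledger, np.random.default_rng(42), small_inputs)
    assert a.globals == b.globals
    assert np.array_equal(a.phi, b.phi)
    assert np.array_equal(a.p, b.p)
    assert np.array_equal(a.biomass_gm2, b.biomass_gm2)


def test_zero_sd_draw_equals_means(small_config, small_inputs):
    ledger = _zero_sd_ledger(small_config)
    draw = nc.sample_parameters(ledger, np.random.default_rng(0), small_inputs)
    mean = nc.mean_draw(ledger, small_inputs)
    assert draw.globals == mean.globals
    assert np.array_equal(draw.phi, mean.phi)
    assert np.array_equal(draw.biomass_gm2, mean.biomass_gm2)


def test_mean_draw_runs_valid_with_na17_below_na21(small_config, small_inputs):
    record = nc.deterministic_run(small_config, small_inputs)
    assert record.valid, record.reason
    assert record.outputs["na17_pairs"] < record.params["na21_pairs"]
    assert record.outputs["cb17_g"] > record.outputs["cb21_g"]


def test_forced_demand_breach_is_discarded(small_config, small_inputs):
    """A 5-million-whale scenario must blow past Qb and be screened out."""
    ledger = nc.default_ledger(small_config)
    draw = nc.mean_draw(ledger, small_inputs)
    draw.globals["nb17"] = 5e6
    record = nc.run_iteration(draw, small_inputs)
    assert not record.valid and record.reason == "insufficient_bowhead_17"


def test_equal_whale_populations_leave_auks_unchanged(small_config, small_inputs):
    ledger = nc.default_ledger(small_config)
    draw = nc.mean_draw(ledger, small_inputs)
    draw.globals["nb17"] = draw.globals["nb21"]
    record = nc.run_iteration(draw, small_inputs)
    assert record.valid
    assert record.outputs["na17_pairs"] == pytest.approx(draw.globals["na21_pairs"], rel=1e-12)


def test_module_error_recorded_not_raised(small_config, small_inputs):
    ledger = nc.default_ledger(small_config)
    draw = nc.mean_draw(ledger, small_inputs)
    draw.globals["pb_ratio"] = -1.0  # invalid production parameter
    record = nc.run_iteration(draw, small_inputs)
    assert not record.valid and record.reason.startswith("error:")


def test_run_mc_deterministic_given_seed(small_config, small_inputs):
    ledger = nc.default_ledger(small_config)
    a = nc.run_mc(small_inputs, ledger, n_iter=40, seed=11)
    b = nc.run_mc(small_inputs, ledger, n_iter=40, seed=11)
    assert a.summary.to_json() == b.summary.to_json()
    pd.testing.assert_frame_equal(a.records, b.records)
    c = nc.run_mc(small_inputs, ledger, n_iter=40, seed=12)
    assert c.summary.to_json() != a.summary.to_json()


def test_run_mc_zero_sd_records_identical(small_config, small_inputs):
    ledger = _zero_sd_ledger(small_config)
    result = nc.run_mc(small_inputs, ledger, n_iter=10, seed=3)
    outputs = result.records[["qa_g", "qb_g", "na17_pairs"]]
    assert (outputs.nunique() == 1).all()
    det = nc.deterministic_run(small_config, small_inputs)
    # zero-spread MC mean equals the deterministic value exactly
    assert result.summary.table.loc["na17_pairs", "mean"] == det.outputs["na17_pairs"]
    assert result.summary.discard_fraction == 0.0


def test_summary_excludes_discarded_iterations(small_config, small_inputs):
    ledger = nc.default_ledger(small_config)
    result = nc.run_mc(small_inputs, ledger, n_iter=60, seed=5)
    records = result.records
    retained = records[records["valid"]]
    assert result.summary.n_retained == len(retained)
    assert sum(result.summary.reason_counts.values()) == len(records) - len(retained)
    mx = result.summary.table.loc["na17_pairs", "p97_5"]
    assert mx <= retained["na17_pairs"].max() + 1e-9


def test_all_discarded_raises():
    records = pd.DataFrame(
        {"valid": [False, False], "reason": ["insufficient_auk_21"] * 2, "na17_pairs": [np.nan] * 2}
    )
    with pytest.raises(AllIterationsDiscardedError):
        summarize_records(records, seed=0)


def test_run_mc_rejects_bad_n(small_config, small_inputs):
    with pytest.raises(InputError):
        nc.run_mc(small_inputs, nc.default_ledger(small_config), n_iter=0, seed=1)


def _linear_records(n=10_000, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    c = rng.standard_normal(n)
    return pd.DataFrame({"a": a, "b": b, "c": c, "y": 2 * a + b, "valid": True})


def test_anova_recovers_known_variance_split():
    """y = 2a + b with iid standard normals: shares 0.80 / 0.20."""
    records = _linear_records()
    result = nc.anova_sensitivity(records, parameters=["a", "b", "c"], response="y")
    assert result.shares["a"] == pytest.approx(0.80, abs=0.02)
    assert result.shares["b"] == pytest.approx(0.20, abs=0.02)
    assert result.shares["c"] < 0.01
    assert result.residual < 0.01


def test_anova_pure_response():
    records = _linear_records()
    records["y"] = records["a"]
    result = nc.anova_sensitivity(records, parameters=["a", "b"], response="y")
    assert result.shares["a"] == pytest.approx(1.0, abs=1e-6)
    assert result.residual == pytest.approx(0.0, abs=1e-6)


def test_anova_constant_parameter_dropped_with_zero_share():
    records = _linear_records(n=500)
    records["const"] = 1.0
    result = nc.anova_sensitivity(records, parameters=["a", "b", "const"], response="y")
    assert "const" in result.dropped and result.shares["const"] == 0.0


def test_anova_requires_enough_records():
    with pytest.raises(InputError):
        nc.anova_sensitivity(_linear_records(n=10), parameters=["a"], response="y")
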