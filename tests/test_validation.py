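"""Calibration fitting, Mandel linearity, LOD/LOQ, precision, recovery,
quantification and fining-group comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from flavanms import (
    REGISTRY_NAMES,
    MethodValidation,
    SimulationConfig,
    compare_treatments,
    fit_calibration,
    horwitz_prsd,
    lod_loq,
    mandel_test,
    precision_metrics,
    quantify,
    recovery_analysis,
    simulate_calibration,
    simulate_fining_trial,
    simulate_precision_series,
    simulate_spike_recovery,
    simulate_wines,
)

LEVELS = [0.1, 0.2, 0.4, 0.6, 0.8, 1.0]


def _table(levels, areas, compound="catechin"):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(levels))],
        "group": "calibration",
        "compound": compound,
        "level_mg_L": levels,
        "area": areas,
        "replicate": 1,
        "day": 1,
        "ascorbic": True,
    })


# -- calibration ----------------------------------------------------------

def test_fit_exact_line():
    x = np.array(LEVELS)
    res = fit_calibration(_table(x, 2.0 * x), "catechin")
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    assert res.s_y == pytest.approx(0.0, abs=1e-9)
    assert res.qc_mean_pct == pytest.approx(0.0, abs=1e-9)
    assert res.r2 == pytest.approx(1.0)


def test_fit_needs_three_distinct_levels():
    with pytest.raises(ValueError):
        fit_calibration(_table([0.1, 0.1, 0.2], [1, 1, 2]), "catechin")


def test_fitted_slope_within_3_se_of_configured(calibration_table, cfg):
    for name in REGISTRY_NAMES:
        res = fit_calibration(calibration_table, name)
        assert abs(res.slope - cfg.slope(name)) < 3 * res.slope_se


def test_qc_mean_small_under_default_noise(calibration_table):
    res = fit_calibration(calibration_table, "catechin")
    assert 0 < res.qc_mean_pct < 5.0


def test_qc_mean_decreases_with_injection_cv():
    qc = []
    for cv in (0.06, 0.03, 0.01, 0.0):
        cfg = SimulationConfig(seed=4, cv_injection=cv, sd_additive=0.0)
        res = fit_calibration(simulate_calibration(LEVELS, 3, cfg), "catechin")
        qc.append(res.qc_mean_pct)
    assert qc == sorted(qc, reverse=True)


# -- Mandel ---------------------------------------------------------------

def test_mandel_exact_line_is_linear():
    x = np.array(LEVELS)
    res = mandel_test(_table(x, 5.0 * x + 1.0), "catechin")
    assert res.linear and res.f_stat == 0.0


def test_mandel_pure_quadratic_is_nonlinear():
    x = np.array(LEVELS)
    res = mandel_test(_table(x, x**2), "catechin")
    assert not res.linear and res.f_stat == math.inf


def test_mandel_noisy_quadratic_detected():
    rng = np.random.default_rng(0)
    x = np.repeat(LEVELS, 3)
    y = 1e5 * x + 4e4 * x**2 + rng.normal(0, 300, x.size)
    res = mandel_test(_table(x, y), "catechin")
    assert res.f_stat > res.f_crit and not res.linear


def test_mandel_needs_five_points():
    with pytest.raises(ValueError):
        mandel_test(_table([0.1, 0.2, 0.4, 0.6], [1, 2, 4, 6]), "catechin")


# -- LOD / LOQ ------------------------------------------------------------

def test_lod_loq_arithmetic():
    res = fit_calibration(_table(np.array(LEVELS), 100.0 * np.array(LEVELS)), "catechin")
    res = res.__class__(**{**res.__dict__, "s_y": 1.0})  # s_y/slope = 0.01
    lim = lod_loq(res, dilution_factor=20.0)
    assert lim.lod_diluted == pytest.approx(0.033)
    assert lim.lod_wine == pytest.approx(0.66)
    assert lim.loq_wine == pytest.approx(2.0)


def test_lod_loq_ratio_and_dilution_scaling(calibration_table):
    res = fit_calibration(calibration_table, "procyanidin C1")
    for df in (1.0, 5.0, 20.0):
        lim = lod_loq(res, dilution_factor=df)
        assert lim.loq_diluted / lim.lod_diluted == pytest.approx(10 / 3.3)
        assert lim.lod_wine == pytest.approx(lim.lod_diluted * df)


def test_lod_loq_zero_residual_zero_limits():
    x = np.array(LEVELS)
    lim = lod_loq(fit_calibration(_table(x, 3.0 * x), "catechin"))
    assert lim.lod_wine == pytest.approx(0.0, abs=1e-9)


def test_lod_loq_requires_positive_slope():
    x = np.array(LEVELS)
    res = fit_calibration(_table(x, -2.0 * x), "catechin")
    with pytest.raises(ValueError):
        lod_loq(res)


# -- Horwitz --------------------------------------------------------------

def test_horwitz_closed_forms():
    # C = 1 (mass fraction) -> 2%; C = 1e-5 -> 2^3.5 %
    assert horwitz_prsd(1e6) == pytest.approx(2.0)
    assert horwitz_prsd(10.0) == pytest.approx(2**3.5)
    assert horwitz_prsd(10.0, "repeatability") == pytest.approx(0.66 * 2**3.5)


def test_horwitz_monotone_decreasing():
    concs = [0.5, 5.0, 50.0, 500.0]
    vals = [horwitz_prsd(c) for c in concs]
    assert vals == sorted(vals, reverse=True)
    with pytest.raises(ValueError):
        horwitz_prsd(0.0)


# -- precision ------------------------------------------------------------

def test_precision_zero_noise_zero_rsd(quiet_cfg):
    quiet = SimulationConfig(seed=0, cv_injection=0.0, sd_additive=0.0, day_bias_sd=0.0)
    table = simulate_precision_series({"catechin": 0.75}, cfg=quiet)
    cal = simulate_calibration(LEVELS, 3, quiet)
    rep = precision_metrics(table, fit_calibration(cal, "catechin"), "catechin")
    assert rep.rsd_r_pct == pytest.approx(0.0, abs=1e-9)
    assert rep.rsd_ir_pct == pytest.approx(0.0, abs=1e-9)


def test_precision_default_config_bands(cfg, calibration_table):
    """Default noise puts within-day RSD in the 2-8% working band and
    between-day RSD at or above it."""
    table = simulate_precision_series({n: 0.75 for n in REGISTRY_NAMES}, cfg=cfg)
    model = fit_calibration(calibration_table, "catechin")
    rep = precision_metrics(table, model, "catechin")
    assert 0.5 < rep.rsd_r_pct < 8.0
    assert rep.rsd_ir_pct >= rep.rsd_r_pct - 1e-9
    assert rep.horrat_r == pytest.approx(rep.rsd_r_pct / rep.prsd_r_pct)


def test_precision_horrat_flag_windows(cfg, calibration_table):
    table = simulate_precision_series({"catechin": 0.75}, cfg=cfg)
    rep = precision_metrics(table, fit_calibration(calibration_table, "catechin"),
                            "catechin")
    assert rep.horrat_r_ok == (0.3 <= rep.horrat_r <= 1.3)
    assert rep.horrat_ir_ok == (0.5 <= rep.horrat_ir <= 2.0)


def test_precision_needs_replication(cfg, calibration_table):
    table = simulate_precision_series({"catechin": 0.75}, days=1, reps=3, cfg=cfg)
    with pytest.raises(ValueError):
        precision_metrics(table, fit_calibration(calibration_table, "catechin"),
                          "catechin")


# -- recovery -------------------------------------------------------------

def test_recovery_perfect_data_slope_one(quiet_cfg):
    table = simulate_spike_recovery({"catechin": 0.3}, LEVELS, cfg=quiet_cfg)
    cal = simulate_calibration(LEVELS, 3, quiet_cfg)
    rep = recovery_analysis(table, fit_calibration(cal, "catechin"))
    assert rep.slope == pytest.approx(1.0, abs=1e-9)
    assert rep.recovery_pct == pytest.approx(100.0, abs=1e-6)
    assert not rep.deviates_from_1


def test_recovery_without_ascorbic_reflects_oxidized_fraction():
    cfg = SimulationConfig(seed=2, cv_injection=0.0, sd_additive=0.0, f_oxidized=0.3)
    cal = simulate_calibration(LEVELS, 3, cfg, ascorbic=True)
    spk = simulate_spike_recovery({"catechin": 0.3}, LEVELS, cfg=cfg, ascorbic=False)
    rep = recovery_analysis(spk, fit_calibration(cal, "catechin"))
    assert rep.slope == pytest.approx(0.7, abs=1e-9)
    assert rep.deviates_from_1


def test_recovery_needs_three_levels(cfg, calibration_table):
    spk = simulate_spike_recovery({"catechin": 0.3}, [0.2, 0.4], cfg=cfg)
    with pytest.raises(ValueError):
        recovery_analysis(spk, fit_calibration(calibration_table, "catechin"))


# -- quantification -------------------------------------------------------

def test_quantify_roundtrip_zero_noise(quiet_cfg):
    cal = simulate_calibration(LEVELS, 3, quiet_cfg)
    model = fit_calibration(cal, "catechin")
    wines = simulate_wines({"w": {"catechin": 15.0}}, reps=2, cfg=quiet_cfg)
    out = quantify(wines, model, dilution_factor=20.0)
    assert np.allclose(out["conc_mg_L"], 15.0)


def test_quantify_area_at_intercept_is_zero(quiet_cfg):
    cal = simulate_calibration(LEVELS, 3, quiet_cfg)
    model = fit_calibration(cal, "catechin")
    table = simulate_wines({"w": {"catechin": 0.0}}, reps=1, cfg=quiet_cfg)
    out = quantify(table, model, 20.0)
    assert out["conc_mg_L"].iloc[0] == pytest.approx(0.0, abs=1e-6)


def test_quantify_flags_below_limits(cfg, calibration_table):
    model = fit_calibration(calibration_table, "catechin")
    limits = lod_loq(model, 20.0)
    wines = simulate_wines({"hi": {"catechin": 15.0}, "lo": {"catechin": 0.2}},
                           reps=1, cfg=cfg)
    out = quantify(wines, model, 20.0, limits)
    hi = out[out["sample_id"] == "hi"].iloc[0]
    lo = out[out["sample_id"] == "lo"].iloc[0]
    assert hi["flag"] == ""
    assert lo["flag"] in ("<LOD", "<LOQ", "below_intercept")


# -- group comparison -----------------------------------------------------

def _conc_frame(groups: dict[str, list[float]], compound="catechin"):
    rows = [
        {"compound": compound, "group": g, "conc_mg_L": v, "flag": ""}
        for g, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


def test_compare_identical_groups_f_zero():
    res = compare_treatments(_conc_frame({"a": [5.0, 5.0], "b": [5.0, 5.0]}))
    cmp_res = res["catechin"]
    assert cmp_res.f_stat == 0.0
    assert set(cmp_res.group_letters.values()) == {"a"}


def test_compare_zero_variance_distinct_groups():
    res = compare_treatments(_conc_frame({"a": [5.0, 5.0], "b": [9.0, 9.0]}))
    cmp_res = res["catechin"]
    assert cmp_res.f_stat == math.inf and cmp_res.p_value == 0.0
    assert cmp_res.group_letters["a"] != cmp_res.group_letters["b"]


def test_compare_large_removal_separates_group(cfg, calibration_table):
    removal = {"patatin": {"catechin": 0.9}, "gelatin": {"catechin": 0.0}}
    low_noise = SimulationConfig(seed=8, cv_injection=0.02, sd_additive=100.0)
    table = simulate_fining_trial({"catechin": 0.8}, removal, reps=3, cfg=low_noise)
    model = fit_calibration(calibration_table, "catechin")
    conc = quantify(table, model, 20.0)
    res = compare_treatments(conc)["catechin"]
    letters = res.group_letters
    assert letters["patatin"] not in (letters["control"], letters["gelatin"])
    assert res.p_value < 0.05


def test_compare_excludes_flagged_rows():
    frame = _conc_frame({"a": [5.0, 5.1, 4.9], "b": [5.0, 5.2, 4.8]})
    frame.loc[0, "flag"] = "<LOQ"
    res = compare_treatments(frame)["catechin"]
    assert res.n_excluded == 1


def test_compare_needs_two_groups():
    with pytest.raises(ValueError):
        compare_treatments(_conc_frame({"a": [1.0, 2.0]}))


# -- whole-study fit ------------------------------------------------------

def test_method_validation_report_shape(cfg):
    cal = simulate_calibration(LEVELS, 3, cfg)
    prec = simulate_precision_series({n: 0.75 for n in REGISTRY_NAMES}, cfg=cfg)
    spk = simulate_spike_recovery({n: 0.3 for n in REGISTRY_NAMES}, LEVELS, cfg=cfg)
    results = MethodValidation(cal, prec, spk).fit()
    table = results.summary()
    assert len(table) == 8
    assert set(table["compound"]) == set(REGISTRY_NAMES)
    assert table["mandel_linear"].all()
    assert (table["loq_wine_mg_L"] / table["lod_wine_mg_L"]).round(9).eq(
        round(10 / 3.3, 9)).all()
    assert results.to_json().startswith("{")
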