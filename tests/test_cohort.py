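import dataclasses
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semcohort import GeneratorConfig, construct_reliability
from semcohort.cohort import (build_generating_parameters, calibrate_loadings,
                              score_retest_correlations, simulate_baseline,
                              simulate_cohort, simulate_followup,
                              simulate_mortality)
from semcohort.errors import ConfigError, DataError
from semcohort.modelspecs import BIOMARKERS
from semcohort.sem import implied_covariance


# ----------------------------------------------------------------------
# calibration helpers
# ----------------------------------------------------------------------
def test_calibrate_loadings_examples():
    assert calibrate_loadings(0.63, 4) == pytest.approx(0.5464, abs=1e-4)
    assert calibrate_loadings(0.70, 2) == pytest.approx(0.7338, abs=1e-4)


def test_calibrate_loadings_limit_case():
    assert calibrate_loadings(0.999999, 5) == pytest.approx(1.0, abs=1e-3)


def test_calibrate_loadings_rejects_bad_inputs():
    with pytest.raises(ConfigError):
        calibrate_loadings(1.0, 4)
    with pytest.raises(ConfigError):
        calibrate_loadings(0.5, 1)


@given(cr=st.floats(0.05, 0.95), k=st.integers(2, 10))
@settings(max_examples=50, deadline=None)
def test_calibrate_loadings_inverts_reliability(cr, k):
    lam = calibrate_loadings(cr, k)
    back = construct_reliability([lam] * k, [1 - lam**2] * k)
    assert back == pytest.approx(cr, abs=1e-12)


def test_generating_disturbances():
    spec, params = build_generating_parameters(GeneratorConfig())
    dist = params.disturbance_variances()
    assert dist["fibrosis"] == pytest.approx(1 - 0.74**2, abs=1e-12)
    assert dist["infl_ox"] == pytest.approx(1 - 0.29**2, abs=1e-12)
    sigma = implied_covariance(spec, params)
    assert np.allclose(np.diag(sigma.values), 1.0, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(sigma.values) > 0)


def test_zero_paths_give_block_diagonal_covariance():
    config = dataclasses.replace(
        GeneratorConfig(), sel_to_io=0.0, io_to_fib=0.0, io_to_myo=0.0,
        second_order={"inflammation": 0.0, "oxidative_stress": 0.0})
    spec, params = build_generating_parameters(config)
    sigma = implied_covariance(spec, params)
    frame = pd.DataFrame(sigma.values, index=sigma.labels,
                         columns=sigma.labels)
    assert frame.loc["tnfr1", "copeptin"] == 0.0
    assert frame.loc["gdf15", "ntprobnp"] == 0.0
    assert frame.loc["tnfr1", "tnfr2"] > 0.0


def test_incompatible_coefficients_rejected():
    config = dataclasses.replace(GeneratorConfig(), io_to_fib=1.2)
    with pytest.raises(ConfigError, match="explained variance"):
        build_generating_parameters(config)


# ----------------------------------------------------------------------
# baseline simulation
# ----------------------------------------------------------------------
def test_same_seed_gives_identical_csv_bytes(default_config):
    def render(cfg):
        buf = io.StringIO()
        simulate_cohort(cfg).to_csv(buf, index=False)
        return buf.getvalue()

    assert render(default_config) == render(GeneratorConfig(seed=1))


def test_different_seeds_differ():
    a = simulate_baseline(GeneratorConfig(seed=1))
    b = simulate_baseline(GeneratorConfig(seed=2))
    assert not np.allclose(a["tnfr1"], b["tnfr1"])


def test_selenium_mean_calibrated(baseline_50k):
    assert baseline_50k["selenium_ugL"].mean() == pytest.approx(67.1,
                                                                abs=0.5)


def test_selenium_age_correlation(baseline_50k):
    r = np.corrcoef(baseline_50k["selenium_ugL"],
                    baseline_50k["age_years"])[0, 1]
    assert r == pytest.approx(-0.13, abs=0.03)


def test_age_within_configured_range(baseline_50k):
    assert baseline_50k["age_years"].between(70, 88).all()


def test_concentrations_positive(baseline_50k):
    for marker in BIOMARKERS:
        assert (baseline_50k[marker] > 0).all()


def test_log_indicator_correlations_match_implied(baseline_50k):
    config = GeneratorConfig(seed=1)
    spec, params = build_generating_parameters(config)
    sigma = pd.DataFrame(implied_covariance(spec, params).values,
                         index=spec.manifest_names,
                         columns=spec.manifest_names)
    cols = list(BIOMARKERS)
    logs = np.log(baseline_50k[cols].to_numpy())
    logs = np.column_stack([logs, baseline_50k["_z_q"].to_numpy()])
    emp = np.corrcoef(logs, rowvar=False)
    imp = sigma.loc[cols + ["sel_age"], cols + ["sel_age"]].to_numpy()
    assert np.max(np.abs(emp - imp)) < 0.02


def test_covariance_converges_with_n():
    config = GeneratorConfig(seed=5)
    spec, params = build_generating_parameters(config)
    imp = implied_covariance(spec, params).values[:13, :13]

    def frob(n):
        frame = simulate_baseline(config, n=n)
        emp = np.corrcoef(np.log(frame[list(BIOMARKERS)].to_numpy()),
                          rowvar=False)
        return np.linalg.norm(emp - imp)

    assert frob(50_000) < frob(5_000)


def test_marker_age_correlations_in_configured_band(baseline_50k):
    config = GeneratorConfig(seed=1)
    rs = [np.corrcoef(np.log(baseline_50k[m]),
                      baseline_50k["age_years"])[0, 1]
          for m in config.age_links]
    assert 0.18 - 0.03 <= min(rs)
    assert max(rs) <= 0.37 + 0.03
    assert np.mean(rs) == pytest.approx(0.25, abs=0.02)


# ----------------------------------------------------------------------
# follow-up
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def quiet_followup():
    config = dataclasses.replace(GeneratorConfig(seed=2),
                                 arm_effects={"placebo": {}, "active": {}})
    base = simulate_baseline(config, n=50_000)
    return config, base, simulate_followup(config, base)


def test_factor_score_retest_matches_configured_rho(quiet_followup):
    config, base, follow = quiet_followup
    retest = score_retest_correlations(config, base, follow)
    assert retest["inflammation"] == pytest.approx(0.57, abs=0.02)
    assert retest["oxidative_stress"] == pytest.approx(0.67, abs=0.02)
    assert retest["fibrosis"] == pytest.approx(0.76, abs=0.02)


def test_unit_rho_and_no_shift_reproduces_latents():
    config = dataclasses.replace(
        GeneratorConfig(seed=3),
        retest_rho={f: 1.0 - 1e-12 for f in
                    ("inflammation", "oxidative_stress", "fibrosis",
                     "myocardium")},
        arm_effects={"placebo": {}, "active": {}})
    base = simulate_baseline(config, n=500)
    follow = simulate_followup(config, base)
    for fac in ("inflammation", "fibrosis"):
        assert np.allclose(follow[f"_f_{fac}"], base[f"_f_{fac}"],
                           atol=1e-5)


def test_arm_shift_signs_on_latents():
    config = GeneratorConfig(seed=4)
    base = simulate_baseline(config, n=20_000)
    follow = simulate_followup(config, base)
    delta = (follow.set_index("subject_id")["_f_inflammation"]
             - base.set_index("subject_id")["_f_inflammation"])
    arm = base.set_index("subject_id")["arm"]
    assert delta[arm == "placebo"].mean() > 0
    assert delta[arm == "active"].mean() < 0


def test_followup_requires_generator_state(default_config):
    base = simulate_baseline(default_config, n=100)
    with pytest.raises(DataError, match="generator state"):
        simulate_followup(default_config,
                          base.drop(columns=["_z_age"]))


# ----------------------------------------------------------------------
# mortality
# ----------------------------------------------------------------------
def _arm_frame(n):
    return pd.DataFrame({
        "subject_id": np.arange(n),
        "arm": np.array(["active", "placebo"] * (n // 2)),
        "occasion_months": 0,
        "selenium_ugL": 67.0,
    })


def test_rct_mortality_rates():
    config = GeneratorConfig(seed=1)
    out = simulate_mortality(config, _arm_frame(200_000))
    placebo = out[out["arm"] == "placebo"]["cv_death_5y"].mean()
    active = out[out["arm"] == "active"]["cv_death_5y"].mean()
    assert placebo == pytest.approx(0.126, abs=0.004)
    assert active == pytest.approx(0.059, abs=0.004)


def test_zero_rate_means_no_deaths():
    config = dataclasses.replace(GeneratorConfig(seed=1),
                                 mortality_rate_active=0.0,
                                 mortality_rate_placebo=0.0)
    out = simulate_mortality(config, _arm_frame(5000))
    assert out["cv_death_5y"].sum() == 0


def test_observational_quartile_rates():
    config = GeneratorConfig(seed=1, mode="observational")
    rng = np.random.default_rng(0)
    n = 200_000
    frame = pd.DataFrame({
        "subject_id": np.arange(n), "arm": "none", "occasion_months": 0,
        "selenium_ugL": rng.normal(67, 16, n)})
    out = simulate_mortality(config, frame)
    quart = pd.qcut(out["selenium_ugL"], 4, labels=False)
    low = out["cv_death_5y"][quart == 0].mean()
    high = out["cv_death_5y"][quart == 3].mean()
    assert low == pytest.approx(29 / 107, abs=0.006)
    assert high == pytest.approx(16 / 111, abs=0.006)


def test_mortality_counts_binomially_consistent():
    # chi-square goodness of fit vs the configured rate over seeds
    config = GeneratorConfig(seed=0)
    n = 20_000
    for seed in range(5):
        out = simulate_mortality(dataclasses.replace(config, seed=seed),
                                 _arm_frame(n))
        placebo = out[out["arm"] == "placebo"]["cv_death_5y"]
        k, m = placebo.sum(), len(placebo)
        expected = m * 0.126
        chi2 = ((k - expected) ** 2 / expected
                + ((m - k) - m * 0.874) ** 2 / (m * 0.874))
        from scipy import stats
        assert stats.chi2.sf(chi2, 1) > 0.001


def test_missing_arm_rejected():
    config = GeneratorConfig(seed=1)
    frame = _arm_frame(100)
    frame.loc[3, "arm"] = "mystery"
    with pytest.raises(DataError, match="arm"):
        simulate_mortality(config, frame)


def test_death_consistent_across_occasions():
    config = GeneratorConfig(seed=6)
    cohort = simulate_cohort(config)
    per_subject = cohort.groupby("subject_id")["cv_death_5y"].nunique()
    assert (per_subject == 1).all()


# ----------------------------------------------------------------------
# config
# ----------------------------------------------------------------------
def test_unknown_config_key_rejected():
    with pytest.raises(ConfigError, match="unknown config key"):
        GeneratorConfig.from_dict({"not_a_key": 1})


def test_rate_out_of_range_rejected():
    with pytest.raises(ConfigError, match="outside"):
        GeneratorConfig.from_dict({"mortality_rate_placebo": 1.5})


def test_unknown_marker_in_age_links_rejected():
    with pytest.raises(ConfigError, match="unknown biomarker"):
        GeneratorConfig.from_dict({"age_links": {"unobtainium": 0.2}})


def test_nested_merge_keeps_other_defaults():
    config = GeneratorConfig.from_dict(
        {"age_links": {"tnfr1": 0.3}})
    assert config.age_links["tnfr1"] == 0.3
    assert config.age_links["ntprobnp"] == 0.37


def test_with_total_n_splits_arms():
    config = GeneratorConfig().with_total_n(1001)
    assert config.n_active + config.n_placebo == 1001
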