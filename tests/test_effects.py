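import numpy as np
import pandas as pd
import pytest

from semcohort.errors import DataError
from semcohort.sem import (CovMatrix, construct_reliability, factor_scores,
                           fit, implied_covariance, indirect_effects,
                           parse_model, standardize)
from semcohort.sem.effects import standardize_params
from semcohort.sem.params import build_template

STRUCTURAL = ("factor f: a b c\nfactor g: d e\n"
              "second_order s: f g\nobserved_exogenous x\n"
              "path x -> s\n")


# ----------------------------------------------------------------------
# standardization
# ----------------------------------------------------------------------
def _random_sample_cov(rng, labels):
    p = len(labels)
    y = rng.standard_normal((600, p)) + 0.8 * rng.standard_normal((600, 1))
    return CovMatrix(labels, np.cov(y, rowvar=False), 600)


def test_standardize_idempotent():
    spec = parse_model("factor f: a b c\n")
    tpl = build_template(spec)
    tpl.lam[:, 0] = [0.8, 0.7, 0.6]
    tpl.psi[0, 0] = 1.0
    tpl.theta[:] = 1.0 - np.array([0.8, 0.7, 0.6]) ** 2
    std = standardize_params(tpl)
    assert np.allclose(std.pack(), tpl.pack(), atol=1e-12)
    again = standardize_params(std)
    assert np.allclose(again.pack(), std.pack(), atol=1e-12)


def test_standardized_solution_marker_invariant():
    rng = np.random.default_rng(9)
    s = _random_sample_cov(rng, ("a", "b", "c", "d", "e"))
    text = "factor f: a b c\nfactor g: d e\npath f -> g\n"
    fit_marker = fit(parse_model(text), s, n=600)
    fit_unit = fit(parse_model(text, identification="unit-latent-variance"),
                   s, n=600)
    assert fit_marker.converged and fit_unit.converged
    sm, su = fit_marker.standardized, fit_unit.standardized
    assert np.allclose(np.abs(sm.lam), np.abs(su.lam), atol=1e-6)
    assert np.allclose(np.abs(sm.beta), np.abs(su.beta), atol=1e-6)
    assert np.allclose(sm.theta, su.theta, atol=1e-6)


def test_standardize_accepts_fitresult():
    rng = np.random.default_rng(10)
    s = _random_sample_cov(rng, ("a", "b", "c"))
    result = fit(parse_model("factor f: a b c\n"), s, n=600)
    std = standardize(result)
    # standardized manifest variances are 1: lam^2 + theta = 1
    total = std.lam[:, 0] ** 2 * 1.0 + std.theta
    assert np.allclose(total, 1.0, atol=1e-8)


# ----------------------------------------------------------------------
# indirect effects
# ----------------------------------------------------------------------
def _structural_params(x_to_s=-0.29, s_to_f=0.8, s_to_g=0.98):
    spec = parse_model(STRUCTURAL)
    tpl = build_template(spec)
    lat = {name: j for j, name in enumerate(spec.latent_names)}
    tpl.beta[:] = 0.0
    tpl.beta[lat["f"], lat["s"]] = s_to_f
    tpl.beta[lat["g"], lat["s"]] = s_to_g
    tpl.beta[lat["s"], lat["x"]] = x_to_s
    tpl.lam[:3, lat["f"]] = 0.7
    tpl.lam[3:5, lat["g"]] = 0.7
    tpl.lam[5, lat["x"]] = 1.0
    tpl.theta[:5] = 0.51
    tpl.theta[5] = 0.0
    np.fill_diagonal(tpl.psi, [1 - s_to_f**2, 1 - s_to_g**2,
                               1 - x_to_s**2, 1.0])
    return spec, tpl


def test_indirect_effect_is_chain_product():
    _, params = _structural_params(x_to_s=-0.29, s_to_f=0.74)
    eff = indirect_effects(params, "x", "f", standardized=False)
    assert eff.total == pytest.approx(-0.29 * 0.74, abs=1e-12)
    assert round(eff.total, 2) == -0.21


def test_indirect_effect_second_chain():
    _, params = _structural_params(x_to_s=-0.29, s_to_g=0.65)
    eff = indirect_effects(params, "x", "g", standardized=False)
    assert eff.total == pytest.approx(-0.29 * 0.65, abs=1e-12)
    assert round(eff.total, 2) == -0.19


def test_zero_coefficient_kills_chain():
    _, params = _structural_params(x_to_s=0.0)
    eff = indirect_effects(params, "x", "f", standardized=False)
    assert eff.total == 0.0


def test_no_path_reports_note():
    _, params = _structural_params()
    eff = indirect_effects(params, "f", "g", standardized=False)
    assert eff.total == 0.0
    assert "no indirect path" in eff.note


def test_indirect_effects_match_matrix_enumeration():
    # oracle: total-effects identity (I-B)^-1 - I; indirect = total - B
    rng = np.random.default_rng(21)
    for _ in range(10):
        k = 6
        lines = [f"factor f{i}: x{i} y{i}" for i in range(k)]
        edges = [(i, j) for i in range(k) for j in range(i + 1, k)
                 if rng.random() < 0.5]
        lines += [f"path f{i} -> f{j}" for i, j in edges]
        spec = parse_model("\n".join(lines))
        tpl = build_template(spec)
        tpl.beta[tpl.beta_free] = rng.uniform(-0.8, 0.8,
                                              int(tpl.beta_free.sum()))
        b = tpl.beta[:k, :k]
        total = np.linalg.inv(np.eye(k) - b) - np.eye(k)
        indirect = total - b
        for i, j in edges:
            eff = indirect_effects(tpl, f"f{i}", f"f{j}",
                                   standardized=False)
            assert eff.total == pytest.approx(indirect[j, i], abs=1e-10)


# ----------------------------------------------------------------------
# construct reliability
# ----------------------------------------------------------------------
def test_perfect_indicators_give_unit_reliability():
    assert construct_reliability([1.0, 1.0], [0.0, 0.0]) == 1.0


def test_reliability_examples_from_equal_loadings():
    lam = 0.5464
    assert construct_reliability([lam] * 4, [1 - lam**2] * 4) \
        == pytest.approx(0.63, abs=0.001)
    lam = 0.7338
    assert construct_reliability([lam] * 2, [1 - lam**2] * 2) \
        == pytest.approx(0.70, abs=0.001)


def test_empty_indicator_list_rejected():
    with pytest.raises(DataError):
        construct_reliability([], [])


# ----------------------------------------------------------------------
# factor scores
# ----------------------------------------------------------------------
@pytest.fixture()
def toy_fit():
    spec = parse_model("factor f: a b\nfactor g: c d\n")
    rng = np.random.default_rng(31)
    eta = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 4000)
    y = np.column_stack([
        eta[:, 0] + 0.6 * rng.standard_normal(4000),
        0.8 * eta[:, 0] + 0.6 * rng.standard_normal(4000),
        eta[:, 1] + 0.6 * rng.standard_normal(4000),
        0.8 * eta[:, 1] + 0.6 * rng.standard_normal(4000),
    ])
    data = pd.DataFrame(y, columns=["a", "b", "c", "d"])
    s = CovMatrix.from_data(data)
    return fit(spec, s, n=4000), data, eta


def test_scores_zero_at_means(toy_fit):
    result, data, _ = toy_fit
    at_mean = pd.DataFrame([data.mean()], columns=data.columns)
    scores = factor_scores(result, at_mean)
    assert np.allclose(scores.to_numpy(), 0.0, atol=1e-10)


def test_scores_match_hand_linear_algebra(toy_fit):
    result, data, _ = toy_fit
    params = result.estimates
    c = np.linalg.inv(np.eye(2) - params.beta)
    cov_ey = c @ params.psi @ c.T @ params.lam.T
    w = np.linalg.solve(result.S.values, cov_ey.T)
    expected = (data.to_numpy() - data.mean().to_numpy()) @ w
    scores = factor_scores(result, data)
    assert np.allclose(scores.to_numpy(), expected, atol=1e-10)


def test_scores_track_true_latents(toy_fit):
    result, data, eta = toy_fit
    scores = factor_scores(result, data)
    for j, fac in enumerate(["f", "g"]):
        assert np.corrcoef(scores[fac], eta[:, j])[0, 1] > 0.6


def test_scores_missing_column_rejected(toy_fit):
    result, data, _ = toy_fit
    with pytest.raises(DataError, match="missing"):
        factor_scores(result, data.drop(columns=["a"]))


def test_own_indicator_scores_shape(toy_fit):
    result, data, _ = toy_fit
    scores = factor_scores(result, data, own_indicators=True)
    assert list(scores.columns) == ["f", "g"]
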