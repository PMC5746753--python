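"""Clearance OLS, stepwise selection and constant models against
independent linear-algebra oracles."""

import numpy as np
import pandas as pd
import pytest

import ipmsim as ip
from ipmsim.errors import ConfigError, SingularDesignError
from ipmsim.terms import Term, build_candidate_terms


# -- candidate term enumeration --------------------------------------------

def test_candidate_terms_two_factors():
    terms = build_candidate_terms(["A", "B"])
    assert [t.label for t in terms] == ["A", "B", "A*B", "A^2", "B^2"]


def test_candidate_terms_single_factor_has_no_interaction():
    terms = build_candidate_terms(["A"], include_interactions=True)
    assert [t.label for t in terms] == ["A", "A^2"]


def test_candidate_terms_count_five_factors():
    # 5 mains + C(5,2)=10 interactions + 5 quadratics
    assert len(build_candidate_terms(list("abcde"))) == 20


def test_candidate_terms_duplicate_names_rejected():
    with pytest.raises(ConfigError, match="duplicate"):
        build_candidate_terms(["A", "A"])


def test_term_validation():
    with pytest.raises(ConfigError):
        Term("interaction", ("A", "A"))
    with pytest.raises(ConfigError):
        Term("quadratic", ("A", "B"))


# -- OLS against the normal-equations oracle --------------------------------

def _oracle(M, y):
    """Explicit normal equations on the raw model matrix with intercept."""
    xtxi = np.linalg.inv(M.T @ M)
    beta = xtxi @ M.T @ y
    resid = y - M @ beta
    s = float(np.sqrt(resid @ resid / (len(y) - M.shape[1])))
    return beta, s, xtxi


def _fixture(seed):
    rng = np.random.default_rng(seed)
    n = 12
    X = pd.DataFrame({"a": rng.uniform(1, 3, n), "b": rng.uniform(10, 20, n)})
    y = (
        5
        + 0.8 * X.a
        - 0.1 * X.b
        + 0.05 * X.a * X.b
        + 0.3 * X.a**2
        + rng.normal(0, 0.2, n)
    )
    terms = (
        Term("main", ("a",)),
        Term("main", ("b",)),
        Term("interaction", ("a", "b")),
        Term("quadratic", ("a",)),
    )
    M = np.column_stack([np.ones(n), X.a, X.b, X.a * X.b, X.a**2])
    return X, y.to_numpy(), terms, M


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
def test_ols_matches_normal_equations_oracle(seed):
    """Coefficients, residual SE and leverage-based prediction SD agree with
    an explicit matrix oracle to 1e-10 relative, quadratic model included."""
    X, y, terms, M = _fixture(seed)
    fit = ip.ClearanceOLS(terms).fit(X, y)
    beta, s, xtxi = _oracle(M, y)
    nat = fit.natural_coefficients()
    got = np.array([nat["(intercept)"], nat["a"], nat["b"], nat["a*b"], nat["a^2"]])
    np.testing.assert_allclose(got, beta, rtol=1e-10)
    assert fit.residual_se_ == pytest.approx(s, rel=1e-10)
    rng = np.random.default_rng(100 + seed)
    Xn = pd.DataFrame({"a": rng.uniform(1, 3, 5), "b": rng.uniform(10, 20, 5)})
    Mn = np.column_stack([np.ones(5), Xn.a, Xn.b, Xn.a * Xn.b, Xn.a**2])
    np.testing.assert_allclose(fit.predict(Xn), Mn @ beta, rtol=1e-10)
    # the centered 1/n + leverage form equals the full-matrix leverage form
    sd_oracle = s * np.sqrt(np.einsum("ij,jk,ik->i", Mn, xtxi, Mn))
    np.testing.assert_allclose(fit.predict_sd(Xn), sd_oracle, rtol=1e-10)


def test_noiseless_fit_is_exact_interpolation():
    X = pd.DataFrame({"x1": [-1.0, 1.0, -1.0, 1.0]})
    y = 2.0 * X.x1 + 1.0
    fit = ip.ClearanceOLS((Term("main", ("x1",)),)).fit(X, y)
    assert fit.residual_se_ == pytest.approx(0.0, abs=1e-12)
    assert fit.predict({"x1": 3.0})[0] == pytest.approx(7.0, rel=1e-12)
    nat = fit.natural_coefficients()
    assert nat["x1"] == pytest.approx(2.0, rel=1e-12)
    assert nat["(intercept)"] == pytest.approx(1.0, rel=1e-10)
    # zero residual -> zero prediction SD everywhere
    assert fit.predict_sd({"x1": 5.0})[0] == pytest.approx(0.0, abs=1e-12)


def test_intercept_only_fit_is_mean():
    rng = np.random.default_rng(0)
    y = rng.normal(3.0, 0.5, 10)
    fit = ip.ClearanceOLS(()).fit({"x1": np.zeros(10)}, y)
    assert fit.intercept_ == pytest.approx(y.mean(), rel=1e-12)
    assert fit.predict({"x1": 42.0})[0] == pytest.approx(y.mean(), rel=1e-12)
    # intercept-only SD is s * sqrt(1/n)
    assert fit.predict_sd({"x1": 0.0})[0] == pytest.approx(
        y.std(ddof=1) / np.sqrt(10), rel=1e-12
    )


def test_prediction_sd_at_center_of_orthogonal_design():
    """At the centroid of a centered orthogonal design the leverage vanishes
    and the SD reduces to s/sqrt(n); it is minimal there."""
    design = ip.generate_dsd(5, n_runs=13)
    X = pd.DataFrame(design, columns=list("abcde"))
    rng = np.random.default_rng(3)
    y = 4.0 + design[:, 0] + rng.normal(0, 0.3, 13)
    fit = ip.ClearanceOLS(tuple(Term("main", (f,)) for f in "abcde")).fit(X, y)
    center = {f: 0.0 for f in "abcde"}
    sd_center = fit.predict_sd(center)[0]
    assert sd_center == pytest.approx(fit.residual_se_ * np.sqrt(1 / 13), rel=1e-10)
    corners = pd.DataFrame(
        np.random.default_rng(4).uniform(-1, 1, (50, 5)), columns=list("abcde")
    )
    assert (fit.predict_sd(corners) >= sd_center - 1e-12).all()


def test_singular_design_names_aliased_terms():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    X["b"] = X["a"]  # perfectly aliased factor
    y = np.arange(6.0)
    terms = (Term("main", ("a",)), Term("main", ("b",)))
    with pytest.raises(SingularDesignError, match="b"):
        ip.ClearanceOLS(terms).fit(X, y)


def test_sampling_moments_and_zero_sd(scenario):
    fit = scenario["models"].get("CC1", "PRI2").doe_fit
    point = {p.name: p.setpoint for p in scenario["process"].uo("CC1").pps}
    mu = ip.predict_mean(fit, point)
    sd = ip.prediction_sd(fit, point)
    rng = ip.substream(9, "draws")
    draws = fit.sample(
        {k: np.full(100_000, v) for k, v in point.items()}, rng
    )
    assert draws.mean() == pytest.approx(mu, abs=4 * sd / np.sqrt(100_000))
    assert draws.std(ddof=1) == pytest.approx(sd, rel=0.03)


def test_zero_sd_sample_returns_mean_exactly():
    X = pd.DataFrame({"x1": [-1.0, 1.0, -1.0, 1.0]})
    fit = ip.ClearanceOLS((Term("main", ("x1",)),)).fit(X, 2.0 * X.x1 + 5.0)
    out = ip.sample_clearance_doe(fit, {"x1": 0.5}, ip.substream(0, "z"))
    assert out == pytest.approx(6.0, rel=1e-12)


def test_floor_policy_counts_interventions():
    model = ip.ConstantClearance()
    model.mean_, model.sd_, model.n_ = 0.5, 5.0, 9
    counters = ip.FloorCounters()
    draws = model.sample(ip.substream(1, "f"), size=2000, counters=counters)
    assert (draws >= 1e-6).all()
    assert counters.total > 0


# -- constant model ----------------------------------------------------------

def test_constant_model_arithmetic():
    m = ip.fit_constant_model([2.0, 2.0, 2.0])
    assert (m.mean_, m.sd_) == (2.0, 0.0)
    m = ip.fit_constant_model([1.0, 3.0])
    assert m.mean_ == pytest.approx(2.0)
    assert m.sd_ == pytest.approx(np.sqrt(2.0), rel=1e-12)
    with pytest.raises(ConfigError):
        ip.fit_constant_model([1.0])


def test_constant_model_recovers_ls_mean():
    rng = ip.substream(12, "ls")
    values = rng.normal(4.0, 0.25, 9)
    m = ip.fit_constant_model(values)
    assert abs(m.mean_ - 4.0) < 3 * 0.25 / np.sqrt(9)
    draws = m.sample(ip.substream(13, "d"), size=100_000)
    assert draws.mean() == pytest.approx(m.mean_, abs=4 * m.sd_ / np.sqrt(100_000))
    assert draws.std(ddof=1) == pytest.approx(m.sd_, rel=0.03)
    assert (draws > 0).all()


# -- stepwise ----------------------------------------------------------------

def test_stepwise_selects_dominant_effect():
    design = ip.generate_dsd(4)
    X = pd.DataFrame(design, columns=["x1", "x2", "x3", "x4"])
    rng = np.random.default_rng(21)
    y = 10.0 + 3.0 * design[:, 0] + rng.normal(0, 0.05, len(design))
    cands = [Term("main", (f,)) for f in X.columns]
    sw = ip.fit_stepwise(
        ip.DoEDataset(runs=X.assign(**{"sc.Y": y}), pp_names=list(X.columns),
                      response_names=["Y"]),
        "Y",
        cands,
    )
    assert {t.label for t in sw.selected_terms_} == {"x1"}


def test_stepwise_is_deterministic(scenario):
    doe = scenario["doe"]["CC1"]
    a = ip.fit_stepwise(doe, "PRI2")
    b = ip.fit_stepwise(doe, "PRI2")
    assert [t.label for t in a.selected_terms_] == [t.label for t in b.selected_terms_]
    np.testing.assert_array_equal(a.model_.coef_, b.model_.coef_)


def test_stepwise_respects_degrees_of_freedom():
    """With more candidates than runs allow, the model never exhausts the
    residual degrees of freedom."""
    rng = np.random.default_rng(5)
    n = 7
    X = pd.DataFrame(rng.uniform(-1, 1, (n, 5)), columns=list("abcde"))
    y = rng.normal(0, 1, n)
    sw = ip.StepwiseOLS(tuple(build_candidate_terms(list("abcde")))).fit(X, y)
    assert sw.model_.p_ <= n - 2


def test_stepwise_serialization_roundtrip(scenario):
    fit = scenario["models"].get("CC1", "PRI2").doe_fit
    again = ip.ClearanceOLS.from_dict(fit.to_dict())
    point = {p.name: p.setpoint * 1.01 for p in scenario["process"].uo("CC1").pps}
    assert again.predict(point)[0] == pytest.approx(fit.predict(point)[0], rel=1e-12)
    assert again.predict_sd(point)[0] == pytest.approx(
        fit.predict_sd(point)[0], rel=1e-12
    )
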