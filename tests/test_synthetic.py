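"""Designs, ground-truth generation and the brute-force oracle."""

import numpy as np
import pytest
from scipy import stats

import ipmsim as ip
from ipmsim.config import AssignmentSpec, CQASpec, ModelKind, ProcessDefinition, ProductSpec, UnitOperationSpec
from ipmsim.errors import ConfigError
from ipmsim.synthetic import TrueConstant, SyntheticTruth, TruthConfig
from conftest import TINY, make_pp


# -- definitive screening designs -------------------------------------------

def test_dsd_five_factors_thirteen_runs():
    d = ip.generate_dsd(5)
    assert d.shape == (13, 5)  # 2(k+1) fold-over rows + center for odd k
    assert ip.generate_dsd(5, n_runs=15).shape == (15, 5)
    # full rank: all five main effects estimable
    assert np.linalg.matrix_rank(d) == 5


@pytest.mark.parametrize("k", range(4, 13))
def test_dsd_structure(k):
    d = ip.generate_dsd(k)
    noncenter = d[:-1]
    m = len(noncenter) // 2
    assert set(np.unique(d)) <= {-1.0, 0.0, 1.0}
    # rows come in fold-over pairs summing to zero
    np.testing.assert_array_equal(noncenter[:m] + noncenter[m:], 0.0)
    assert (d[-1] == 0).all()
    zeros = (noncenter == 0).sum(axis=1)
    if k % 2 == 0:
        # conference fold-over: exactly one mid level per run
        assert (zeros == 1).all()
    else:
        # column-dropped construction: one fold-over pair has no mid level
        assert set(zeros) == {0, 1} and (zeros == 0).sum() == 2


def test_dsd_even_k_orthogonal_mains():
    for k in (4, 6, 8, 10, 12):
        d = ip.generate_dsd(k)
        xtx = d.T @ d
        np.testing.assert_allclose(xtx, np.diag(np.diag(xtx)), atol=1e-12)


def test_dsd_bad_arguments():
    with pytest.raises(ConfigError):
        ip.generate_dsd(3)
    with pytest.raises(ConfigError):
        ip.generate_dsd(13)
    with pytest.raises(ConfigError):
        ip.generate_dsd(5, n_runs=10)


def test_full_factorial():
    assert ip.generate_full_factorial(3, center_reps=3).shape == (11, 3)
    assert ip.generate_full_factorial(1).shape == (2, 1)
    corners = ip.generate_full_factorial(4)
    np.testing.assert_allclose(corners.mean(axis=0), 0.0, atol=1e-15)
    with pytest.raises(ConfigError):
        ip.generate_full_factorial(5)


# -- ground truth ------------------------------------------------------------

def test_truth_reproducible():
    a = ip.generate_truth(seed=4)
    b = ip.generate_truth(seed=4)
    assert a.to_json() == b.to_json()
    c = ip.generate_truth(seed=5)
    assert c.to_json() != a.to_json()


def test_truth_template_counts(truth):
    assert len(truth.process.unit_operations) == 3
    n_assign = sum(len(u.assignments) for u in truth.process.unit_operations)
    assert n_assign == 15  # 12 CQA + 3 yield
    assert len(truth.spiking_models) >= 1
    assert len(truth.doe_models) + len(truth.constant_models) == 15


def test_truth_near_usl_calibration(truth):
    """The designated CQA sits at the target OOS; the others far below."""
    oos = ip.brute_force_oos(truth, n=200_000, seed=99)
    target = truth.config.target_oos
    assert oos["PRI2"] == pytest.approx(target, abs=0.01)
    for cqa in ("PRI1", "PCI1", "PCI2"):
        assert oos[cqa] < 0.001


def test_noiseless_doe_responses_lie_on_surface():
    cfg = TruthConfig(doe_resid_cv=0.0, yield_resid_sd=0.0, ls_cv=0.0)
    truth = ip.generate_truth(cfg, seed=6)
    ds = ip.simulate_doe_responses(truth, truth.designs["CC1"], "CC1",
                                   ip.substream(0, "d"))
    surf = truth.doe_models[("CC1", "PRI2")]
    pp = {name: ds.runs[name].to_numpy() for name in ds.pp_names}
    np.testing.assert_allclose(ds.response("PRI2"), surf.evaluate(pp), rtol=1e-12)


def test_doe_residual_sd_recovered():
    """fit_ols on simulated 13-run datasets recovers the true residual SD
    within 30% on average over 200 replicates."""
    truth = ip.generate_truth(seed=7)
    surf = truth.doe_models[("CC1", "PRI2")]
    rng = ip.substream(8, "reps")
    estimates = []
    for _ in range(200):
        ds = ip.simulate_doe_responses(truth, truth.designs["CC1"], "CC1", rng)
        fit = ip.fit_ols(ds, "PRI2", surf.terms)
        estimates.append(fit.residual_se_)
    assert np.mean(estimates) == pytest.approx(surf.residual_sd, rel=0.3)


def test_ls_campaign_shape_and_zero_variance():
    truth = ip.generate_truth(seed=9)
    ls = ip.simulate_ls_campaign(truth, 9, ip.substream(10, "ls"))
    assert ls.n_runs == 9
    cfg = TruthConfig(
        doe_resid_cv=0.0, yield_resid_sd=0.0, ls_cv=0.0, init_cv=0.0,
        product_init_cv=0.0, spiking_resid_cv=0.0, pp_std_scale=1e-9,
    )
    frozen = ip.generate_truth(cfg, seed=9)
    ls0 = ip.simulate_ls_campaign(frozen, 9, ip.substream(11, "ls"))
    for col in ls0.runs.columns:
        np.testing.assert_allclose(ls0.runs[col], ls0.runs[col].iloc[0], rtol=1e-6)


def test_constant_model_refit_from_campaign(truth):
    ls = ip.simulate_ls_campaign(truth, 9, ip.substream(12, "ls"))
    chain = [u.name for u in truth.process.unit_operations]
    true = truth.constant_models[("CC2", "PRI2")]
    fit = ip.fit_constant_model(ls.sc_values(chain, "CC2", "PRI2"))
    assert abs(fit.mean_ - true.mean) < 3 * true.sd / np.sqrt(9)


def test_brute_force_single_uo_matches_closed_form():
    mu, sigma, s0, usl = 10.0, 2.0, 4.0, 3.2
    pp = make_pp("p1", 1.0, TINY)
    process = ProcessDefinition(
        name="one",
        product=ProductSpec(init_mean=100.0, init_sd=TINY),
        cqas=[CQASpec(name="IMP", kind="process_related", usl=usl,
                      init_mean=mu, init_sd=sigma)],
        unit_operations=[
            UnitOperationSpec(
                name="U1", order_index=1, column_volume=10.0, pps=[pp],
                assignments={"IMP": AssignmentSpec(model_kind=ModelKind.CONSTANT_LS),
                             "yield": AssignmentSpec(model_kind=ModelKind.CONSTANT_LS)},
            )
        ],
    )
    truth = SyntheticTruth(process=process, config=TruthConfig(), seed=0)
    truth.constant_models[("U1", "IMP")] = TrueConstant(mean=s0, sd=0.0)
    truth.constant_models[("U1", "yield")] = TrueConstant(mean=0.9, sd=0.0)
    n = 200_000
    oos = ip.brute_force_oos(truth, n=n, seed=1)["IMP"]
    expected = stats.norm.sf((usl * s0 - mu) / sigma)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(oos - expected) < 3 * se
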