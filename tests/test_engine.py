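"""Monte Carlo engine: sampling, propagation, concatenation, OOS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ipmsim as ip
from ipmsim.errors import ConfigError
from conftest import TINY, make_chain_process, make_pp


# -- process-parameter sampling ---------------------------------------------

def test_pp_sampling_degenerate_sd_returns_setpoints():
    specs = [make_pp("a", 7.0, TINY), make_pp("b", 30.0, TINY, half_nor=5.0)]
    pp = ip.sample_process_parameters(specs, 10, ip.substream(0, "pp"))
    assert (pp["a"] == 7.0).all() and (pp["b"] == 30.0).all()


def test_pp_sampling_moments():
    # pH-like parameter: 1.61% relative SD around 7.0
    spec = make_pp("pH", 7.0, 7.0 * 0.0161, half_nor=0.25)
    pp = ip.sample_process_parameters([spec], 100_000, ip.substream(1, "pp"))
    se = spec.std / np.sqrt(100_000)
    assert pp["pH"].mean() == pytest.approx(7.0, abs=4 * se)
    assert pp["pH"].std(ddof=1) == pytest.approx(spec.std, rel=0.02)


def test_pp_sampling_independence():
    specs = [make_pp("a", 1.0, 0.1), make_pp("b", 2.0, 0.2)]
    pp = ip.sample_process_parameters(specs, 100_000, ip.substream(2, "pp"))
    assert abs(np.corrcoef(pp["a"], pp["b"])[0, 1]) < 0.02


# -- initial state -----------------------------------------------------------

def test_initial_state_moments_and_truncation():
    cqas = [
        ip.CQASpec(name="A", kind="process_related", usl=1.0, init_mean=5.0, init_sd=0.5),
        ip.CQASpec(name="B", kind="product_related", usl=1.0, init_mean=0.01, init_sd=1.0),
    ]
    counters = ip.FloorCounters()
    st = ip.sample_initial_state(cqas, 100.0, 5.0, 100_000, ip.substream(3, "i"), counters)
    assert st.c_cqa["A"].mean() == pytest.approx(5.0, abs=4 * 0.5 / np.sqrt(100_000))
    assert (st.c_cqa["B"] > 0).all()
    assert counters.total > 0  # mean barely above zero forces interventions
    assert (st.p_product > 0).all()


def test_initial_state_degenerate_sd_identical():
    cqas = [ip.CQASpec(name="A", kind="process_related", usl=1.0,
                       init_mean=5.0, init_sd=TINY)]
    st = ip.sample_initial_state(cqas, 100.0, TINY, 50, ip.substream(4, "i"))
    assert (st.c_cqa["A"] == 5.0).all() and (st.p_product == 100.0).all()


# -- propagation -------------------------------------------------------------

def test_single_step_clearance_arithmetic():
    process, models = make_chain_process([4.0], [0.9], init_mean=8.0)
    res = ip.run_simulation(process, models, n_sims=3, seed=0)
    np.testing.assert_allclose(res.final_concentration("IMP"), 2.0, rtol=1e-14)


def test_deterministic_chain_product():
    """SCs (2, 5, 10) divide the load by 100 exactly; SYs (0.9, 0.8, 0.95)
    retain 68.4% of product."""
    process, models = make_chain_process(
        [2.0, 5.0, 10.0], [0.9, 0.8, 0.95], init_mean=10.0, p_init_mean=100.0
    )
    res = ip.run_simulation(process, models, n_sims=2, seed=1)
    np.testing.assert_allclose(res.final_concentration("IMP"), 0.1, rtol=1e-12)
    np.testing.assert_allclose(res.final_product(), 68.4, rtol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_conservation_under_determinism_random_chains(seed):
    """With every model SD zero, final concentration is c_init / prod(SC)
    and product is p_init * prod(SY), to 1e-12 relative, chains of 1-5 UOs."""
    rng = np.random.default_rng(seed)
    n_uo = int(rng.integers(1, 6))
    scs = rng.uniform(1.5, 20.0, n_uo)
    sys_ = rng.uniform(0.7, 0.99, n_uo)
    process, models = make_chain_process(list(scs), list(sys_), init_mean=7.3)
    res = ip.run_simulation(process, models, n_sims=4, seed=seed)
    np.testing.assert_allclose(
        res.final_concentration("IMP"), 7.3 / np.prod(scs), rtol=1e-12
    )
    np.testing.assert_allclose(
        res.final_product(), 100.0 * np.prod(sys_), rtol=1e-12
    )


def test_spiking_increases_clearance_for_higher_load():
    """Two deterministic states differing x2 in load concentration: the
    spiking-enabled CQA clears more at the higher loading density."""
    ild_pts = np.array([1.0, 2.0, 3.0, 4.0])
    spk = ip.fit_spiking(list(zip(ild_pts, 2.0 + 0.5 * ild_pts)))  # noiseless
    from conftest import constant_assignment
    for c0 in (0.2, 0.4):
        process, models = make_chain_process([4.0], [1.0], init_mean=c0,
                                             usl=10.0, column_volume=10.0)
        models.set("U1", constant_assignment("IMP", 4.0, 0.0, spiking=spk))
        res = ip.run_simulation(process, models, n_sims=1, seed=0)
        sc_eff = c0 / res.final_concentration("IMP")[0]
        if c0 == 0.2:
            sc_low = sc_eff
    assert sc_eff > sc_low


# -- reproducibility and ablation -------------------------------------------

def test_seed_reproducibility_bit_identical(scenario):
    a = ip.run_simulation(scenario["process"], scenario["models"], 300, seed=5)
    b = ip.run_simulation(scenario["process"], scenario["models"], 300, seed=5)
    for cqa in a.cqa_names:
        np.testing.assert_array_equal(a.c_traj[cqa], b.c_traj[cqa])
    np.testing.assert_array_equal(a.p_traj, b.p_traj)
    for uo in a.uo_names:
        pd.testing.assert_frame_equal(a.pp_samples[uo], b.pp_samples[uo])


def test_spiking_neutral_at_mean_ild_draw_for_draw():
    """With zero spiking SD and the loading density pinned at the mean DoE
    ILD, runs with and without the spiking component are identical
    draw-for-draw (independent substreams per component)."""
    c0, p0, cv = 0.5, 100.0, 10.0
    ild0 = c0 * p0 / cv  # deterministic incoming ILD = 5.0
    pts = ild0 * np.array([0.5, 1.5, 0.75, 1.25, 1.0])  # mean exactly ild0
    spk = ip.fit_spiking(list(zip(pts, 3.0 + 0.8 * pts)))  # noiseless line
    assert spk.mean_ild_ == ild0
    from conftest import constant_assignment
    process, models = make_chain_process(
        [4.0], [1.0], init_mean=c0, p_init_mean=p0, column_volume=cv,
        sc_sds=[0.3],
    )
    models.set("U1", constant_assignment("IMP", 4.0, 0.3, spiking=spk))
    on = ip.run_simulation(process, models, 500, seed=9)
    off = ip.run_simulation(process, models, 500, seed=9, disable_spiking=True)
    # same substream consumption; the neutral multiplicative factor can
    # perturb the last bit only
    np.testing.assert_allclose(on.c_traj["IMP"], off.c_traj["IMP"], rtol=1e-14)
    np.testing.assert_array_equal(on.p_traj, off.p_traj)


def test_unfitted_assignment_rejected_before_sampling():
    process, models = make_chain_process([2.0], [0.9])
    del models.assignments["U1"]["yield"]
    with pytest.raises(ConfigError, match="unfitted"):
        ip.run_simulation(process, models, 10, seed=0)


# -- OOS estimation ----------------------------------------------------------

def test_oos_counting():
    process, models = make_chain_process([2.0], [0.9], init_mean=10.0, usl=100.0)
    res = ip.run_simulation(process, models, n_sims=1000, seed=0)
    # craft the final stage: 91 of 1000 above the limit
    res.c_traj["IMP"][-1] = np.where(np.arange(1000) < 91, 200.0, 1.0)
    table = ip.estimate_oos(res, process.cqas)
    assert table.loc["IMP", "oos"] == pytest.approx(0.091)
    assert table.loc["IMP", "ci_low"] < 0.091 < table.loc["IMP", "ci_high"]
    res.c_traj["IMP"][-1] = np.full(1000, 1.0)
    assert ip.estimate_oos(res, process.cqas).loc["IMP", "oos"] == 0.0


def test_oos_closed_form_constant_clearance():
    """Single constant-clearance step, fixed SC: OOS has the closed form
    1 - Phi((usl*s0 - mu)/sigma)."""
    mu, sigma, s0, usl = 10.0, 2.0, 4.0, 3.0
    process, models = make_chain_process(
        [s0], [0.9], init_mean=mu, init_sd=sigma, usl=usl
    )
    n = 40_000
    res = ip.run_simulation(process, models, n_sims=n, seed=3)
    expected = stats.norm.sf((usl * s0 - mu) / sigma)
    se = np.sqrt(expected * (1 - expected) / n)
    oos = ip.estimate_oos(res, process.cqas).loc["IMP", "oos"]
    assert abs(oos - expected) < 3 * se


def test_pool_distribution_positive_skew():
    """A clearance CV >= 10% makes the pool a ratio of normals with
    positive skewness."""
    process, models = make_chain_process(
        [4.0], [0.9], init_mean=10.0, init_sd=TINY, sc_sds=[0.5]
    )
    res = ip.run_simulation(process, models, n_sims=20_000, seed=7)
    assert stats.skew(res.final_concentration("IMP")) > 0


def test_oos_monotone_in_initial_burden():
    """Increasing the initial mean under common random numbers never
    decreases the estimated OOS (no spiking models)."""
    oos_vals = []
    for mu in (8.0, 10.0, 12.0):
        process, models = make_chain_process(
            [4.0], [0.9], init_mean=mu, init_sd=2.0, usl=3.0, sc_sds=[0.2]
        )
        res = ip.run_simulation(process, models, n_sims=4000, seed=8)
        oos_vals.append(ip.estimate_oos(res, process.cqas).loc["IMP", "oos"])
    assert oos_vals == sorted(oos_vals)


def test_trajectories_complete_under_floor_stress():
    """Pathological clearance (mean 0.5, SD 5): the floor policy keeps every
    simulation finite and present."""
    process, models = make_chain_process(
        [0.5], [0.9], init_mean=10.0, sc_sds=[5.0]
    )
    res = ip.run_simulation(process, models, n_sims=2000, seed=9)
    assert np.isfinite(res.final_concentration("IMP")).all()
    assert res.floor.total > 0
    assert res.to_trajectories_frame().shape[0] == 2000 * 2  # load + 1 UO
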