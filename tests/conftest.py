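"""Shared fixtures: the synthetic three-column scenario and small crafted
processes with analytically known behavior."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ipmsim as ip
from ipmsim.config import (
    AssignmentSpec,
    CQASpec,
    ModelKind,
    ProcessDefinition,
    ProcessParameterSpec,
    ProductSpec,
    UnitOperationSpec,
)
from ipmsim.models import ModelAssignment, ModelSet

SCENARIO_SEED = 2026

# effectively-zero SD: keeps the schema's std > 0 invariant while adding
# nothing to double-precision values of order one
TINY = 1e-300


@pytest.fixture(scope="session")
def truth():
    return ip.generate_truth(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario(truth):
    """Truth plus simulated datasets and the fitted model set."""
    seed = SCENARIO_SEED
    proc = truth.process
    doe = {
        u.name: ip.simulate_doe_responses(
            truth, truth.designs[u.name], u.name, ip.substream(seed, "doe", u.name)
        )
        for u in proc.unit_operations
    }
    ls = ip.simulate_ls_campaign(truth, 9, ip.substream(seed, "ls"))
    spiking = {
        key: ip.simulate_spiking_dataset(truth, *key, ip.substream(seed, "spk", *key))
        for key in truth.spiking_models
    }
    report = ip.fit_model_set(proc, doe, ls, spiking)
    return {
        "truth": truth,
        "process": proc,
        "doe": doe,
        "ls": ls,
        "spiking": spiking,
        "report": report,
        "models": report.models,
    }


def make_pp(name="p1", setpoint=1.0, std=TINY, half_nor=0.5, unit="") -> ProcessParameterSpec:
    return ProcessParameterSpec(
        name=name, unit=unit, setpoint=setpoint, std=std,
        nor_low=setpoint - half_nor, nor_high=setpoint + half_nor,
    )


def constant_assignment(response: str, mean: float, sd: float = 0.0,
                        spiking=None) -> ModelAssignment:
    const = ip.ConstantClearance()
    const.mean_, const.sd_, const.n_ = float(mean), float(sd), 9
    return ModelAssignment(
        response=response, model_kind=ModelKind.CONSTANT_LS,
        constant_model=const, spiking=spiking,
    )


def make_chain_process(
    sc_means,
    sy_means,
    init_mean=10.0,
    init_sd=TINY,
    usl=100.0,
    sc_sds=None,
    sy_sds=None,
    p_init_mean=100.0,
    p_init_sd=TINY,
    cqa_name="IMP",
    column_volume=10.0,
):
    """A chain of constant-clearance unit operations with one CQA.

    Returns (process, models).  With all SDs zero the final state is the
    exact deterministic product/quotient of the chain.
    """
    sc_sds = sc_sds or [0.0] * len(sc_means)
    sy_sds = sy_sds or [0.0] * len(sy_means)
    uos = []
    models = ModelSet()
    for i, (sc, sy) in enumerate(zip(sc_means, sy_means)):
        name = f"U{i + 1}"
        uos.append(
            UnitOperationSpec(
                name=name,
                order_index=i + 1,
                column_volume=column_volume,
                pps=[make_pp(f"p{i + 1}")],
                assignments={
                    cqa_name: AssignmentSpec(model_kind=ModelKind.CONSTANT_LS),
                    "yield": AssignmentSpec(model_kind=ModelKind.CONSTANT_LS),
                },
            )
        )
        models.set(name, constant_assignment(cqa_name, sc, sc_sds[i]))
        models.set(name, constant_assignment("yield", sy, sy_sds[i]))
    process = ProcessDefinition(
        name="chain",
        product=ProductSpec(init_mean=p_init_mean, init_sd=p_init_sd),
        cqas=[
            CQASpec(name=cqa_name, kind="process_related", usl=usl,
                    init_mean=init_mean, init_sd=max(init_sd, TINY))
        ],
        unit_operations=uos,
    )
    return process, models
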