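"""One-at-a-time parameter sensitivity analysis of the OOS probability.

Three perturbation families mirror the questions asked of an integrated
process model: what happens to drug-substance out-of-specification
probability when (a) a process-parameter set-point shifts, (b) the
routine variance of a process parameter grows or shrinks, and (c) the
initial impurity burden after primary recovery changes.

Every grid always contains the 0% point, and all grid points are run
with common random numbers (the same master seed, hence the same named
substreams), so the 0% point reproduces the baseline simulation
bit-for-bit and the OOS curves are smooth in the perturbation rather
than jittered by Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import ProcessDefinition
from .engine import estimate_oos, run_simulation
from .errors import ConfigError
from .models import ModelSet

__all__ = ["PSAResult", "psa_setpoint", "psa_variance", "psa_initial_burden"]

SETPOINT_GRID = (-10.0, -7.5, -5.0, -2.5, 0.0, 2.5, 5.0, 7.5, 10.0)
VARIANCE_GRID = (-50.0, -37.5, -25.0, -12.5, 0.0, 12.5, 25.0, 37.5, 50.0)
BURDEN_GRID = (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0)


@dataclass
class PSAResult:
    """OOS probability per grid point and CQA, with Wilson intervals."""

    target: str
    kind: str  # "setpoint" | "variance" | "init_burden"
    grid: list[float]
    oos: pd.DataFrame      # index: grid point (%), columns: CQA
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_sims: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy curve table: one row per grid point and CQA."""
        rows = []
        for g in self.grid:
            for cqa in self.oos.columns:
                rows.append(
                    {
                        "target": self.target,
                        "kind": self.kind,
                        "change_pct": g,
                        "cqa": cqa,
                        "oos": self.oos.loc[g, cqa],
                        "ci_low": self.ci_low.loc[g, cqa],
                        "ci_high": self.ci_high.loc[g, cqa],
                    }
                )
        return pd.DataFrame(rows)


def _resolve_pp(process: ProcessDefinition, pp_id: str) -> tuple[str, str]:
    """Resolve '<uo>.<pp>' or a bare PP name unique across the chain."""
    if "." in pp_id:
        uo_name, pp_name = pp_id.split(".", 1)
        process.uo(uo_name).pp(pp_name)  # raises if unknown
        return uo_name, pp_name
    hits = [
        (u.name, pp_id) for u in process.unit_operations if pp_id in u.pp_names
    ]
    if not hits:
        raise ConfigError(f"unknown process parameter {pp_id!r}")
    if len(hits) > 1:
        raise ConfigError(
            f"process parameter {pp_id!r} appears in several unit operations; "
            f"qualify as '<uo>.{pp_id}'"
        )
    return hits[0]


def _sweep(
    process: ProcessDefinition,
    models: ModelSet,
    target: str,
    kind: str,
    grid: Sequence[float],
    mutate: Callable[[ProcessDefinition, float], None],
    n_sims: int,
    seed: int,
    disable_spiking: bool = False,
) -> PSAResult:
    grid = sorted(set(float(g) for g in grid) | {0.0})
    oos, lo, hi = {}, {}, {}
    for g in grid:
        p = process.model_copy(deep=True)
        mutate(p, g)
        result = run_simulation(
            p, models, n_sims=n_sims, seed=seed, disable_spiking=disable_spiking
        )
        table = estimate_oos(result, p.cqas)
        oos[g] = table["oos"]
        lo[g] = table["ci_low"]
        hi[g] = table["ci_high"]
    return PSAResult(
        target=target,
        kind=kind,
        grid=list(grid),
        oos=pd.DataFrame(oos).T,
        ci_low=pd.DataFrame(lo).T,
        ci_high=pd.DataFrame(hi).T,
        n_sims=n_sims,
        seed=seed,
    )


def psa_setpoint(
    process: ProcessDefinition,
    models: ModelSet,
    pp_id: str,
    shifts_pct: Sequence[float] = SETPOINT_GRID,
    n_sims: int = 1000,
    seed: int = 0,
    max_shift_pct: float = 50.0,
    disable_spiking: bool = False,
) -> PSAResult:
    """OOS response to relative set-point shifts of one process parameter."""
    uo_name, pp_name = _resolve_pp(process, pp_id)
    if any(abs(s) > max_shift_pct for s in shifts_pct):
        raise ConfigError(f"set-point shifts beyond +/-{max_shift_pct}% rejected")

    def mutate(p: ProcessDefinition, g: float) -> None:
        spec = p.uo(uo_name).pp(pp_name)
        new = spec.setpoint * (1.0 + g / 100.0)
        # widen the NOR first so the nor_low < setpoint < nor_high
        # invariant holds while the set-point moves
        spec.nor_low = min(spec.nor_low, new - 1e-12 * max(1.0, abs(new)))
        spec.nor_high = max(spec.nor_high, new + 1e-12 * max(1.0, abs(new)))
        spec.setpoint = new

    return _sweep(
        process, models, f"{uo_name}.{pp_name}", "setpoint",
        shifts_pct, mutate, n_sims, seed, disable_spiking,
    )


def psa_variance(
    process: ProcessDefinition,
    models: ModelSet,
    pp_id: str,
    scale_pct: Sequence[float] = VARIANCE_GRID,
    n_sims: int = 1000,
    seed: int = 0,
    disable_spiking: bool = False,
) -> PSAResult:
    """OOS response to scaling the routine SD of one process parameter."""
    uo_name, pp_name = _resolve_pp(process, pp_id)
    if any(s <= -100.0 for s in scale_pct):
        raise ConfigError("variance scale must stay above -100%")

    def mutate(p: ProcessDefinition, g: float) -> None:
        spec = p.uo(uo_name).pp(pp_name)
        new_std = spec.std * (1.0 + g / 100.0)
        if new_std <= 0:
            new_std = 1e-300  # exact zero violates std > 0; draws are unchanged below ~1e-290
        spec.std = new_std

    return _sweep(
        process, models, f"{uo_name}.{pp_name}", "variance",
        scale_pct, mutate, n_sims, seed, disable_spiking,
    )


def psa_initial_burden(
    process: ProcessDefinition,
    models: ModelSet,
    cqa_id: str,
    shifts_pct: Sequence[float] = BURDEN_GRID,
    n_sims: int = 1000,
    seed: int = 0,
    disable_spiking: bool = False,
) -> PSAResult:
    """OOS response to shifting the initial specific concentration of one CQA."""
    process.cqa(cqa_id)  # raises if unknown

    def mutate(p: ProcessDefinition, g: float) -> None:
        spec = p.cqa(cqa_id)
        spec.init_mean = spec.init_mean * (1.0 + g / 100.0)

    return _sweep(
        process, models, cqa_id, "init_burden", shifts_pct, mutate, n_sims, seed,
        disable_spiking,
    )
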