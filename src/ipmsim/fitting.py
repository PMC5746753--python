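"""Fit every declared model assignment of a process from datasets.

For each unit operation and response the declared model kind decides the
route: DoE assignments run stepwise selection on the unit operation's
DoE dataset (falling back to a constant large-scale clearance, with a
note, when no candidate term enters the model — the standard practice
when no process parameter shows a significant effect); constant
assignments take mean and sample SD of the large-scale specific
clearances; spiking-flagged CQAs additionally get a clearance-vs-
loading-density regression which is attached only if it passes the
significance screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import DoEDataset, LSDataset, ModelKind, ProcessDefinition
from .errors import ConfigError, DatasetError, IPMError
from .models import ModelAssignment, ModelSet
from .regression import ConstantClearance, StepwiseOLS, fit_constant_model
from .spiking import SpikingRegression, fit_spiking
from .terms import build_candidate_terms

__all__ = ["FitReport", "fit_model_set"]


@dataclass
class FitReport:
    """Fitted models plus diagnostics and free-text notes."""

    models: ModelSet
    diagnostics: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def _fit_doe(
    uo_name: str,
    response: str,
    doe: DoEDataset,
    ls_values: np.ndarray | None,
    p_enter: float,
    p_remove: float,
    include_interactions: bool,
    include_quadratics: bool,
    notes: list[str],
) -> tuple[ModelAssignment, dict]:
    candidates = build_candidate_terms(
        doe.pp_names,
        include_interactions=include_interactions,
        include_quadratics=include_quadratics,
    )
    sw = StepwiseOLS(tuple(candidates), p_enter=p_enter, p_remove=p_remove)
    sw.fit(doe.pp_values(), doe.response(response))
    if sw.selected_terms_:
        fit = sw.model_
        diag = {
            "model": "doe",
            "terms": " + ".join(t.label for t in fit.terms),
            "min_p": float(np.min(fit.pvalues_)),
            "r2": fit.r2_,
            "fallback": False,
        }
        return (
            ModelAssignment(response=response, model_kind=ModelKind.DOE, doe_fit=fit),
            diag,
        )
    # no significant PP effect: the mean large-scale clearance is taken
    if ls_values is None:
        raise ConfigError(
            f"{uo_name}:{response}: no term entered the DoE model and no "
            "large-scale data available for the constant fallback"
        )
    notes.append(
        f"{uo_name}:{response}: no process parameter entered the model; "
        "fell back to the constant large-scale clearance"
    )
    const = fit_constant_model(ls_values)
    diag = {"model": "constant_ls", "terms": "", "min_p": float("nan"),
            "r2": float("nan"), "fallback": True}
    return (
        ModelAssignment(
            response=response, model_kind=ModelKind.CONSTANT_LS, constant_model=const
        ),
        diag,
    )


def fit_model_set(
    process: ProcessDefinition,
    doe_data: Mapping[str, DoEDataset],
    ls: LSDataset | None = None,
    spiking_data: Mapping[tuple[str, str], pd.DataFrame] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    include_interactions: bool = True,
    include_quadratics: bool = True,
    include_ls_spiking_points: bool = True,
    spiking_alpha: float = 0.05,
    spiking_max_gap: float = 0.3,
) -> FitReport:
    """Fit all assignments; aggregate every failure into one error."""
    spiking_data = spiking_data or {}
    chain = [u.name for u in process.unit_operations]
    models = ModelSet()
    notes: list[str] = []
    failures: list[str] = []
    rows = []
    for uo in process.unit_operations:
        for response, aspec in uo.assignments.items():
            row = {"uo": uo.name, "response": response}
            try:
                ls_values = None
                if ls is not None:
                    try:
                        ls_values = (
                            ls.yields(uo.name)
                            if response == "yield"
                            else ls.sc_values(chain, uo.name, response)
                        )
                    except DatasetError:
                        ls_values = None
                if aspec.model_kind == ModelKind.DOE:
                    if uo.name not in doe_data:
                        raise ConfigError(
                            f"{uo.name}:{response}: DoE assignment but no DoE dataset"
                        )
                    assignment, diag = _fit_doe(
                        uo.name, response, doe_data[uo.name], ls_values,
                        p_enter, p_remove,
                        include_interactions, include_quadratics, notes,
                    )
                    row.update(diag)
                else:
                    if ls_values is None or len(ls_values) < 2:
                        raise ConfigError(
                            f"{uo.name}:{response}: constant model requires "
                            "large-scale data (>= 2 runs)"
                        )
                    const = fit_constant_model(ls_values)
                    assignment = ModelAssignment(
                        response=response,
                        model_kind=ModelKind.CONSTANT_LS,
                        constant_model=const,
                    )
                    row.update(
                        {"model": "constant_ls", "terms": "", "min_p": float("nan"),
                         "r2": float("nan"), "fallback": False}
                    )
                if aspec.spiking:
                    key = (uo.name, response)
                    if key not in spiking_data:
                        raise ConfigError(
                            f"{uo.name}:{response}: spiking declared but no "
                            "spiking dataset provided"
                        )
                    spk = fit_spiking(
                        spiking_data[key], include_ls=include_ls_spiking_points
                    )
                    row["spiking_p"] = spk.pvalue_
                    row["spiking_q2"] = spk.q2_
                    if spk.passes_screen(alpha=spiking_alpha, max_r2_q2_gap=spiking_max_gap):
                        assignment.spiking = spk
                        row["spiking"] = True
                    else:
                        row["spiking"] = False
                        notes.append(
                            f"{uo.name}:{response}: spiking model failed the "
                            f"significance screen (p={spk.pvalue_:.3g}, "
                            f"R2-Q2={spk.r2_ - spk.q2_:.3g}); not attached"
                        )
                models.set(uo.name, assignment)
            except IPMError as exc:
                failures.append(str(exc))
            rows.append(row)
    if failures:
        raise ConfigError(
            "could not fit all assignments:\n  " + "\n  ".join(failures)
        )
    diagnostics = pd.DataFrame(rows)
    return FitReport(models=models, diagnostics=diagnostics, notes=notes)
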