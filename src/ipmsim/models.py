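"""Fitted model assignments: which model governs which response where.

A :class:`ModelAssignment` binds one response (a CQA clearance or the
step yield) at one unit operation to exactly one fitted base model — a
DoE response surface (:class:`~ipmsim.regression.ClearanceOLS`) or a
constant large-scale clearance
(:class:`~ipmsim.regression.ConstantClearance`) — plus an optional
multiplicative spiking component.  A :class:`ModelSet` collects the
assignments for a whole process and serializes to a single JSON file so
simulations can run without access to any raw data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from ._sampling import FloorCounters
from .config import ModelKind, ProcessDefinition
from .errors import ConfigError
from .regression import ClearanceOLS, ConstantClearance
from .spiking import SpikingRegression, combine_clearances

__all__ = ["ModelAssignment", "ModelSet"]


@dataclass
class ModelAssignment:
    """One response's fitted clearance/yield model at one unit operation."""

    response: str
    model_kind: ModelKind
    doe_fit: Optional[ClearanceOLS] = None
    constant_model: Optional[ConstantClearance] = None
    spiking: Optional[SpikingRegression] = None

    def __post_init__(self):
        if self.model_kind == ModelKind.DOE:
            if self.doe_fit is None or self.constant_model is not None:
                raise ConfigError(
                    f"assignment {self.response!r}: model_kind 'doe' requires "
                    "doe_fit and no constant_model"
                )
        else:
            if self.constant_model is None or self.doe_fit is not None:
                raise ConfigError(
                    f"assignment {self.response!r}: model_kind 'constant_ls' requires "
                    "constant_model and no doe_fit"
                )
        if self.spiking is not None and self.response == "yield":
            raise ConfigError("spiking models never attach to the yield response")

    def sample_base(
        self,
        pp_rows,
        n: int,
        rng: np.random.Generator,
        cap: float | None = None,
        counters: FloorCounters | None = None,
    ) -> np.ndarray:
        """Draw the PP-driven clearance (or yield), one value per simulation."""
        if self.model_kind == ModelKind.DOE:
            return self.doe_fit.sample(pp_rows, rng, cap=cap, counters=counters)
        return self.constant_model.sample(rng, size=n, cap=cap, counters=counters)

    def sample(
        self,
        pp_rows,
        n: int,
        rng_model: np.random.Generator,
        rng_spiking: np.random.Generator,
        ild: np.ndarray | None = None,
        cap: float | None = None,
        disable_spiking: bool = False,
        counters: FloorCounters | None = None,
    ) -> np.ndarray:
        base = self.sample_base(pp_rows, n, rng_model, cap=cap, counters=counters)
        if self.spiking is not None and not disable_spiking:
            if ild is None:
                raise ConfigError(
                    f"assignment {self.response!r} has a spiking model but no ILD"
                )
            draw = self.spiking.sample(ild, rng_spiking, counters=counters)
            base = combine_clearances(base, draw, self.spiking.sc_at_mean_ild_)
        return base

    def to_dict(self) -> dict:
        d: dict = {"response": self.response, "model_kind": self.model_kind.value}
        if self.doe_fit is not None:
            d["doe_fit"] = self.doe_fit.to_dict()
        if self.constant_model is not None:
            d["constant_model"] = self.constant_model.to_dict()
        if self.spiking is not None:
            d["spiking"] = self.spiking.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelAssignment":
        return cls(
            response=d["response"],
            model_kind=ModelKind(d["model_kind"]),
            doe_fit=ClearanceOLS.from_dict(d["doe_fit"]) if "doe_fit" in d else None,
            constant_model=(
                ConstantClearance.from_dict(d["constant_model"])
                if "constant_model" in d
                else None
            ),
            spiking=SpikingRegression.from_dict(d["spiking"]) if "spiking" in d else None,
        )


@dataclass
class ModelSet:
    """All fitted assignments of a process, keyed by unit operation."""

    assignments: dict[str, dict[str, ModelAssignment]] = field(default_factory=dict)

    def get(self, uo: str, response: str) -> ModelAssignment:
        try:
            return self.assignments[uo][response]
        except KeyError:
            raise ConfigError(f"no fitted model for response {response!r} at {uo!r}")

    def set(self, uo: str, assignment: ModelAssignment) -> None:
        self.assignments.setdefault(uo, {})[assignment.response] = assignment

    def validate_against(self, process: ProcessDefinition) -> None:
        """Every declared assignment must be fitted before any sampling."""
        missing = []
        for u in process.unit_operations:
            for resp in u.assignments:
                if resp not in self.assignments.get(u.name, {}):
                    missing.append(f"{u.name}:{resp}")
        if missing:
            raise ConfigError("unfitted assignments: " + ", ".join(sorted(missing)))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            uo: {resp: a.to_dict() for resp, a in by_resp.items()}
            for uo, by_resp in self.assignments.items()
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelSet":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = json.loads(text)
        ms = cls()
        for uo, by_resp in payload.items():
            for resp, d in by_resp.items():
                ms.set(uo, ModelAssignment.from_dict(d))
        return ms
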