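"""Process definitions and tabular datasets.

A process definition is the static description of the purification
train: the ordered unit operations (preparative chromatography columns),
their process parameters (PPs) with set-points and routine-manufacturing
standard deviations, the critical quality attributes (CQAs, specific
impurity concentrations), upper specification limits, the distribution
of each CQA at the load of the first modeled column, and — per unit
operation and response — which kind of clearance model applies.

Configuration files are YAML (JSON, being a YAML subset, is accepted).
Schema (all keys lower case)::

    name: my-process
    product:
      init_mean: 1000.0      # product amount at the first load
      init_sd: 50.0
    cqas:
      - name: PRI1
        kind: product_related   # or process_related
        usl: 0.5                # upper specification limit (specific conc.)
        init_mean: 0.9
        init_sd: 0.2
    unit_operations:
      - name: CC1
        order_index: 1
        column_volume: 50.0
        pps:
          - name: pH
            unit: "-"
            setpoint: 7.0
            rel_std_pct: 1.61   # or absolute: std: 0.113
            nor_low: 6.75
            nor_high: 7.25
        assignments:
          PRI1: {model_kind: doe}
          PCI2: {model_kind: constant_ls, spiking: true}
          yield: {model_kind: doe}

Only *upper* specification limits are modeled; a ``lsl`` key is rejected
by the schema.

Dataset CSV conventions (UTF-8, header row, one run per row, decimal
point):

* DoE datasets: PP columns named exactly like the PPs, response columns
  ``sc.<CQA>`` (specific clearance) and ``yield`` (step yield), optional
  ``ild.<CQA>`` impurity loading densities.
* Large-scale (LS) datasets: ``init.<CQA>`` load-of-first-column
  specific concentrations, ``init.product`` product amount, and per unit
  operation ``<UO>.<CQA>`` pool specific concentrations, ``<UO>.yield``
  step yields and optional ``<UO>.pp.<PP>`` settings.  Empty cells are
  treated as below the limit of quantification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError, DatasetError

__all__ = [
    "ProcessParameterSpec",
    "CQASpec",
    "ProductSpec",
    "AssignmentSpec",
    "UnitOperationSpec",
    "ProcessDefinition",
    "ModelKind",
    "DoEDataset",
    "LSDataset",
    "load_process_definition",
    "write_process_definition",
    "load_dataset",
]


class ModelKind(str, enum.Enum):
    DOE = "doe"
    CONSTANT_LS = "constant_ls"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ProcessParameterSpec(_StrictModel):
    """A controlled process parameter and its routine sampling distribution.

    ``std`` is the absolute standard deviation under routine
    manufacturing; it may instead be supplied as ``rel_std_pct`` (percent
    of set-point, the way large-scale variability tables usually quote
    it) and is stored internally as absolute:
    ``std = setpoint * rel_std_pct / 100``.  Note this treats pH like any
    other parameter even though a relative SD on a log-scale quantity is
    a convention rather than a ratio.
    """

    name: str
    unit: str = ""
    setpoint: float
    std: Optional[float] = None
    rel_std_pct: Optional[float] = None
    nor_low: float
    nor_high: float

    @model_validator(mode="after")
    def _check(self):
        if self.std is None:
            if self.rel_std_pct is None:
                raise ValueError(f"PP {self.name!r}: give either std or rel_std_pct")
            object.__setattr__(self, "std", self.setpoint * self.rel_std_pct / 100.0)
        if self.std is None or self.std <= 0:
            raise ValueError(f"PP {self.name!r}: std must be > 0")
        if not (self.nor_low < self.setpoint < self.nor_high):
            raise ValueError(
                f"PP {self.name!r}: setpoint {self.setpoint} outside normal "
                f"operating range ({self.nor_low}, {self.nor_high})"
            )
        return self

    @property
    def half_nor(self) -> float:
        return 0.5 * (self.nor_high - self.nor_low)


class CQASpec(_StrictModel):
    """A critical quality attribute: a specific impurity concentration.

    ``usl`` is the upper specification limit at drug substance;
    ``init_mean`` / ``init_sd`` parameterize the normal distribution of
    the specific concentration at the load of the first modeled unit
    operation, estimated from large-scale runs.
    """

    name: str
    kind: Literal["process_related", "product_related"]
    usl: float = Field(gt=0)
    init_mean: float = Field(gt=0)
    init_sd: float = Field(gt=0)


class ProductSpec(_StrictModel):
    """Distribution of the product amount at the first load."""

    init_mean: float = Field(gt=0)
    init_sd: float = Field(ge=0)


class AssignmentSpec(_StrictModel):
    """Which model kind governs one response at one unit operation."""

    model_kind: ModelKind
    spiking: bool = False


class UnitOperationSpec(_StrictModel):
    name: str
    order_index: int
    column_volume: float = Field(gt=0)
    pps: list[ProcessParameterSpec] = Field(min_length=1)
    assignments: dict[str, AssignmentSpec]

    @model_validator(mode="after")
    def _check(self):
        names = [p.name for p in self.pps]
        if len(set(names)) != len(names):
            raise ValueError(f"unit operation {self.name!r}: duplicate PP names")
        if self.assignments.get("yield") is not None and self.assignments["yield"].spiking:
            raise ValueError(
                f"unit operation {self.name!r}: spiking models apply to impurity "
                "clearances, never to yield"
            )
        return self

    @property
    def pp_names(self) -> list[str]:
        return [p.name for p in self.pps]

    def pp(self, name: str) -> ProcessParameterSpec:
        for p in self.pps:
            if p.name == name:
                return p
        raise ConfigError(f"unit operation {self.name!r} has no PP {name!r}")


class ProcessDefinition(_StrictModel):
    """The ordered chain of unit operations with CQA and PP specifications."""

    name: str = "process"
    product: ProductSpec
    cqas: list[CQASpec] = Field(min_length=1)
    unit_operations: list[UnitOperationSpec] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self):
        cqa_names = [c.name for c in self.cqas]
        if len(set(cqa_names)) != len(cqa_names):
            raise ValueError("duplicate CQA names")
        order = [u.order_index for u in self.unit_operations]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValueError("order_index must be strictly increasing along the chain")
        uo_names = [u.name for u in self.unit_operations]
        if len(set(uo_names)) != len(uo_names):
            raise ValueError("duplicate unit operation names")
        expected = set(cqa_names) | {"yield"}
        for u in self.unit_operations:
            got = set(u.assignments)
            if got != expected:
                missing = sorted(expected - got)
                extra = sorted(got - expected)
                raise ValueError(
                    f"unit operation {u.name!r}: every CQA and 'yield' needs exactly "
                    f"one assignment (missing {missing}, unknown {extra})"
                )
        return self

    @property
    def cqa_names(self) -> list[str]:
        return [c.name for c in self.cqas]

    def cqa(self, name: str) -> CQASpec:
        for c in self.cqas:
            if c.name == name:
                return c
        raise ConfigError(f"no CQA named {name!r}")

    def uo(self, name: str) -> UnitOperationSpec:
        for u in self.unit_operations:
            if u.name == name:
                return u
        raise ConfigError(f"no unit operation named {name!r}")


def load_process_definition(path: str | Path) -> ProcessDefinition:
    """Parse and fully validate a process definition from YAML/JSON."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough detail
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ProcessDefinition(**data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid process definition:\n" + "\n".join(lines)) from exc


def write_process_definition(process: ProcessDefinition, path: str | Path) -> None:
    data = process.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

_SC_PREFIX = "sc."
_ILD_PREFIX = "ild."


@dataclass
class DoEDataset:
    """Design-of-experiments dataset for one unit operation.

    ``runs`` holds one row per DoE run, PP settings in natural units,
    specific clearances in ``sc.<CQA>`` columns, step yields in
    ``yield``, optional impurity loading densities in ``ild.<CQA>``.
    """

    runs: pd.DataFrame
    pp_names: list[str]
    response_names: list[str]
    ild_names: list[str] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def pp_values(self) -> pd.DataFrame:
        return self.runs[self.pp_names]

    def response(self, name: str) -> np.ndarray:
        col = name if name == "yield" else _SC_PREFIX + name
        if col not in self.runs.columns:
            raise DatasetError(f"dataset has no response column {col!r}")
        return self.runs[col].to_numpy(dtype=float)


@dataclass
class LSDataset:
    """Large-scale manufacturing campaign: per-run trajectories.

    Columns follow the dotted convention documented in the module
    docstring.  Missing pool concentrations (empty cells) are below the
    limit of quantification and excluded from any estimate.
    """

    runs: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def _col(self, name: str) -> np.ndarray:
        if name not in self.runs.columns:
            raise DatasetError(f"LS dataset has no column {name!r}")
        return self.runs[name].to_numpy(dtype=float)

    def init_conc(self, cqa: str) -> np.ndarray:
        return self._col(f"init.{cqa}")

    def init_product(self) -> np.ndarray:
        return self._col("init.product")

    def pool_conc(self, uo: str, cqa: str) -> np.ndarray:
        return self._col(f"{uo}.{cqa}")

    def yields(self, uo: str) -> np.ndarray:
        return self._col(f"{uo}.yield")

    def sc_values(self, chain: Sequence[str], uo: str, cqa: str) -> np.ndarray:
        """Specific clearances at ``uo``: load conc / pool conc per run.

        ``chain`` is the ordered unit-operation name list; the load of
        the first unit operation is the ``init.<cqa>`` column.  Runs
        where either value is missing are dropped.
        """
        chain = list(chain)
        idx = chain.index(uo)
        load = self.init_conc(cqa) if idx == 0 else self.pool_conc(chain[idx - 1], cqa)
        pool = self.pool_conc(uo, cqa)
        ok = np.isfinite(load) & np.isfinite(pool)
        if (pool[ok] <= 0).any():
            raise DatasetError(f"non-positive pool concentration for {uo}.{cqa}")
        return load[ok] / pool[ok]


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"{path}: no runs (empty file)") from exc
    if len(df) == 0:
        raise DatasetError(f"{path}: no runs")
    return df


def load_dataset(path: str | Path, kind: str) -> DoEDataset | LSDataset:
    """Load a CSV dataset; ``kind`` is ``"doe"`` or ``"ls"``.

    Validation: non-numeric cells, missing PP values and non-positive
    specific clearances are rejected with the offending row index; step
    yields must lie in (0, 1.1] (slightly above 1 tolerated as
    measurement noise).
    """
    df = _read_csv(path)
    if "run_id" in df.columns:
        df = df.set_index("run_id")
    if kind == "ls":
        value_cols = [c for c in df.columns if c != "run_id"]
        for c in value_cols:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        conc_cols = [c for c in df.columns if not c.endswith(".yield") and ".pp." not in c]
        for c in conc_cols:
            vals = df[c]
            bad = vals[vals < 0]
            if len(bad):
                raise DatasetError(
                    f"{path}: negative concentration in column {c!r}, rows {list(bad.index)}"
                )
        return LSDataset(runs=df)
    if kind != "doe":
        raise ConfigError(f"unknown dataset kind {kind!r}")

    sc_cols = [c for c in df.columns if c.startswith(_SC_PREFIX)]
    ild_cols = [c for c in df.columns if c.startswith(_ILD_PREFIX)]
    yield_cols = ["yield"] if "yield" in df.columns else []
    pp_cols = [c for c in df.columns if c not in sc_cols + ild_cols + yield_cols]
    if not sc_cols and not yield_cols:
        raise DatasetError(f"{path}: no response columns (sc.<CQA> or yield)")
    if not pp_cols:
        raise DatasetError(f"{path}: no process parameter columns")
    for c in df.columns:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[converted.isna() & df[c].notna()]
        if len(bad):
            raise DatasetError(f"{path}: non-numeric cells in column {c!r}, rows {list(bad)}")
        df[c] = converted
    missing_pp = df.index[df[pp_cols].isna().any(axis=1)]
    if len(missing_pp):
        raise DatasetError(f"{path}: missing PP values in rows {list(missing_pp)}")
    for c in sc_cols:
        bad = df.index[~(df[c] > 0)]
        if len(bad):
            raise DatasetError(
                f"{path}: specific clearance must be > 0 in column {c!r}, rows {list(bad)}"
            )
    for c in yield_cols:
        bad = df.index[~((df[c] > 0) & (df[c] <= 1.1))]
        if len(bad):
            raise DatasetError(
                f"{path}: step yield must be in (0, 1.1] in column {c!r}, rows {list(bad)}"
            )
    responses = [c[len(_SC_PREFIX) :] for c in sc_cols] + yield_cols
    return DoEDataset(
        runs=df,
        pp_names=pp_cols,
        response_names=responses,
        ild_names=[c[len(_ILD_PREFIX) :] for c in ild_cols],
    )
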