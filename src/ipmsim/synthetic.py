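"""Synthetic ground-truth processes, designs and datasets.

Real process-characterization data of this kind is proprietary, so every
other module is exercised against a synthetic three-column template that
mirrors the structure of an industrial purification train: three
preparative chromatography columns with 5/3/4 varied process parameters,
a 13-run definitive screening design (DSD), an 11-run full factorial
with center replicates and a 9-run DSD, a 9-run large-scale campaign,
two process-related and two product-related impurities plus a step
yield per column, and a mixed model pattern (DoE response surfaces,
constant large-scale clearances, four spiking components).

The generator owns the *true* coefficients and noise levels
(:class:`SyntheticTruth`), simulates the experiments other modules fit
models to, and provides a large-n brute-force simulation from the true
models as the oracle for end-to-end parameter-recovery testing.

Definitive screening designs are built from conference matrices
(zero-diagonal +/-1 matrices C with C'C = (n-1)I): fold-over pairs
[C; -C] plus center points.  Orders 6 and 14 use the Paley construction
over GF(q) with q = 5, 13; orders 8 and 12 the skew Paley construction
with q = 7, 11; order 10 the Paley construction over GF(9); order 4 a
literal skew matrix.  For an odd number of factors k, where no
conference matrix exists, the order-(k+1) matrix is used with its last
column dropped (the standard construction; 13 runs for k = 5).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._sampling import FLOOR, draw_positive
from ._streams import substream
from .config import (
    AssignmentSpec,
    CQASpec,
    DoEDataset,
    LSDataset,
    ModelKind,
    ProcessDefinition,
    ProductSpec,
    UnitOperationSpec,
)
from .errors import ConfigError
from .terms import Term

__all__ = [
    "generate_dsd",
    "truth_model_set",
    "generate_full_factorial",
    "TruthConfig",
    "SyntheticTruth",
    "generate_truth",
    "simulate_doe_responses",
    "simulate_spiking_dataset",
    "simulate_ls_campaign",
    "brute_force_oos",
    "TEMPLATES",
]


# ---------------------------------------------------------------------------
# Experimental designs
# ---------------------------------------------------------------------------

def _legendre(a: int, q: int) -> int:
    a %= q
    if a == 0:
        return 0
    return 1 if pow(a, (q - 1) // 2, q) == 1 else -1


def _conference_paley(q: int) -> np.ndarray:
    """Order q+1 conference matrix from quadratic residues mod prime q."""
    S = np.zeros((q, q), dtype=float)
    for i in range(q):
        for j in range(q):
            if i != j:
                S[i, j] = _legendre(i - j, q)
    n = q + 1
    C = np.zeros((n, n))
    C[0, 1:] = 1.0
    C[1:, 1:] = S
    C[1:, 0] = 1.0 if q % 4 == 1 else -1.0  # symmetric vs skew Paley
    return C


def _conference_gf9() -> np.ndarray:
    """Order 10 conference matrix via the quadratic character of GF(9)."""
    els = [(a, b) for a in range(3) for b in range(3)]

    def sub(u, v):
        return ((u[0] - v[0]) % 3, (u[1] - v[1]) % 3)

    def mul(u, v):  # GF(3)[x]/(x^2+1)
        return ((u[0] * v[0] - u[1] * v[1]) % 3, (u[0] * v[1] + u[1] * v[0]) % 3)

    squares = {mul(e, e) for e in els if e != (0, 0)}
    chi = lambda e: 0 if e == (0, 0) else (1 if e in squares else -1)
    S = np.array([[chi(sub(u, v)) for v in els] for u in els], dtype=float)
    C = np.zeros((10, 10))
    C[0, 1:] = 1.0
    C[1:, 0] = 1.0
    C[1:, 1:] = S
    return C


def _conference_matrix(n: int) -> np.ndarray:
    if n == 4:
        C = np.array(
            [
                [0, 1, 1, 1],
                [-1, 0, 1, -1],
                [-1, -1, 0, 1],
                [-1, 1, -1, 0],
            ],
            dtype=float,
        )
    elif n == 10:
        C = _conference_gf9()
    elif n in (6, 8, 12, 14):
        C = _conference_paley(n - 1)
    else:
        raise ConfigError(f"no conference matrix construction for order {n}")
    assert np.allclose(C.T @ C, (n - 1) * np.eye(n)), "conference matrix defect"
    return C


def generate_dsd(k_factors: int, n_runs: int | None = None) -> np.ndarray:
    """Definitive screening design in coded units (-1, 0, +1).

    For even k the base design is the conference-matrix fold-over
    [C; -C] plus one center row (2k + 1 runs, every non-center run with
    exactly one factor at its mid level).  For odd k no conference
    matrix of order k exists; the standard construction keeps all rows
    of the order-(k+1) matrix and drops its last column (2k + 3 runs,
    e.g. 13 runs for k = 5; the fold-over pair whose mid level sat in
    the dropped column has none).  Extra center replicates are appended
    to reach a requested ``n_runs``.
    """
    k = int(k_factors)
    if not 4 <= k <= 12:
        raise ConfigError(f"DSD supported for 4 <= k <= 12 factors, got {k}")
    if k % 2 == 0:
        D = _conference_matrix(k)
    else:
        D = _conference_matrix(k + 1)[:, :k]
    design = np.vstack([D, -D, np.zeros((1, k))])
    base = len(design)
    if n_runs is not None:
        if n_runs < base:
            raise ConfigError(f"DSD for k={k} needs at least {base} runs, got {n_runs}")
        design = np.vstack([design, np.zeros((n_runs - base, k))])
    return design


def generate_full_factorial(k_factors: int, center_reps: int = 0) -> np.ndarray:
    """Two-level full factorial (coded corners) plus center replicates."""
    k = int(k_factors)
    if k < 1 or k > 4:
        raise ConfigError(f"full factorial supported for 1 <= k <= 4 factors, got {k}")
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    if center_reps:
        corners = np.vstack([corners, np.zeros((center_reps, k))])
    return corners


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class TrueSurface:
    """True polynomial response surface, in coded (set-point, half-NOR) units."""

    terms: list[Term]
    beta0: float
    beta: list[float]
    residual_sd: float
    factor_center: dict[str, float]
    factor_scale: dict[str, float]

    def evaluate(self, pp: Mapping[str, np.ndarray]) -> np.ndarray:
        coded = {
            f: (np.asarray(pp[f], dtype=float) - self.factor_center[f])
            / self.factor_scale[f]
            for f in self.factor_center
        }
        out = np.full_like(next(iter(coded.values())), self.beta0, dtype=float)
        for b, t in zip(self.beta, self.terms):
            out = out + b * t.evaluate(coded)
        return out


@dataclass
class TrueConstant:
    mean: float
    sd: float


@dataclass
class TrueSpiking:
    """True linear clearance-vs-loading-density relation."""

    intercept: float
    slope: float
    residual_sd: float
    ild_ref: float  # anchor loading density (typical routine ILD)

    def evaluate(self, ild) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ild, dtype=float)


@dataclass
class TruthConfig:
    """Knobs of the synthetic template; defaults are the study conditions."""

    doe_resid_cv: float = 0.02       # DoE residual SD / base clearance
    ls_cv: float = 0.02              # LS run-to-run clearance CV
    spiking_resid_cv: float = 0.02
    yield_resid_sd: float = 0.008
    snr: float = 6.0                 # active effect size / residual SD
    init_cv: float = 0.20            # initial impurity burden CV
    product_init_mean: float = 1000.0
    product_init_cv: float = 0.05
    spiking_sensitivity: float = 0.3  # d ln SC / d ln ILD at routine loading
    target_oos: float = 0.07         # true OOS of the near-USL CQA
    near_usl_cqa: str = "PRI2"
    n_spiking_points: int = 10
    calibration_n: int = 200_000
    pp_std_scale: float = 1.0        # scales all PP routine SDs
    base_jitter: float = 0.15        # relative jitter of base levels across seeds


TEMPLATES: dict[str, TruthConfig] = {"three-column": TruthConfig()}

# (setpoint, unit, rel_std_pct, std/half-NOR ratio) per unit operation
_PP_TABLE: dict[str, list[tuple[str, float, str, float, float]]] = {
    "CC1": [
        ("pH", 7.0, "-", 1.61, 0.46),
        ("load_density", 30.0, "g/L", 12.05, 0.50),
        ("wash_strength", 150.0, "mM", 5.00, 0.62),
        ("elution_strength", 300.0, "mM", 5.00, 0.44),
        ("end_pooling", 2.0, "CV", 1.36, 0.40),
    ],
    "CC2": [
        ("pH", 5.5, "-", 0.79, 0.30),
        ("load_density", 25.0, "g/L", 4.84, 0.20),
        ("gradient_slope", 20.0, "%B", 5.00, 0.40),
    ],
    "CC3": [
        ("pH", 7.5, "-", 0.92, 0.35),
        ("load_density", 35.0, "g/L", 12.78, 0.30),
        ("gradient_slope", 15.0, "%B", 5.00, 0.40),
        ("wash_strength", 120.0, "mM", 5.00, 0.50),
    ],
}

_COLUMN_VOLUME = {"CC1": 50.0, "CC2": 30.0, "CC3": 20.0}
_DESIGNS = {"CC1": ("dsd", 13), "CC2": ("ff", 11), "CC3": ("dsd", 9)}

# (model kind, form) per response following the industrial template:
# form is "linear"/"quadratic" for DoE models, "spiking"/None for constants.
_PATTERN: dict[tuple[str, str], tuple[str, Optional[str]]] = {
    ("CC1", "PRI1"): ("doe", "linear"),
    ("CC1", "PRI2"): ("doe", "linear"),
    ("CC1", "PCI1"): ("doe", "quadratic"),
    ("CC1", "PCI2"): ("constant", "spiking"),
    ("CC1", "yield"): ("doe", "linear"),
    ("CC2", "PRI1"): ("constant", "spiking"),
    ("CC2", "PRI2"): ("constant", None),
    ("CC2", "PCI1"): ("constant", "spiking"),
    ("CC2", "PCI2"): ("constant", None),
    ("CC2", "yield"): ("constant", None),
    ("CC3", "PRI1"): ("doe", "quadratic"),
    ("CC3", "PRI2"): ("constant", None),
    ("CC3", "PCI1"): ("doe", "quadratic"),
    ("CC3", "PCI2"): ("constant", "spiking"),
    ("CC3", "yield"): ("doe", "quadratic"),
}

_BASE_SC = {
    "PRI1": {"CC1": 8.0, "CC2": 4.0, "CC3": 6.0},
    "PRI2": {"CC1": 5.0, "CC2": 3.0, "CC3": 4.0},
    "PCI1": {"CC1": 12.0, "CC2": 6.0, "CC3": 10.0},
    "PCI2": {"CC1": 15.0, "CC2": 5.0, "CC3": 8.0},
    "yield": {"CC1": 0.90, "CC2": 0.95, "CC3": 0.92},
}

_INIT_MEAN = {"PRI1": 2.0, "PRI2": 1.0, "PCI1": 50.0, "PCI2": 20.0}
_CQA_KIND = {
    "PRI1": "product_related",
    "PRI2": "product_related",
    "PCI1": "process_related",
    "PCI2": "process_related",
}


@dataclass
class SyntheticTruth:
    """Ground truth: process definition plus true models and noise levels."""

    process: ProcessDefinition
    config: TruthConfig
    seed: int
    doe_models: dict[tuple[str, str], TrueSurface] = field(default_factory=dict)
    constant_models: dict[tuple[str, str], TrueConstant] = field(default_factory=dict)
    spiking_models: dict[tuple[str, str], TrueSpiking] = field(default_factory=dict)
    designs: dict[str, np.ndarray] = field(default_factory=dict)

    def model_kind(self, uo: str, response: str) -> str:
        return "doe" if (uo, response) in self.doe_models else "constant"

    def to_json(self, path: str | Path | None = None) -> str:
        def surf(s: TrueSurface) -> dict:
            return {
                "terms": [t.to_dict() for t in s.terms],
                "beta0": s.beta0,
                "beta": list(s.beta),
                "residual_sd": s.residual_sd,
                "factor_center": s.factor_center,
                "factor_scale": s.factor_scale,
            }

        payload = {
            "seed": self.seed,
            "config": self.config.__dict__,
            "doe_models": {f"{u}:{r}": surf(s) for (u, r), s in self.doe_models.items()},
            "constant_models": {
                f"{u}:{r}": {"mean": c.mean, "sd": c.sd}
                for (u, r), c in self.constant_models.items()
            },
            "spiking_models": {
                f"{u}:{r}": {
                    "intercept": s.intercept,
                    "slope": s.slope,
                    "residual_sd": s.residual_sd,
                    "ild_ref": s.ild_ref,
                }
                for (u, r), s in self.spiking_models.items()
            },
            "usl": {c.name: c.usl for c in self.process.cqas},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _active_terms(uo: str, response: str, form: str) -> list[tuple[Term, float]]:
    """True active terms with sign conventions: higher pH lowers clearance,
    the second control raises it; quadratic forms add positive curvature."""
    pps = [p[0] for p in _PP_TABLE[uo]]
    second = pps[2] if len(pps) > 2 else pps[1]
    if response == "yield":
        return [(Term("main", (pps[1],)), 1.0)]
    acts = [(Term("main", (pps[0],)), -1.0), (Term("main", (second,)), 1.0)]
    if form == "quadratic":
        acts.append((Term("quadratic", (pps[0],)), 0.7))
    return acts


def generate_truth(config: TruthConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Build a reproducible synthetic truth for the three-column template.

    Base clearances are mildly jittered across seeds so repeated
    scenarios are genuinely different processes; signs and structure are
    fixed.  Upper specification limits are calibrated from a seeded
    large-n simulation of the true process so that the near-USL CQA has
    a true OOS probability of ``config.target_oos`` and the remaining
    CQAs sit far below their limits.
    """
    cfg = config or TruthConfig()
    rng = substream(seed, "truth")
    uo_names = list(_PP_TABLE)
    cqa_names = list(_INIT_MEAN)

    pp_specs = {
        uo: [
            {
                "name": name,
                "unit": unit,
                "setpoint": sp,
                "std": sp * rel / 100.0 * cfg.pp_std_scale,
                "nor_low": sp - (sp * rel / 100.0) / ratio,
                "nor_high": sp + (sp * rel / 100.0) / ratio,
            }
            for (name, sp, unit, rel, ratio) in _PP_TABLE[uo]
        ]
        for uo in uo_names
    }

    truth = SyntheticTruth(process=None, config=cfg, seed=seed)  # process set below
    half_nor = {
        uo: {d["name"]: 0.5 * (d["nor_high"] - d["nor_low"]) for d in pp_specs[uo]}
        for uo in uo_names
    }
    setpoints = {uo: {d["name"]: d["setpoint"] for d in pp_specs[uo]} for uo in uo_names}

    for (uo, resp), (kind, form) in _PATTERN.items():
        base = _BASE_SC[resp][uo]
        if resp != "yield":
            base *= float(rng.uniform(1 - cfg.base_jitter, 1 + cfg.base_jitter))
        resid = cfg.yield_resid_sd if resp == "yield" else cfg.doe_resid_cv * base
        if kind == "doe":
            acts = _active_terms(uo, resp, form)
            terms = [t for t, _ in acts]
            beta = [s * cfg.snr * resid for _, s in acts]
            centers = {f: setpoints[uo][f] for t in terms for f in t.factors}
            scales = {f: half_nor[uo][f] for t in terms for f in t.factors}
            truth.doe_models[(uo, resp)] = TrueSurface(
                terms=terms, beta0=base, beta=beta, residual_sd=resid,
                factor_center=centers, factor_scale=scales,
            )
        else:
            sd = (cfg.yield_resid_sd if resp == "yield" else cfg.ls_cv * base)
            truth.constant_models[(uo, resp)] = TrueConstant(mean=base, sd=sd)

    # anchor spiking lines at the typical routine loading density of the
    # deterministic mean trajectory
    c_mean = dict(_INIT_MEAN)
    p_mean = cfg.product_init_mean
    for uo in uo_names:
        for cqa in cqa_names:
            if _PATTERN[(uo, cqa)][1] == "spiking":
                base = (
                    truth.doe_models[(uo, cqa)].beta0
                    if (uo, cqa) in truth.doe_models
                    else truth.constant_models[(uo, cqa)].mean
                )
                ild_ref = c_mean[cqa] * p_mean / _COLUMN_VOLUME[uo]
                slope = cfg.spiking_sensitivity * base / ild_ref
                truth.spiking_models[(uo, cqa)] = TrueSpiking(
                    intercept=base * (1.0 - cfg.spiking_sensitivity),
                    slope=slope,
                    residual_sd=cfg.spiking_resid_cv * base,
                    ild_ref=ild_ref,
                )
        for cqa in cqa_names:
            kind = truth.model_kind(uo, cqa)
            sc = (
                truth.doe_models[(uo, cqa)].beta0
                if kind == "doe"
                else truth.constant_models[(uo, cqa)].mean
            )
            c_mean[cqa] /= sc
        sy = (
            truth.doe_models[(uo, "yield")].beta0
            if truth.model_kind(uo, "yield") == "doe"
            else truth.constant_models[(uo, "yield")].mean
        )
        p_mean *= sy

    for uo in uo_names:
        kind, runs = _DESIGNS[uo]
        k = len(_PP_TABLE[uo])
        truth.designs[uo] = (
            generate_dsd(k, n_runs=runs)
            if kind == "dsd"
            else generate_full_factorial(k, center_reps=runs - 2**k)
        )

    # provisional process without USLs, used for calibration
    provisional_usl = {c: 1e9 for c in cqa_names}
    truth.process = _build_process(cfg, pp_specs, provisional_usl)
    finals, sc_min = _propagate_truth(truth, cfg.calibration_n, substream(seed, "calibrate"))
    for resp, smin in sc_min.items():
        if smin <= 0:
            raise ConfigError(
                f"infeasible truth: clearance {resp} non-positive over the sampling region"
            )
    usl = {}
    for cqa in cqa_names:
        if cqa == cfg.near_usl_cqa:
            usl[cqa] = float(np.quantile(finals[cqa], 1.0 - cfg.target_oos))
        else:
            usl[cqa] = float(np.quantile(finals[cqa], 0.999) * 2.0)
    truth.process = _build_process(cfg, pp_specs, usl)
    return truth


def _build_process(
    cfg: TruthConfig, pp_specs: dict, usl: dict[str, float]
) -> ProcessDefinition:
    cqas = [
        CQASpec(
            name=c,
            kind=_CQA_KIND[c],
            usl=usl[c],
            init_mean=_INIT_MEAN[c],
            init_sd=max(cfg.init_cv * _INIT_MEAN[c], 1e-12),
        )
        for c in _INIT_MEAN
    ]
    uos = []
    for i, uo in enumerate(_PP_TABLE):
        assignments = {}
        for (u, resp), (kind, form) in _PATTERN.items():
            if u != uo:
                continue
            assignments[resp] = AssignmentSpec(
                model_kind=ModelKind.DOE if kind == "doe" else ModelKind.CONSTANT_LS,
                spiking=form == "spiking",
            )
        uos.append(
            UnitOperationSpec(
                name=uo,
                order_index=i + 1,
                column_volume=_COLUMN_VOLUME[uo],
                pps=pp_specs[uo],
                assignments=assignments,
            )
        )
    return ProcessDefinition(
        name="synthetic-three-column",
        product=ProductSpec(
            init_mean=cfg.product_init_mean,
            init_sd=cfg.product_init_cv * cfg.product_init_mean,
        ),
        cqas=cqas,
        unit_operations=uos,
    )


# ---------------------------------------------------------------------------
# Simulation from the truth (generative law)
# ---------------------------------------------------------------------------

def _propagate_truth(
    truth: SyntheticTruth,
    n: int,
    rng: np.random.Generator,
    collect: bool = False,
):
    """Simulate n batches from the true models.

    DoE-governed responses are deterministic functions of the drawn
    process parameters (residual variance is attributed to the assay);
    constant-model responses fluctuate with the true large-scale
    variance; spiking components scale deterministically with the
    loading density relative to the anchor.  Returns final
    concentrations per CQA and the minimum sampled clearance per
    response (for positivity checks); with ``collect=True`` also the
    per-stage records needed for a campaign dataset.
    """
    proc = truth.process
    cqa_names = proc.cqa_names
    c = {
        s.name: draw_positive(s.init_mean, s.init_sd, rng, size=n) for s in proc.cqas
    }
    p = draw_positive(proc.product.init_mean, proc.product.init_sd, rng, size=n)
    records: dict[str, np.ndarray] = {}
    if collect:
        for cqa in cqa_names:
            records[f"init.{cqa}"] = c[cqa].copy()
        records["init.product"] = p.copy()
    sc_min: dict[str, float] = {}
    for uo in proc.unit_operations:
        pp = {
            spec.name: spec.setpoint + spec.std * rng.standard_normal(n)
            for spec in uo.pps
        }
        if collect:
            for name, vals in pp.items():
                records[f"{uo.name}.pp.{name}"] = vals
        for cqa in cqa_names:
            key = (uo.name, cqa)
            if key in truth.doe_models:
                sc = truth.doe_models[key].evaluate(pp)
            else:
                m = truth.constant_models[key]
                sc = draw_positive(m.mean, m.sd, rng, size=n)
            spk = truth.spiking_models.get(key)
            if spk is not None:
                ild = c[cqa] * p / uo.column_volume
                sc = sc * spk.evaluate(ild) / spk.evaluate(spk.ild_ref)
            label = f"{uo.name}:{cqa}"
            sc_min[label] = float(np.min(sc))
            sc = np.maximum(sc, FLOOR)
            c[cqa] = c[cqa] / sc
            if collect:
                records[f"{uo.name}.{cqa}"] = c[cqa].copy()
        ykey = (uo.name, "yield")
        if ykey in truth.doe_models:
            sy = truth.doe_models[ykey].evaluate(pp)
        else:
            m = truth.constant_models[ykey]
            sy = draw_positive(m.mean, m.sd, rng, size=n)
        sy = np.clip(sy, FLOOR, 1.0)
        sc_min[f"{uo.name}:yield"] = float(np.min(sy))
        p = p * sy
        if collect:
            records[f"{uo.name}.yield"] = sy.copy()
    finals = {cqa: c[cqa] for cqa in cqa_names}
    if collect:
        return finals, sc_min, records
    return finals, sc_min


def simulate_doe_responses(
    truth: SyntheticTruth,
    design: np.ndarray,
    uo: str,
    rng: np.random.Generator,
) -> DoEDataset:
    """DoE dataset for one unit operation: true surface plus assay noise.

    The coded design maps to natural units via set-point +/- half-NOR
    (characterization ranges spanning the normal operating range).
    """
    spec = truth.process.uo(uo)
    design = np.asarray(design, dtype=float)
    if design.shape[1] != len(spec.pps):
        raise ConfigError(
            f"design has {design.shape[1]} columns, {uo} has {len(spec.pps)} PPs"
        )
    n = design.shape[0]
    pp = {
        s.name: s.setpoint + design[:, j] * s.half_nor
        for j, s in enumerate(spec.pps)
    }
    data = dict(pp)
    for resp in truth.process.cqa_names + ["yield"]:
        key = (uo, resp)
        if key in truth.doe_models:
            m = truth.doe_models[key]
            y = m.evaluate(pp) + m.residual_sd * rng.standard_normal(n)
        else:
            m = truth.constant_models[key]
            y = draw_positive(m.mean, m.sd, rng, size=n)
        y = np.maximum(y, FLOOR)
        if resp == "yield":
            data["yield"] = np.minimum(y, 1.1)
        else:
            data[f"sc.{resp}"] = y
    return DoEDataset(
        runs=pd.DataFrame(data),
        pp_names=[s.name for s in spec.pps],
        response_names=truth.process.cqa_names + ["yield"],
    )


def simulate_spiking_dataset(
    truth: SyntheticTruth,
    uo: str,
    cqa: str,
    rng: np.random.Generator,
    n_points: int | None = None,
) -> pd.DataFrame:
    """(ILD, SC) pairs around the routine loading density.

    Spiked development points span a wide loading range; large-scale
    points cluster near the routine loading, the way both populations
    sit on one regression in practice.  Columns: ild, sc, source.
    """
    spk = truth.spiking_models.get((uo, cqa))
    if spk is None:
        raise ConfigError(f"truth has no spiking model for {uo}:{cqa}")
    n = n_points or truth.config.n_spiking_points
    n_doe = max(n - 4, 2)
    n_ls = n - n_doe
    ild_doe = spk.ild_ref * np.linspace(0.5, 1.8, n_doe)
    ild_ls = spk.ild_ref * (1.0 + 0.15 * rng.standard_normal(n_ls))
    ild = np.concatenate([ild_doe, np.abs(ild_ls)])
    sc = spk.evaluate(ild) + spk.residual_sd * rng.standard_normal(len(ild))
    return pd.DataFrame(
        {
            "ild": ild,
            "sc": np.maximum(sc, FLOOR),
            "source": ["doe"] * n_doe + ["ls"] * n_ls,
        }
    )


def simulate_ls_campaign(
    truth: SyntheticTruth, n_runs: int = 9, rng: np.random.Generator | None = None
) -> LSDataset:
    """A large-scale manufacturing campaign drawn from the true process."""
    rng = rng if rng is not None else np.random.default_rng(0)
    _, _, records = _propagate_truth(truth, n_runs, rng, collect=True)
    df = pd.DataFrame(records)
    df.index.name = "run_id"
    return LSDataset(runs=df)


def truth_model_set(truth: SyntheticTruth) -> "ModelSet":
    """Exact model set mirroring the truth with zero model uncertainty.

    Running the Monte Carlo engine with this set reproduces the truth's
    generative law (deterministic response surfaces, constant models at
    their true mean and SD, deterministic spiking multipliers), so it
    serves as an oracle separating engine behavior from fitting error.
    """
    from .models import ModelAssignment, ModelSet

    def exact_ols(terms, beta0, beta, centers, scales) -> "ClearanceOLS":
        from .regression import ClearanceOLS

        est = ClearanceOLS(tuple(terms))
        p = len(terms)
        est.intercept_ = float(beta0)
        est.coef_ = np.asarray(beta, dtype=float)
        est.pvalues_ = np.zeros(p)
        est.residual_se_ = 0.0
        est.r2_ = 1.0
        est.n_ = 1
        est.p_ = p
        est.factor_center_ = dict(centers)
        est.factor_scale_ = dict(scales)
        est.col_center_ = np.zeros(p)
        est.xtx_inv_ = np.zeros((p, p))
        return est

    from .regression import ConstantClearance
    from .spiking import SpikingRegression

    ms = ModelSet()
    proc = truth.process
    for uo in proc.unit_operations:
        for resp in proc.cqa_names + ["yield"]:
            key = (uo.name, resp)
            spk_model = None
            spk = truth.spiking_models.get(key)
            if spk is not None:
                s = SpikingRegression()
                s._ols_ = exact_ols(
                    [Term("main", ("ild",))], spk.intercept, [spk.slope],
                    {"ild": 0.0}, {"ild": 1.0},
                )
                s.q2_ = s.r2_ = 1.0
                s.pvalue_ = 0.0
                s.slope_, s.intercept_ = spk.slope, spk.intercept
                s.mean_ild_ = spk.ild_ref
                s.sc_at_mean_ild_ = float(spk.evaluate(spk.ild_ref))
                s.n_ = 4
                spk_model = s
            if key in truth.doe_models:
                surf = truth.doe_models[key]
                fit = exact_ols(
                    surf.terms, surf.beta0, surf.beta,
                    surf.factor_center, surf.factor_scale,
                )
                ms.set(uo.name, ModelAssignment(
                    response=resp, model_kind=ModelKind.DOE,
                    doe_fit=fit, spiking=spk_model,
                ))
            else:
                c = truth.constant_models[key]
                const = ConstantClearance()
                const.mean_, const.sd_, const.n_ = c.mean, c.sd, 9
                ms.set(uo.name, ModelAssignment(
                    response=resp, model_kind=ModelKind.CONSTANT_LS,
                    constant_model=const, spiking=spk_model,
                ))
    return ms


def brute_force_oos(
    truth: SyntheticTruth, n: int = 1_000_000, seed: int = 0
) -> pd.Series:
    """Per-CQA OOS probability by direct large-n simulation of the truth."""
    finals, _ = _propagate_truth(truth, n, substream(seed, "bruteforce"))
    return pd.Series(
        {
            c.name: float(np.mean(finals[c.name] > c.usl))
            for c in truth.process.cqas
        },
        name="oos",
    )
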