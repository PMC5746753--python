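"""Comparison of simulated against observed CQA distributions.

Per unit operation and CQA the simulated pool distribution is overlaid
with the observed large-scale pool values, both normalized by the
maximum over their union (so the largest value maps to exactly 1.0 and
relative shapes are preserved).  Visual-inspection overlays need a
numeric surrogate for testing, so the two-sample Kolmogorov–Smirnov
statistic is attached as the overlap metric.  The observed-data OOS
probability is computed the way a practitioner treats a 9-run campaign:
a normal distribution is fitted by mean and sample SD and the upper
tail beyond the specification limit is read off.

Observed values below the limit of quantification (missing cells) are
excluded, not imputed; their count is reported, and a panel whose
observed side is entirely below LoQ is emitted empty and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CQASpec, LSDataset
from .engine import SimulationResult
from .errors import DatasetError

__all__ = ["observed_oos_normal_fit", "PanelReport", "OverlayReport", "overlay_report"]


def observed_oos_normal_fit(values, usl: float) -> float:
    """OOS probability of observed data via a fitted normal distribution.

    Degenerate spread (all values equal) collapses to 0 or 1 by the sign
    of ``usl - mean``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise DatasetError("need at least 2 observed values for a normal fit")
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        return 0.0 if mu <= usl else 1.0
    return float(stats.norm.sf((usl - mu) / sd))


@dataclass
class PanelReport:
    """One unit-operation x CQA overlay panel."""

    uo: str
    cqa: str
    norm_divisor: float
    hist: pd.DataFrame           # bin_low, bin_high, sim_frac, obs_frac (normalized units)
    simulated_norm: np.ndarray
    observed_norm: np.ndarray
    ks_stat: float
    ks_pvalue: float
    oos_sim: float
    oos_observed: float
    n_observed: int
    n_loq_excluded: int
    observed_empty: bool

    def summary(self) -> dict:
        return {
            "uo": self.uo,
            "cqa": self.cqa,
            "ks_stat": self.ks_stat,
            "ks_pvalue": self.ks_pvalue,
            "oos_sim": self.oos_sim,
            "oos_observed": self.oos_observed,
            "n_observed": self.n_observed,
            "n_loq_excluded": self.n_loq_excluded,
            "observed_empty": self.observed_empty,
        }


@dataclass
class OverlayReport:
    panels: dict[tuple[str, str], PanelReport]

    def panel(self, uo: str, cqa: str) -> PanelReport:
        return self.panels[(uo, cqa)]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.summary() for p in self.panels.values()])


def overlay_report(
    result: SimulationResult,
    ls: LSDataset,
    cqa_specs: Sequence[CQASpec],
    bins: int = 20,
) -> OverlayReport:
    """Build max-normalized overlay panels for every unit operation and CQA."""
    panels: dict[tuple[str, str], PanelReport] = {}
    specs = {s.name: s for s in cqa_specs}
    for uo in result.uo_names:
        for cqa in result.cqa_names:
            sim = result.pool_concentration(uo, cqa)
            try:
                obs_raw = ls.pool_conc(uo, cqa)
            except DatasetError:
                obs_raw = np.full(ls.n_runs, np.nan)
            obs = obs_raw[np.isfinite(obs_raw)]
            n_loq = int(len(obs_raw) - len(obs))
            divisor = float(np.max(np.concatenate([sim, obs])) if len(obs) else sim.max())
            sim_n = sim / divisor
            obs_n = obs / divisor
            edges = np.linspace(0.0, 1.0, bins + 1)
            sim_frac, _ = np.histogram(sim_n, bins=edges)
            obs_frac, _ = np.histogram(obs_n, bins=edges)
            hist = pd.DataFrame(
                {
                    "bin_low": edges[:-1],
                    "bin_high": edges[1:],
                    "sim_frac": sim_frac / len(sim_n),
                    "obs_frac": obs_frac / len(obs_n) if len(obs_n) else 0.0,
                }
            )
            if len(obs) >= 1:
                ks = stats.ks_2samp(sim, obs)
                ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
            else:
                ks_stat, ks_p = float("nan"), float("nan")
            usl = specs[cqa].usl
            oos_sim = float(np.mean(sim > usl))
            oos_obs = observed_oos_normal_fit(obs, usl) if len(obs) >= 2 else float("nan")
            panels[(uo, cqa)] = PanelReport(
                uo=uo,
                cqa=cqa,
                norm_divisor=divisor,
                hist=hist,
                simulated_norm=sim_n,
                observed_norm=obs_n,
                ks_stat=ks_stat,
                ks_pvalue=ks_p,
                oos_sim=oos_sim,
                oos_observed=oos_obs,
                n_observed=int(len(obs)),
                n_loq_excluded=n_loq,
                observed_empty=len(obs) == 0,
            )
    return OverlayReport(panels=panels)
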