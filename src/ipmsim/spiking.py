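"""Spiking models: clearance as a function of impurity loading density.

Spiking studies load a chromatography column with deliberately elevated
impurity amounts and show that the specific clearance rises with the
impurity loading density (ILD = loaded impurity amount per column
volume).  A spiking model is a strictly one-factor *linear* regression
of SC on ILD.  It is accepted only if it passes the significance screen
(slope p-value < 0.05 and R^2 - Q^2 < 0.3, with Q^2 the leave-one-out
cross-validated explained variance), and it enters the Monte Carlo
engine multiplicatively: the PP-driven clearance draw is scaled by the
ILD-driven draw relative to the clearance at the mean DoE loading
density,

    SC = SC(PP) * SC(ILD) / SC(mean ILD),

so that at mean loading the spiking component is exactly neutral.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._sampling import FLOOR, FloorCounters, draw_positive
from .errors import ConfigError, DatasetError, NumericalError
from .regression import ClearanceOLS
from .terms import Term

__all__ = [
    "compute_ild",
    "SpikingRegression",
    "fit_spiking",
    "passes_spiking_screen",
    "sample_clearance_spiking",
    "combine_clearances",
]

_ILD = "ild"


def compute_ild(c_load, p_load, cv: float):
    """Impurity loading density: specific load conc. x product amount / CV."""
    c_load = np.asarray(c_load, dtype=float)
    p_load = np.asarray(p_load, dtype=float)
    if cv <= 0:
        raise ConfigError(f"column volume must be positive, got {cv}")
    if np.any(c_load <= 0):
        raise ConfigError("impurity load concentration must be positive for an ILD")
    if np.any(p_load <= 0):
        raise ConfigError("product load amount must be positive for an ILD")
    out = c_load * p_load / cv
    return float(out) if out.ndim == 0 else out


class SpikingRegression(BaseEstimator):
    """One-factor linear regression of specific clearance on ILD.

    Fitted attributes include the leave-one-out ``q2_`` (1 - PRESS/TSS),
    the mean DoE loading density ``mean_ild_`` and the predicted
    clearance there, ``sc_at_mean_ild_`` — the normalization constant of
    the multiplicative combination.
    """

    def __init__(self, floor: float = FLOOR):
        self.floor = floor

    def fit(self, ild, sc):
        ild = np.asarray(ild, dtype=float).ravel()
        sc = np.asarray(sc, dtype=float).ravel()
        if len(ild) != len(sc):
            raise DatasetError("ild and sc must have equal length")
        if len(ild) < 4:
            raise DatasetError("need at least 4 (ILD, SC) pairs for a spiking fit")
        if np.ptp(ild) == 0:
            raise DatasetError("degenerate ILD spread: all loading densities equal")
        self._ols_ = ClearanceOLS((Term("main", (_ILD,)),), floor=self.floor).fit(
            {_ILD: ild}, sc
        )
        n = len(ild)
        # leave-one-out Q2 via the hat-matrix shortcut on the full design
        xc = ild - ild.mean()
        h = 1.0 / n + xc**2 / (xc**2).sum()
        resid = sc - self._ols_.predict({_ILD: ild})
        press = float(np.sum((resid / (1.0 - h)) ** 2))
        tss = float(np.sum((sc - sc.mean()) ** 2))
        self.q2_ = 1.0 - press / tss if tss > 0 else 0.0
        self.r2_ = self._ols_.r2_
        self.pvalue_ = float(self._ols_.pvalues_[0])
        nat = self._ols_.natural_coefficients()
        self.slope_ = float(nat[_ILD])
        self.intercept_ = float(nat["(intercept)"])
        self.mean_ild_ = float(ild.mean())
        self.sc_at_mean_ild_ = float(self._ols_.predict({_ILD: self.mean_ild_})[0])
        if self.sc_at_mean_ild_ <= 0:
            raise NumericalError("predicted clearance at mean ILD must be positive")
        self.n_ = n
        return self

    def predict(self, ild) -> np.ndarray:
        return self._ols_.predict({_ILD: np.asarray(ild, dtype=float)})

    def predict_sd(self, ild) -> np.ndarray:
        """SD of the mean prediction, same 1/n + leverage form as the DoE models."""
        return self._ols_.predict_sd({_ILD: np.asarray(ild, dtype=float)})

    def sample(
        self, ild, rng: np.random.Generator, counters: FloorCounters | None = None
    ) -> np.ndarray:
        ild = np.asarray(ild, dtype=float)
        if np.any(ild <= 0):
            raise ConfigError("ILD must be positive")
        return draw_positive(
            self.predict(ild), self.predict_sd(ild), rng,
            floor=self.floor, counters=counters,
        )

    def passes_screen(self, alpha: float = 0.05, max_r2_q2_gap: float = 0.3) -> bool:
        return (self.pvalue_ < alpha) and ((self.r2_ - self.q2_) < max_r2_q2_gap)

    def to_dict(self) -> dict:
        return {
            "type": "spiking",
            "ols": self._ols_.to_dict(),
            "q2": self.q2_,
            "r2": self.r2_,
            "pvalue": self.pvalue_,
            "slope": self.slope_,
            "intercept": self.intercept_,
            "mean_ild": self.mean_ild_,
            "sc_at_mean_ild": self.sc_at_mean_ild_,
            "n": self.n_,
            "floor": self.floor,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpikingRegression":
        est = cls(floor=d.get("floor", FLOOR))
        est._ols_ = ClearanceOLS.from_dict(d["ols"])
        est.q2_ = float(d["q2"])
        est.r2_ = float(d["r2"])
        est.pvalue_ = float(d["pvalue"])
        est.slope_ = float(d["slope"])
        est.intercept_ = float(d["intercept"])
        est.mean_ild_ = float(d["mean_ild"])
        est.sc_at_mean_ild_ = float(d["sc_at_mean_ild"])
        est.n_ = int(d["n"])
        return est


def fit_spiking(pairs, include_ls: bool = True) -> SpikingRegression:
    """Fit a spiking model from (ILD, SC) pairs.

    ``pairs`` may be a sequence of 2-tuples or a DataFrame with columns
    ``ild``, ``sc`` and optionally ``source`` in {"doe", "ls"}.  By
    default DoE and large-scale points are pooled (both populations sit
    on one regression); ``include_ls=False`` restricts to DoE points.
    The *mean ILD* anchoring the multiplicative combination is taken
    from the DoE points when a source column distinguishes them.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs
        if "source" in df.columns and not include_ls:
            df = df[df["source"] == "doe"]
        ild = df["ild"].to_numpy(dtype=float)
        sc = df["sc"].to_numpy(dtype=float)
        est = SpikingRegression().fit(ild, sc)
        if "source" in pairs.columns:
            doe_ild = pairs.loc[pairs["source"] == "doe", "ild"].to_numpy(dtype=float)
            if len(doe_ild):
                est.mean_ild_ = float(doe_ild.mean())
                est.sc_at_mean_ild_ = float(est.predict(est.mean_ild_)[0])
        return est
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DatasetError("pairs must be (ILD, SC) tuples")
    return SpikingRegression().fit(arr[:, 0], arr[:, 1])


def passes_spiking_screen(
    model: SpikingRegression, alpha: float = 0.05, max_r2_q2_gap: float = 0.3
) -> bool:
    return model.passes_screen(alpha=alpha, max_r2_q2_gap=max_r2_q2_gap)


def sample_clearance_spiking(
    model: SpikingRegression, ild: float, rng: np.random.Generator,
    counters: FloorCounters | None = None,
) -> float:
    return float(model.sample(np.atleast_1d(ild), rng, counters=counters)[0])


def combine_clearances(sc_pp, sc_ild_sample, sc_at_mean_ild: float):
    """Multiplicative combination of PP- and ILD-driven clearances.

    Returns ``sc_pp * sc_ild_sample / sc_at_mean_ild``: the expected
    clearance change due to off-mean impurity loading scales the
    PP-driven draw, and is exactly neutral at the mean loading density.
    """
    if sc_at_mean_ild <= 0:
        raise NumericalError("clearance at mean ILD must be positive")
    out = np.asarray(sc_pp, dtype=float) * np.asarray(sc_ild_sample, dtype=float) / sc_at_mean_ild
    return float(out) if out.ndim == 0 else out
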