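"""Clearance and yield models as functions of process parameters.

The specific clearance of an impurity across a chromatography step (or
the step yield of product) is modeled as a linear model in the process
parameters,

    SC = beta0 + sum_k beta_k t_k(PP) + eps,

with terms ``t_k`` drawn from main effects, two-factor interactions and
pure quadratics.  Three estimators implement the modeling choices:

``ClearanceOLS``
    Ordinary least squares on a *coded* model matrix: each factor is
    mean-centered and scaled to the half-range of the design, and each
    term column is additionally centered to its design mean.  With the
    model matrix orthogonal to the intercept, the standard deviation of
    the mean response at a new point decomposes exactly into

        sd(x) = s * sqrt(1/n + h(x)),   h(x) = x (X'X)^-1 x',

    the form used when sampling the clearance in the Monte Carlo engine.
    Note this is the uncertainty of the *mean* response (a confidence,
    not a prediction, band): residual variance is attributed to the
    assay, not to batch-to-batch process variation, and is deliberately
    not added for new observations.

``StepwiseOLS``
    Bidirectional stepwise selection: candidates whose partial p-value
    (coefficient t-test in the current multivariate model) is below
    ``p_enter`` may enter, smallest first; after each entry any included
    term whose partial p-value exceeds ``p_remove`` is removed, worst
    first, one at a time; iteration stops when the model structure no
    longer changes.  Deterministic given data, candidate order and
    thresholds.

``ConstantClearance``
    When no process parameter significantly affects a clearance, the
    clearance is constant over the design space and sampled from the
    mean and (n-1)-denominator standard deviation of the large-scale
    runs.

All estimators follow scikit-learn conventions (``fit`` /
``get_params`` / fitted attributes with trailing underscores) and
compose with sklearn tooling.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from ._sampling import FLOOR, FloorCounters, draw_positive
from .config import DoEDataset
from .errors import ConfigError, NumericalError, SingularDesignError
from .terms import Term, build_candidate_terms

__all__ = [
    "ClearanceOLS",
    "StepwiseOLS",
    "ConstantClearance",
    "fit_ols",
    "fit_stepwise",
    "fit_constant_model",
    "predict_mean",
    "prediction_sd",
    "sample_clearance_doe",
    "sample_clearance_constant",
]


def _as_columns(X) -> dict[str, np.ndarray]:
    """Normalize factor data to name -> 1-D float array."""
    if isinstance(X, pd.DataFrame):
        return {c: X[c].to_numpy(dtype=float) for c in X.columns}
    if isinstance(X, Mapping):
        return {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in X.items()}
    raise ConfigError("X must be a DataFrame or a mapping of factor name -> values")


class ClearanceOLS(RegressorMixin, BaseEstimator):
    """OLS response-surface model with leverage-based mean-prediction SD."""

    def __init__(self, terms: Sequence[Term] = (), floor: float = FLOOR):
        self.terms = tuple(terms)
        self.floor = floor

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        cols = _as_columns(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        p = len(self.terms)
        if n <= p + 1:
            raise ConfigError(f"need n > p + 1 runs (n={n}, p={p})")
        factors = sorted({f for t in self.terms for f in t.factors})
        for f in factors:
            if f not in cols:
                raise ConfigError(f"missing factor column {f!r}")
        self.factor_center_ = {}
        self.factor_scale_ = {}
        coded = {}
        for f in factors:
            x = np.asarray(cols[f], dtype=float)
            if len(x) != n:
                raise ConfigError(f"factor {f!r} has {len(x)} rows, expected {n}")
            c = float(x.mean())
            s = float(0.5 * (x.max() - x.min())) or 1.0
            self.factor_center_[f] = c
            self.factor_scale_[f] = s
            coded[f] = (x - c) / s
        if p:
            M = np.column_stack([t.evaluate(coded) for t in self.terms])
            self.col_center_ = M.mean(axis=0)
            Mc = M - self.col_center_
            self._check_rank(Mc)
            design = sm.add_constant(Mc, has_constant="add")
        else:
            self.col_center_ = np.zeros(0)
            Mc = np.empty((n, 0))
            design = np.ones((n, 1))
        res = sm.OLS(y, design).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.pvalues_ = np.asarray(res.pvalues[1:], dtype=float)
        self.residual_se_ = float(np.sqrt(res.mse_resid))
        self.r2_ = float(res.rsquared) if p else 0.0
        self.xtx_inv_ = (
            np.linalg.inv(Mc.T @ Mc) if p else np.zeros((0, 0))
        )
        self.n_ = n
        self.p_ = p
        self._result_ = res
        return self

    def _check_rank(self, Mc: np.ndarray) -> None:
        n, p = Mc.shape
        full = np.column_stack([np.ones(n), Mc])
        if np.linalg.matrix_rank(full) == p + 1:
            return
        aliased = []
        rank = 1
        cur = np.ones((n, 1))
        for j, t in enumerate(self.terms):
            trial = np.column_stack([cur, Mc[:, j]])
            r = np.linalg.matrix_rank(trial)
            if r > rank:
                cur, rank = trial, r
            else:
                aliased.append(t.label)
        raise SingularDesignError(aliased)

    # -- prediction ------------------------------------------------------

    def _rows(self, X) -> np.ndarray:
        """Centered coded model-matrix rows for new points."""
        cols = _as_columns(X)
        coded = {}
        for f in self.factor_center_:
            if f not in cols:
                raise ConfigError(f"missing factor value for {f!r}")
            coded[f] = (
                np.asarray(cols[f], dtype=float) - self.factor_center_[f]
            ) / self.factor_scale_[f]
        if not self.terms:
            some = next(iter(cols.values()), np.zeros(1))
            return np.empty((len(np.atleast_1d(some)), 0))
        M = np.column_stack([t.evaluate(coded) for t in self.terms])
        return M - self.col_center_

    def predict(self, X) -> np.ndarray:
        rows = self._rows(X)
        return rows @ self.coef_ + self.intercept_

    def predict_sd(self, X) -> np.ndarray:
        """SD of the mean response: s * sqrt(1/n + leverage)."""
        rows = self._rows(X)
        if self.p_:
            h = np.einsum("ij,jk,ik->i", rows, self.xtx_inv_, rows)
        else:
            h = np.zeros(rows.shape[0])
        return self.residual_se_ * np.sqrt(1.0 / self.n_ + h)

    def sample(
        self,
        X,
        rng: np.random.Generator,
        cap: float | None = None,
        counters: FloorCounters | None = None,
    ) -> np.ndarray:
        """One clearance draw per row: Normal(mean, mean-prediction SD)."""
        return draw_positive(
            self.predict(X), self.predict_sd(X), rng,
            floor=self.floor, cap=cap, counters=counters,
        )

    # -- reporting / serialization --------------------------------------

    def natural_coefficients(self) -> dict[str, float]:
        """Coefficients re-expanded in natural (uncoded) factor units."""
        out: dict[str, float] = {"(intercept)": self.intercept_ - float(self.coef_ @ self.col_center_) if self.p_ else self.intercept_}
        c = self.factor_center_
        s = self.factor_scale_
        for beta, t in zip(self.coef_, self.terms):
            if t.kind == "main":
                (f,) = t.factors
                out[f] = out.get(f, 0.0) + beta / s[f]
                out["(intercept)"] -= beta * c[f] / s[f]
            elif t.kind == "interaction":
                a, b = t.factors
                d = s[a] * s[b]
                out[t.label] = out.get(t.label, 0.0) + beta / d
                out[a] = out.get(a, 0.0) - beta * c[b] / d
                out[b] = out.get(b, 0.0) - beta * c[a] / d
                out["(intercept)"] += beta * c[a] * c[b] / d
            else:
                (f,) = t.factors
                d = s[f] ** 2
                out[t.label] = out.get(t.label, 0.0) + beta / d
                out[f] = out.get(f, 0.0) - 2 * beta * c[f] / d
                out["(intercept)"] += beta * c[f] ** 2 / d
        return out

    def to_dict(self) -> dict:
        return {
            "type": "doe",
            "terms": [t.to_dict() for t in self.terms],
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "pvalues": self.pvalues_.tolist(),
            "residual_se": self.residual_se_,
            "r2": self.r2_,
            "n": self.n_,
            "p": self.p_,
            "factor_center": self.factor_center_,
            "factor_scale": self.factor_scale_,
            "col_center": self.col_center_.tolist(),
            "xtx_inv": self.xtx_inv_.tolist(),
            "floor": self.floor,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClearanceOLS":
        est = cls(terms=tuple(Term.from_dict(t) for t in d["terms"]), floor=d.get("floor", FLOOR))
        est.intercept_ = float(d["intercept"])
        est.coef_ = np.asarray(d["coef"], dtype=float)
        est.pvalues_ = np.asarray(d["pvalues"], dtype=float)
        est.residual_se_ = float(d["residual_se"])
        est.r2_ = float(d["r2"])
        est.n_ = int(d["n"])
        est.p_ = int(d["p"])
        est.factor_center_ = {k: float(v) for k, v in d["factor_center"].items()}
        est.factor_scale_ = {k: float(v) for k, v in d["factor_scale"].items()}
        est.col_center_ = np.asarray(d["col_center"], dtype=float)
        est.xtx_inv_ = np.asarray(d["xtx_inv"], dtype=float).reshape(est.p_, est.p_)
        return est


class StepwiseOLS(BaseEstimator):
    """Bidirectional stepwise term selection around :class:`ClearanceOLS`."""

    def __init__(
        self,
        candidates: Sequence[Term],
        p_enter: float = 0.05,
        p_remove: float = 0.10,
        floor: float = FLOOR,
    ):
        self.candidates = tuple(candidates)
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.floor = floor

    def _fit_subset(self, X, y, idx: list[int]) -> ClearanceOLS:
        terms = tuple(self.candidates[i] for i in sorted(idx))
        return ClearanceOLS(terms, floor=self.floor).fit(X, y)

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        included: list[int] = []
        seen: set[frozenset] = set()
        self.oscillation_ = False
        history: list[frozenset] = []
        while True:
            changed = False
            # forward: smallest partial p below p_enter, ties by candidate order
            best_p, best_j = None, None
            for j in range(len(self.candidates)):
                if j in included:
                    continue
                trial = included + [j]
                if n - (len(trial) + 1) < 1:
                    continue  # no residual degrees of freedom left
                try:
                    fit = self._fit_subset(X, y, trial)
                except SingularDesignError:
                    continue
                pos = sorted(trial).index(j)
                pj = fit.pvalues_[pos]
                if pj < self.p_enter and (best_p is None or pj < best_p):
                    best_p, best_j = pj, j
            if best_j is not None:
                included.append(best_j)
                changed = True
            # backward: worst offender first, one at a time
            while included:
                fit = self._fit_subset(X, y, included)
                order = sorted(included)
                worst_pos = int(np.argmax(fit.pvalues_))
                if fit.pvalues_[worst_pos] > self.p_remove:
                    included.remove(order[worst_pos])
                    changed = True
                else:
                    break
            state = frozenset(included)
            if state in seen:
                self.oscillation_ = True
                break
            seen.add(state)
            history.append(state)
            if not changed:
                break
        self.model_ = self._fit_subset(X, y, included)
        self.selected_terms_ = self.model_.terms
        self.history_ = history
        return self

    # delegate the prediction surface to the selected model
    def predict(self, X):
        return self.model_.predict(X)

    def predict_sd(self, X):
        return self.model_.predict_sd(X)

    def sample(self, X, rng, cap=None, counters=None):
        return self.model_.sample(X, rng, cap=cap, counters=counters)


class ConstantClearance(BaseEstimator):
    """Constant clearance from large-scale runs: Normal(mean, sd^2)."""

    def __init__(self, floor: float = FLOOR):
        self.floor = floor

    def fit(self, values):
        values = np.asarray(values, dtype=float).ravel()
        values = values[np.isfinite(values)]
        if len(values) < 2:
            raise ConfigError("need at least 2 large-scale values for a constant model")
        self.mean_ = float(values.mean())
        self.sd_ = float(values.std(ddof=1))
        self.n_ = len(values)
        if self.mean_ <= 0:
            raise NumericalError("constant clearance mean must be positive")
        return self

    def sample(
        self,
        rng: np.random.Generator,
        size: int | None = None,
        cap: float | None = None,
        counters: FloorCounters | None = None,
    ) -> np.ndarray:
        return draw_positive(
            self.mean_, self.sd_, rng, size=size,
            floor=self.floor, cap=cap, counters=counters,
        )

    def to_dict(self) -> dict:
        return {"type": "constant", "mean": self.mean_, "sd": self.sd_, "n": self.n_,
                "floor": self.floor}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConstantClearance":
        est = cls(floor=d.get("floor", FLOOR))
        est.mean_ = float(d["mean"])
        est.sd_ = float(d["sd"])
        est.n_ = int(d.get("n", 2))
        return est


# ---------------------------------------------------------------------------
# Functional wrappers over the estimators
# ---------------------------------------------------------------------------

def fit_ols(dataset: DoEDataset, response: str, terms: Sequence[Term]) -> ClearanceOLS:
    return ClearanceOLS(tuple(terms)).fit(dataset.pp_values(), dataset.response(response))


def fit_stepwise(
    dataset: DoEDataset,
    response: str,
    candidates: Sequence[Term] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseOLS:
    if candidates is None:
        candidates = build_candidate_terms(dataset.pp_names)
    est = StepwiseOLS(tuple(candidates), p_enter=p_enter, p_remove=p_remove)
    return est.fit(dataset.pp_values(), dataset.response(response))


def fit_constant_model(ls_values) -> ConstantClearance:
    return ConstantClearance().fit(ls_values)


def _fit_of(fit) -> ClearanceOLS:
    return fit.model_ if isinstance(fit, StepwiseOLS) else fit


def predict_mean(fit, pp_vector: Mapping[str, float]) -> float:
    return float(_fit_of(fit).predict(pp_vector)[0])


def prediction_sd(fit, pp_vector: Mapping[str, float]) -> float:
    return float(_fit_of(fit).predict_sd(pp_vector)[0])


def sample_clearance_doe(
    fit, pp_vector: Mapping[str, float], rng: np.random.Generator,
    counters: FloorCounters | None = None,
) -> float:
    return float(_fit_of(fit).sample(pp_vector, rng, counters=counters)[0])


def sample_clearance_constant(
    model: ConstantClearance, rng: np.random.Generator,
    counters: FloorCounters | None = None,
) -> float:
    return float(model.sample(rng, size=1, counters=counters)[0])
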