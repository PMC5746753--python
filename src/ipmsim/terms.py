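"""Model terms for clearance / yield response surfaces.

A term is an intercept-free building block of a polynomial response
surface in the process parameters: a main effect, a two-factor
interaction, or a pure quadratic.  Terms are evaluated on *coded* factor
values (centered, scaled to the half-range of the design), the coding
itself being owned by the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError

__all__ = ["Term", "build_candidate_terms"]

_KINDS = ("main", "interaction", "quadratic")


@dataclass(frozen=True)
class Term:
    """One non-intercept term of a linear model.

    Parameters
    ----------
    kind:
        ``"main"``, ``"interaction"`` or ``"quadratic"``.
    factors:
        One factor name (main, quadratic) or two distinct names
        (interaction).
    """

    kind: str
    factors: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown term kind {self.kind!r}")
        object.__setattr__(self, "factors", tuple(self.factors))
        n = len(self.factors)
        if self.kind == "interaction":
            if n != 2 or self.factors[0] == self.factors[1]:
                raise ConfigError(
                    f"interaction term needs 2 distinct factors, got {self.factors}"
                )
        elif n != 1:
            raise ConfigError(f"{self.kind} term needs exactly 1 factor, got {self.factors}")

    @property
    def label(self) -> str:
        if self.kind == "main":
            return self.factors[0]
        if self.kind == "interaction":
            return f"{self.factors[0]}*{self.factors[1]}"
        return f"{self.factors[0]}^2"

    def evaluate(self, coded: Mapping[str, np.ndarray]) -> np.ndarray:
        """Column of this term given coded factor values."""
        if self.kind == "main":
            return np.asarray(coded[self.factors[0]], dtype=float)
        if self.kind == "interaction":
            a, b = self.factors
            return np.asarray(coded[a], dtype=float) * np.asarray(coded[b], dtype=float)
        x = np.asarray(coded[self.factors[0]], dtype=float)
        return x * x

    def to_dict(self) -> dict:
        return {"kind": self.kind, "factors": list(self.factors)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Term":
        return cls(kind=d["kind"], factors=tuple(d["factors"]))


def build_candidate_terms(
    pp_names: Sequence[str],
    include_interactions: bool = True,
    include_quadratics: bool = True,
) -> list[Term]:
    """Enumerate the candidate term set for stepwise selection.

    Ordering is deterministic: main effects in input order, then
    two-factor interactions in lexicographic order, then quadratics in
    input order.  This ordering is the tie-break used by stepwise
    selection, so it is part of the reproducibility contract.
    """
    names = list(pp_names)
    if not names:
        raise ConfigError("need at least one process parameter name")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate process parameter names: {dupes}")
    terms = [Term("main", (n,)) for n in names]
    if include_interactions and len(names) > 1:
        pairs = sorted(
            {tuple(sorted((a, b))) for i, a in enumerate(names) for b in names[i + 1 :]}
        )
        terms += [Term("interaction", p) for p in pairs]
    if include_quadratics:
        terms += [Term("quadratic", (n,)) for n in names]
    return terms
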