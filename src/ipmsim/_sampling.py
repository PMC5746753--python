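"""Positive-floor sampling policy.

Clearances and yields enter the propagation as divisors/factors, so a
normal draw at or below zero would be unphysical.  Draws at or below a
small floor are redrawn (up to ``max_redraw`` times); survivors are
clipped to the floor.  Yields are additionally capped at 1.  Every
intervention is counted so a run can be audited for how often the
policy fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FloorCounters", "draw_positive", "FLOOR"]

FLOOR = 1e-6
MAX_REDRAW = 100


@dataclass
class FloorCounters:
    """Tally of floor-policy interventions during sampling."""

    redraws: int = 0
    clips: int = 0
    caps: int = 0

    def merge(self, other: "FloorCounters") -> None:
        self.redraws += other.redraws
        self.clips += other.clips
        self.caps += other.caps

    @property
    def total(self) -> int:
        return self.redraws + self.clips + self.caps

    def as_dict(self) -> dict:
        return {"redraws": self.redraws, "clips": self.clips, "caps": self.caps}


def draw_positive(
    mean,
    sd,
    rng: np.random.Generator,
    size: int | None = None,
    floor: float = FLOOR,
    cap: float | None = None,
    max_redraw: int = MAX_REDRAW,
    counters: FloorCounters | None = None,
) -> np.ndarray:
    """Vectorized Normal(mean, sd^2) draws under the floor policy.

    ``mean`` and ``sd`` broadcast against ``size``.  When ``sd`` is zero
    everywhere the mean is returned exactly (no stream consumption
    beyond the initial draw shape is wasted in that case either).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    shape = np.broadcast_shapes(mean.shape, sd.shape, () if size is None else (size,))
    mean_b = np.broadcast_to(mean, shape)
    sd_b = np.broadcast_to(sd, shape)
    if np.all(sd_b == 0):
        x = mean_b.copy()
    else:
        x = mean_b + sd_b * rng.standard_normal(shape)
        bad = x <= floor
        n_redraw = 0
        while bad.any() and n_redraw < max_redraw:
            idx = np.nonzero(bad)
            x[idx] = mean_b[idx] + sd_b[idx] * rng.standard_normal(len(idx[0]))
            if counters is not None:
                counters.redraws += int(len(idx[0]))
            n_redraw += 1
            bad = x <= floor
    below = x <= floor
    if below.any():
        x = np.where(below, floor, x)
        if counters is not None:
            counters.clips += int(below.sum())
    if cap is not None:
        over = x > cap
        if over.any():
            x = np.where(over, cap, x)
            if counters is not None:
                counters.caps += int(over.sum())
    return x
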