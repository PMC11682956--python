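"""Dose event containers.

A :class:`Regimen` is an ordered list of zero-order dose inputs.  Each
event delivers ``amount_mg`` milligrams into the central compartment at a
constant rate over ``duration`` days starting at ``start``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = ["DoseEvent", "Regimen"]


@dataclass(frozen=True)
class DoseEvent:
    start: float  # days
    amount_mg: float
    duration: float  # days (zero-order input duration)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("dose event start must be >= 0")
        if self.amount_mg < 0:
            raise ValueError("dose amount must be >= 0")
        if not self.duration > 0:
            raise ValueError("dose duration must be positive")


class Regimen:
    """Ordered collection of dose events; empty regimen = placebo."""

    def __init__(self, events: Iterable[DoseEvent] = ()):
        events = sorted(events, key=lambda e: e.start)
        self.events: tuple[DoseEvent, ...] = tuple(events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[DoseEvent]:
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, Regimen) and self.events == other.events

    def total_dose_mg(self) -> float:
        return float(sum(e.amount_mg for e in self.events))

    def scaled(self, factor: float) -> "Regimen":
        """Regimen with every amount multiplied by ``factor``."""
        return Regimen(
            DoseEvent(e.start, e.amount_mg * factor, e.duration) for e in self.events
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(start, rate_ug_per_day, duration) arrays for vectorised math."""
        if not self.events:
            z = np.empty(0)
            return z, z.copy(), z.copy()
        start = np.array([e.start for e in self.events])
        dur = np.array([e.duration for e in self.events])
        rate = np.array([e.amount_mg for e in self.events]) * 1e3 / dur  # ug/day
        return start, rate, dur

    @staticmethod
    def bid(
        dose_g: float,
        start_day: float,
        end_day: float,
        duration: float,
        interval: float = 0.5,
    ) -> list[DoseEvent]:
        """Twice-daily events of ``dose_g`` grams on [start_day, end_day)."""
        times = np.arange(start_day, end_day - 1e-9, interval)
        return [DoseEvent(float(t), dose_g * 1e3, duration) for t in times]
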