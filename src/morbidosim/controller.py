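"""Morbidostat decision logic.

Each control cycle the device reads the culture's optical density, estimates
the recent growth rate, and chooses which medium the dilution delivers: drug
medium when the population is both above a preset density threshold and still
growing, drug-free medium otherwise. An equal waste volume is removed every
cycle so the working volume is constant. This is the feedback rule that makes
a morbidostat escalate selection as resistance evolves: a culture that keeps
growing through the drug keeps receiving more of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamics import PumpKind

logger = logging.getLogger(__name__)

__all__ = [
    "OD_FLOOR",
    "ControllerConfig",
    "PumpDecision",
    "estimate_growth_rate",
    "decide",
    "control_tick",
]

#: Nonpositive OD readings are floored here before taking logs.
OD_FLOOR = 1e-4


@dataclass
class ControllerConfig:
    """Feedback-loop settings.

    od_threshold:
        Density above which drug may be added (OD units).
    cycle_period:
        Minutes between control ticks.
    dilution_volume:
        mL added (and removed as waste) each cycle.
    drug_stock_conc:
        Drug concentration of the selective reservoir (ug/mL).
    window:
        Number of most recent OD readings used for the rate estimate.
    rate_threshold:
        Growth rate (per hour) that must be exceeded for drug addition;
        0 encodes "growing at all".
    """

    od_threshold: float = 0.3
    cycle_period: float = 12.0
    dilution_volume: float = 1.0
    drug_stock_conc: float = 40.0
    window: int = 5
    rate_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.od_threshold > 0:
            raise ValueError("od_threshold must be > 0")
        if not self.cycle_period > 0:
            raise ValueError("cycle_period must be > 0")
        if self.dilution_volume < 0:
            raise ValueError("dilution_volume must be >= 0")
        if self.window < 2:
            raise ValueError("window must be >= 2")


@dataclass(frozen=True)
class PumpDecision:
    """One cycle's actuation: which medium, how much, and the paired waste."""

    kind: PumpKind
    volume: float
    waste_volume: float

    def __post_init__(self) -> None:
        if self.volume < 0 or self.waste_volume < 0:
            raise ValueError("volumes must be >= 0")
        if self.volume != self.waste_volume:
            raise ValueError("waste must equal the added volume (constant-volume loop)")


def estimate_growth_rate(times, ods) -> float:
    """Log-linear growth rate: OLS slope of ln(OD) against time (per hour).

    Exact on noiseless exponentials; nonpositive readings are floored at
    ``OD_FLOOR`` with a warning (a photodiode blip must not crash the loop).
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 readings to estimate a growth rate")
    if t.shape != od.shape:
        raise ValueError("times and ods must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(od <= 0):
        logger.warning("nonpositive OD reading(s) floored at %g", OD_FLOOR)
        od = np.maximum(od, OD_FLOOR)
    slope, _ = np.polyfit(t, np.log(od), 1)
    return float(slope)


def decide(current_od: float, growth_rate: float, config: ControllerConfig) -> PumpDecision:
    """The morbidostat rule: drug iff above threshold AND growing.

    SELECTIVE when ``current_od > od_threshold`` and
    ``growth_rate > rate_threshold`` (both strict; ties get drug-free medium),
    otherwise PERMISSIVE. Every cycle delivers ``dilution_volume`` mL with an
    equal waste volume.
    """
    if current_od < 0:
        raise ValueError("current_od must be >= 0")
    if current_od > config.od_threshold and growth_rate > config.rate_threshold:
        kind = PumpKind.SELECTIVE
    else:
        kind = PumpKind.PERMISSIVE
    return PumpDecision(kind=kind, volume=config.dilution_volume,
                        waste_volume=config.dilution_volume)


def control_tick(times, ods, config: ControllerConfig) -> tuple[PumpDecision, float]:
    """One control cycle: estimate the rate over the last ``window`` readings
    and decide which medium to deliver.

    Until ``window`` readings have accumulated the growth rate is treated as
    0, which cannot exceed a rate threshold of 0 — so the start-up phase
    always delivers permissive medium.

    Returns ``(decision, growth_rate_used)``.
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.size == 0:
        raise ValueError("history must be nonempty")
    if t.size < config.window:
        rate = 0.0
    else:
        rate = estimate_growth_rate(t[-config.window:], od[-config.window:])
    return decide(float(od[-1]), rate, config), rate
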