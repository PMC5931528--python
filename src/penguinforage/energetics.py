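"""Activity-budget energetics and colony-scale prey consumption.

Daily energy expenditure (DEE, kJ kg⁻¹ day⁻¹) is modelled as an affine
activity budget: DEE(P) = (1−P)·e_land + P·e_sea, where P is the
proportion of time at sea. The two activity rates are calibrated exactly
through two known (P, DEE) pairs, so the model reproduces stage-specific
expenditure from time budgets alone.

Season-scale colony consumption combines adult daily intake over the
breeding season with total chick requirements.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ActivityRates",
    "ColonyParams",
    "derive_activity_rates",
    "dee_from_time_at_sea",
    "colony_consumption",
]


@dataclass
class ActivityRates:
    """Mass-specific energy expenditure ashore and at sea (kJ kg⁻¹ day⁻¹)."""

    e_land: float
    e_sea: float

    def __post_init__(self):
        if not (self.e_sea >= self.e_land > 0):
            raise ValueError("require e_sea >= e_land > 0")


@dataclass
class ColonyParams:
    """Colony-scale consumption inputs."""

    pairs: int
    chicks: int
    adult_intake_kg_day: float = 1.1
    chick_requirement_kg: float = 60.0
    season_days: int = 137

    def __post_init__(self):
        for f in ("pairs", "chicks", "adult_intake_kg_day", "chick_requirement_kg", "season_days"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def derive_activity_rates(p1: float, dee1: float, p2: float, dee2: float) -> ActivityRates:
    """Solve the affine activity model exactly through two (P, DEE) pairs."""
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    e_sea_minus_land = (dee2 - dee1) / (p2 - p1)
    e_land = dee1 - p1 * e_sea_minus_land
    return ActivityRates(e_land=float(e_land), e_sea=float(e_land + e_sea_minus_land))


def dee_from_time_at_sea(p: float, rates: ActivityRates) -> float:
    """DEE(P) = (1−P)·e_land + P·e_sea; P must lie in [0, 1]."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("P must lie in [0, 1]")
    return float((1.0 - p) * rates.e_land + p * rates.e_sea)


def colony_consumption(c: ColonyParams, round_to: float | None = None) -> float:
    """Season prey consumption (metric tonnes):
    (pairs × 2 × adult intake × season days + chicks × chick requirement) / 1000.

    ``round_to`` optionally rounds to the nearest multiple (e.g. 10 t).
    """
    tonnes = (
        c.pairs * 2 * c.adult_intake_kg_day * c.season_days
        + c.chicks * c.chick_requirement_kg
    ) / 1000.0
    if round_to:
        tonnes = round(tonnes / round_to) * round_to
    return float(tonnes)
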