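"""Population lives-saved model: a transparent multiplicative chain.

Annual preventable deaths under statin therapy for the newly up-classified
fraction of a screening-eligible population:

    deaths/year = n_eligible
                x up_classified_fraction
                x annual_fatal_event_rate_in_upclassified
                x statin_relative_risk_reduction
                x uptake_compliance

All five factors are config inputs with uncertainty passed through
multiplicatively (CI bounds scale with the point estimate). Helpers scale
by uptake, extend over a horizon in years, and produce the rounded
presentation figures (nearest integer deaths; "approximately N thousand";
millions to one decimal, round half up).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ImpactParams",
    "preventable_deaths_annual",
    "scale_by_uptake",
    "lives_saved_over_horizon",
    "upclassified_count",
    "approx_thousands",
    "millions_one_decimal",
]


@dataclass(frozen=True)
class ImpactParams:
    n_eligible: float
    up_classified_fraction: float
    annual_fatal_event_rate_in_upclassified: float
    statin_relative_risk_reduction: float
    uptake_compliance: float = 1.0
    horizon_years: int = 5

    def __post_init__(self) -> None:
        if self.n_eligible <= 0:
            raise ValueError("n_eligible must be positive")
        for name in (
            "up_classified_fraction",
            "annual_fatal_event_rate_in_upclassified",
            "statin_relative_risk_reduction",
            "uptake_compliance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")


def preventable_deaths_annual(params: ImpactParams) -> tuple[float, int]:
    """(unrounded, rounded) preventable deaths per year."""
    deaths = (
        params.n_eligible
        * params.up_classified_fraction
        * params.annual_fatal_event_rate_in_upclassified
        * params.statin_relative_risk_reduction
        * params.uptake_compliance
    )
    return deaths, int(round(deaths))


def scale_by_uptake(
    full_uptake_deaths: float,
    uptake: float,
    ci: tuple[float, float] | None = None,
) -> int | tuple[int, tuple[int, int]]:
    """Deaths under partial uptake/compliance; CI bounds scale identically."""
    if not 0.0 <= uptake <= 1.0:
        raise ValueError("uptake must be within [0, 1]")
    scaled = int(round(full_uptake_deaths * uptake))
    if ci is None:
        return scaled
    lo, hi = sorted(ci)
    return scaled, (int(round(lo * uptake)), int(round(hi * uptake)))


def lives_saved_over_horizon(annual_deaths: float, horizon_years: int) -> float:
    if horizon_years < 1:
        raise ValueError("horizon must be >= 1 year")
    return annual_deaths * horizon_years


def approx_thousands(total: float) -> int:
    """Nearest-thousand presentation figure for 'approximately N' reporting."""
    return int(round(total / 1000.0)) * 1000


def upclassified_count(n_eligible: float, fraction: float) -> float:
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be within [0, 1]")
    return n_eligible * fraction


def millions_one_decimal(count: float) -> str:
    """Millions to one decimal, round half up (7.35e6 -> '7.4')."""
    millions = Decimal(f"{count / 1e6:.6f}").quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return str(millions)
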