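"""The deterministic A-G break-even economics of one feedlot cohort.

The ledger, per animal over the feeding period:

    A  purchase cost   = entry live weight x live price, fully financed
    B  feeding cost    = daily intake x diet cost x DOF, half financed
                         (displayed at the legacy 10%/yr rate, see below)
    C  total carcass cost = A + feed principal financed at the headline rate
    D  carcass income  = exit carcass weight x carcass price
    E  carcass feed cost of gain (CFCOG) = B / carcass gain   [ZAR/kg]
    F  profit          = D - C
    G  profit margin   = 100 * F / C   [%]

Financing is simple pro-rata interest: a financed fraction f of a principal
P accrues P*f*r*days/basis (ACT/365 by default; no compounding). Two feed
rates coexist in the source display: the feeding-cost row B is shown with
r = 10%/yr on half the feed bill, while the cost chain C/F/G is consistent
only with the headline r = 11.75%/yr. The canonical model therefore
finances feed at ``annual_interest_rate`` inside C, and uses
``feed_interest_rate_override`` (default 0.10) solely for the displayed B
row — and hence for E, which the source defines from B. Exact identities
C = A + financed feed, F = D - C and G = 100*F/C hold on every evaluation.

Break-even solvers invert the ledger in closed form: the live purchase
price (or carcass sale price) at which F = 0 with everything else held
fixed. Profit is linear in either price, so the closed forms are exact.
Negative profits are legal outputs throughout, never errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .carcass_model import entry_carcass_weight
from .errors import DomainError, UndefinedRatioError
from .production_data import CohortProduction, EconParams

__all__ = [
    "EconResult",
    "FeedCost",
    "financing_multiplier",
    "purchase_cost",
    "feed_cost",
    "total_cost",
    "carcass_income",
    "cfcog",
    "profit",
    "profit_margin",
    "breakeven_live_price",
    "breakeven_carcass_price",
    "calf_beef_price_ratio",
    "evaluate_cohort",
]

GainSource = Literal["data", "conversion"]


@dataclass(frozen=True)
class EconResult:
    """The A-G ledger for one cohort, plus break-even prices.

    Currency fields are ZAR per animal; ``cfcog_E`` is ZAR/kg carcass gain;
    ``margin_G`` is a percentage. ``base_feed_cost`` is the feed bill before
    any financing; ``feed_cost_B`` is the displayed (override-rate) financed
    feeding cost.
    """

    purchase_cost_A: float
    feed_cost_B: float
    total_cost_C: float
    income_D: float
    cfcog_E: float
    profit_F: float
    margin_G: float
    base_feed_cost: float
    breakeven_live_price: float
    breakeven_carcass_price: float


@dataclass(frozen=True)
class FeedCost:
    base: float      # principal: intake x cost x days, no interest
    financed: float  # principal plus interest on the financed fraction


def financing_multiplier(rate: float, days: float, basis: float,
                         financed_fraction: float) -> float:
    """Simple pro-rata financing multiplier 1 + f * r * days/basis."""
    if rate < 0 or days < 0:
        raise DomainError(f"rate and days must be >= 0 (rate={rate}, days={days})")
    if basis <= 0:
        raise DomainError(f"day-count basis must be > 0, got {basis}")
    if not 0 <= financed_fraction <= 1:
        raise DomainError(f"financed fraction must lie in [0, 1], got {financed_fraction}")
    return 1.0 + financed_fraction * rate * days / basis


def purchase_cost(entry_weight: float, params: EconParams) -> float:
    """Financed calf purchase cost A (ZAR) from live entry weight (kg)."""
    if entry_weight <= 0:
        raise DomainError(f"entry weight must be > 0, got {entry_weight}")
    mult = financing_multiplier(params.annual_interest_rate, params.days_on_feed,
                                params.day_count_basis, params.purchase_financed_fraction)
    return entry_weight * params.live_price * mult


def feed_cost(daily_intake: float, diet_cost: float, params: EconParams,
              rate: float | None = None) -> FeedCost:
    """Feed bill over the period: principal and financed total.

    ``rate`` defaults to the canonical annual rate; pass
    ``params.feed_display_rate`` to reproduce the displayed B row.
    """
    if daily_intake <= 0 or diet_cost <= 0:
        raise DomainError(
            f"intake and diet cost must be > 0 (intake={daily_intake}, cost={diet_cost})")
    if rate is None:
        rate = params.annual_interest_rate
    base = daily_intake * diet_cost * params.days_on_feed
    mult = financing_multiplier(rate, params.days_on_feed, params.day_count_basis,
                                params.feed_financed_fraction)
    return FeedCost(base=base, financed=base * mult)


def total_cost(purchase_A: float, base_feed: float, params: EconParams) -> float:
    """Total carcass cost C = A + feed principal financed at the canonical rate."""
    if purchase_A < 0 or base_feed < 0:
        raise DomainError("costs must be >= 0")
    mult = financing_multiplier(params.annual_interest_rate, params.days_on_feed,
                                params.day_count_basis, params.feed_financed_fraction)
    return purchase_A + base_feed * mult


def carcass_income(carcass_weight: float, carcass_price: float) -> float:
    """Carcass income D = exit carcass weight x carcass price."""
    if carcass_weight <= 0:
        raise DomainError(f"carcass weight must be > 0, got {carcass_weight}")
    if carcass_price < 0:
        raise DomainError(f"carcass price must be >= 0, got {carcass_price}")
    return carcass_weight * carcass_price


def cfcog(financed_feed_cost: float, carcass_gain: float) -> float:
    """Carcass feed cost of gain E = financed feed cost / carcass gain (ZAR/kg)."""
    if carcass_gain <= 0:
        raise UndefinedRatioError(
            f"CFCOG undefined for non-positive carcass gain ({carcass_gain} kg)")
    return financed_feed_cost / carcass_gain


def profit(income_D: float, cost_C: float) -> float:
    """Profit F = D - C; negative values are losses, not errors."""
    return income_D - cost_C


def profit_margin(profit_F: float, cost_C: float) -> float:
    """Profit margin G = 100 * F / C (%)."""
    if cost_C <= 0:
        raise DomainError(f"total cost must be > 0 for a margin, got {cost_C}")
    return 100.0 * profit_F / cost_C


def calf_beef_price_ratio(live_price: float, carcass_price: float) -> float:
    """Calf:beef price ratio (%), the procurement guideline (should be < ~55%)."""
    if carcass_price <= 0:
        raise DomainError(f"carcass price must be > 0, got {carcass_price}")
    if live_price < 0:
        raise DomainError(f"live price must be >= 0, got {live_price}")
    return 100.0 * live_price / carcass_price


def _cohort_gain(cohort: CohortProduction, gain_source: GainSource) -> float:
    if gain_source == "data":
        return cohort.carcass_gain.mean
    if gain_source == "conversion":
        return cohort.carcass_weight.mean - entry_carcass_weight(cohort.entry_weight.mean)
    raise DomainError(f"unknown gain source: {gain_source!r}")


def _financed_feed(cohort: CohortProduction, params: EconParams) -> float:
    return feed_cost(cohort.daily_intake.mean, cohort.diet.cost_per_kg, params).financed


def breakeven_live_price(cohort: CohortProduction, params: EconParams) -> float:
    """Live purchase price (ZAR/kg) at which the cohort's profit is zero.

    A is linear in the live price, so p* = (D - financed feed) / (entry
    weight x purchase financing multiplier); re-evaluating profit at p*
    returns zero to rounding.
    """
    if cohort.entry_weight.mean <= 0:
        raise DomainError("entry weight must be > 0")
    d = carcass_income(cohort.carcass_weight.mean, params.carcass_price)
    mult = financing_multiplier(params.annual_interest_rate, params.days_on_feed,
                                params.day_count_basis, params.purchase_financed_fraction)
    return (d - _financed_feed(cohort, params)) / (cohort.entry_weight.mean * mult)


def breakeven_carcass_price(cohort: CohortProduction, params: EconParams) -> float:
    """Carcass sale price (ZAR/kg) at which the cohort's profit is zero: C / CW."""
    if cohort.carcass_weight.mean <= 0:
        raise DomainError("carcass weight must be > 0")
    a = purchase_cost(cohort.entry_weight.mean, params)
    base = feed_cost(cohort.daily_intake.mean, cohort.diet.cost_per_kg, params).base
    return total_cost(a, base, params) / cohort.carcass_weight.mean


def evaluate_cohort(cohort: CohortProduction, params: EconParams,
                    gain_source: GainSource = "data") -> EconResult:
    """Run the full A-G ledger for one cohort.

    ``gain_source`` selects the carcass gain denominator of E: measured
    cohort data (default) or the entry-carcass conversion applied to the
    cohort means.
    """
    a = purchase_cost(cohort.entry_weight.mean, params)
    fc = feed_cost(cohort.daily_intake.mean, cohort.diet.cost_per_kg, params)
    b_display = feed_cost(cohort.daily_intake.mean, cohort.diet.cost_per_kg, params,
                          rate=params.feed_display_rate).financed
    c = total_cost(a, fc.base, params)
    d = carcass_income(cohort.carcass_weight.mean, params.carcass_price)
    gain = _cohort_gain(cohort, gain_source)
    e = cfcog(b_display, gain)
    f = profit(d, c)
    g = profit_margin(f, c)
    return EconResult(
        purchase_cost_A=a,
        feed_cost_B=b_display,
        total_cost_C=c,
        income_D=d,
        cfcog_E=e,
        profit_F=f,
        margin_G=g,
        base_feed_cost=fc.base,
        breakeven_live_price=breakeven_live_price(cohort, params),
        breakeven_carcass_price=breakeven_carcass_price(cohort, params),
    )
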