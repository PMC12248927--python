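"""Sensitivity analysis and Monte-Carlo propagation of trait uncertainty.

The deterministic ledger prices cohort *means*; this module quantifies how
uncertain those means leave the profit. Two tools:

* one-at-a-time (OAT) sensitivity: re-evaluate profit with a single price or
  production input moved by +/- delta, and report the elasticity
  (% profit change per % input change);
* Monte-Carlo: draw the four priced traits (entry weight, exit carcass
  weight, daily intake, carcass gain) from distributions whose SDs are
  back-converted from the cohort's 95% CIs, evaluate the full-precision
  ledger per draw, and summarize the profit distribution.

Traits are sampled independently — the study publishes no covariances.
Intake and gain are positively correlated in real cattle, and their costs
and revenues enter profit with opposite signs, so independence makes the
simulated profit variance conservative (an overestimate).

Draws use numpy's seeded PCG64 generator (recorded in the summary) and, by
default, antithetic pairing: each standard-normal draw z is mirrored with
-z. Profit is exactly linear in the four traits, so pairing preserves the
simulated mean at the deterministic profit to machine precision while
leaving the spread estimates unbiased; set ``antithetic=False`` for plain
sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import _stats
from .econ_model import evaluate_cohort, financing_multiplier
from .errors import DomainError
from .production_data import CohortProduction, DietSpec, EconParams, TraitSummary

__all__ = [
    "TraitDistribution",
    "MCSummary",
    "OATResult",
    "sd_from_ci",
    "ci_from_sd",
    "cohort_trait_distributions",
    "oat_sensitivity",
    "monte_carlo",
]

Family = Literal["normal", "lognormal"]

#: Traits sampled by the Monte-Carlo, in draw order.
MC_TRAITS = ("entry_weight", "carcass_weight", "daily_intake", "carcass_gain")

#: Inputs the OAT sensitivity can perturb.
OAT_PARAMS = ("live_price", "carcass_price", "diet_cost",
              "annual_interest_rate", "daily_intake", "carcass_gain")

_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class TraitDistribution:
    """Sampling distribution of one animal-level trait."""

    mean: float
    sd: float
    family: Family = "normal"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError(f"sd must be >= 0, got {self.sd}")
        if self.family == "lognormal" and self.mean <= 0:
            raise DomainError("lognormal traits require a positive mean")
        if self.family not in ("normal", "lognormal"):
            raise DomainError(f"unknown distribution family: {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int,
               antithetic: bool = False) -> np.ndarray:
        if antithetic:
            half = rng.standard_normal((size + 1) // 2)
            z = np.concatenate([half, -half])[:size]
        else:
            z = rng.standard_normal(size)
        if self.family == "normal":
            return self.mean + self.sd * z
        # moment-matched lognormal: same mean and sd as requested
        if self.sd == 0:
            return np.full(size, self.mean)
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return np.exp(mu + math.sqrt(sigma2) * z)


@dataclass(frozen=True)
class MCSummary:
    """Summary of a simulated profit distribution (ZAR per animal)."""

    n_draws: int
    profit_mean: float
    profit_sd: float
    profit_q025: float
    profit_q975: float
    prob_loss: float
    seed: int
    n_rejected: int
    rejection_fraction: float
    high_rejection_warning: bool
    antithetic: bool
    bit_generator: str = "PCG64"


@dataclass(frozen=True)
class OATResult:
    """Profit response to a +/- delta perturbation of one input."""

    param: str
    delta: float
    profit_low: float   # input at (1 - delta) x base
    profit_base: float
    profit_high: float  # input at (1 + delta) x base
    elasticity: float | None  # (% profit change)/(% input change); None if F_base = 0
    delta_f: float      # absolute half-range (F_high - F_low)/2


def sd_from_ci(summary: TraitSummary, n: int) -> float:
    """Animal-level SD implied by a 95% t-CI on a mean of n animals.

    sd = sqrt(n) * halfwidth / t_{0.975, n-1}. If the study's CIs were
    z-based instead, this overestimates the SD by t/1.96 — conservative for
    the profit spread.
    """
    if summary.ci_high < summary.ci_low:
        raise DomainError("ci_high must be >= ci_low")
    return _stats.sd_from_halfwidth(summary.halfwidth, n)


def ci_from_sd(mean: float, sd: float, n: int) -> TraitSummary:
    """Inverse of :func:`sd_from_ci`: rebuild the t-based 95% CI."""
    return TraitSummary.from_mean_sd(mean, sd, n)


def cohort_trait_distributions(cohort: CohortProduction, family: Family = "normal"
                               ) -> dict[str, TraitDistribution]:
    """Sampling distributions of the four priced traits of a cohort."""
    return {
        trait: TraitDistribution(
            mean=getattr(cohort, trait).mean,
            sd=sd_from_ci(getattr(cohort, trait), cohort.n),
            family=family,
        )
        for trait in MC_TRAITS
    }


def oat_sensitivity(cohort: CohortProduction, params: EconParams,
                    param_name: str, delta: float) -> OATResult:
    """One-at-a-time sensitivity of profit to one input, perturbed by +/- delta.

    ``param_name`` is one of ``live_price``, ``carcass_price``,
    ``diet_cost``, ``annual_interest_rate``, ``daily_intake``,
    ``carcass_gain``. Elasticity is reported when the base profit is
    nonzero; the absolute half-range ``delta_f`` always is.
    """
    if param_name not in OAT_PARAMS:
        raise DomainError(f"unknown sensitivity parameter: {param_name!r}; "
                          f"expected one of {OAT_PARAMS}")
    if delta < 0:
        raise DomainError(f"delta must be >= 0, got {delta}")

    def perturbed(factor: float) -> float:
        c, p = cohort, params
        if param_name in ("live_price", "carcass_price", "annual_interest_rate"):
            p = params.model_copy(update={param_name: getattr(params, param_name) * factor})
        elif param_name == "diet_cost":
            diet = DietSpec.of(cohort.diet.name, cohort.diet.cost_per_kg * factor)
            c = cohort.model_copy(update={"diet": diet})
        else:  # daily_intake / carcass_gain
            c = cohort.model_copy(
                update={param_name: getattr(cohort, param_name).scaled(factor)})
        return evaluate_cohort(c, p).profit_F

    f_base = evaluate_cohort(cohort, params).profit_F
    f_low = perturbed(1.0 - delta)
    f_high = perturbed(1.0 + delta)
    delta_f = (f_high - f_low) / 2.0
    if f_base != 0 and delta > 0:
        elasticity = (delta_f / f_base) / delta
    else:
        elasticity = None
    return OATResult(param=param_name, delta=delta, profit_low=f_low,
                     profit_base=f_base, profit_high=f_high,
                     elasticity=elasticity, delta_f=delta_f)


def monte_carlo(cohort: CohortProduction, params: EconParams, n_draws: int,
                seed: int, family: Family = "normal",
                antithetic: bool = True) -> MCSummary:
    """Propagate the cohort's trait CIs into a profit distribution.

    Draws the four priced traits independently, rejects and redraws any
    draw with a non-positive carcass gain or intake (counted; a rejection
    fraction above 10% raises the summary's warning flag), and evaluates
    the exact ledger per draw. Identical seed and inputs give bit-identical
    summaries.
    """
    if n_draws < 1:
        raise DomainError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    dists = cohort_trait_distributions(cohort, family=family)

    draws = {t: dists[t].sample(rng, n_draws, antithetic=antithetic) for t in MC_TRAITS}
    n_rejected = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = ((draws["carcass_gain"] <= 0) | (draws["daily_intake"] <= 0)
               | (draws["entry_weight"] <= 0) | (draws["carcass_weight"] <= 0))
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_rejected += n_bad
        for t in MC_TRAITS:
            draws[t][bad] = dists[t].sample(rng, n_bad)
    else:
        raise DomainError(
            "rejection sampling failed to converge; trait distributions put "
            "almost all mass on non-positive values")

    # Same operation order as the scalar ledger, so zero-variance inputs
    # reproduce the deterministic profit bit for bit.
    mult_purch = financing_multiplier(params.annual_interest_rate, params.days_on_feed,
                                      params.day_count_basis,
                                      params.purchase_financed_fraction)
    a = draws["entry_weight"] * params.live_price * mult_purch
    mult_feed = financing_multiplier(params.annual_interest_rate, params.days_on_feed,
                                     params.day_count_basis, params.feed_financed_fraction)
    base = draws["daily_intake"] * cohort.diet.cost_per_kg * params.days_on_feed
    c = a + base * mult_feed
    d = draws["carcass_weight"] * params.carcass_price
    profit = d - c

    rejection_fraction = n_rejected / (n_draws + n_rejected)
    if profit.min() == profit.max():
        # degenerate (zero-variance) distribution: mean is that value
        # exactly, with no summation rounding, and the spread is truly zero
        mean, sd = float(profit[0]), 0.0
    else:
        mean = float(np.mean(profit))
        sd = float(np.std(profit, ddof=1)) if n_draws > 1 else 0.0
    return MCSummary(
        n_draws=n_draws,
        profit_mean=mean,
        profit_sd=sd,
        profit_q025=float(np.quantile(profit, 0.025)),
        profit_q975=float(np.quantile(profit, 0.975)),
        prob_loss=float(np.mean(profit < 0)),
        seed=seed,
        n_rejected=n_rejected,
        rejection_fraction=rejection_fraction,
        high_rejection_warning=rejection_fraction > 0.10,
        antithetic=antithetic,
    )
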