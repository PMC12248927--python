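"""Live-to-carcass conversion at feedlot entry and derived carcass ratios.

Beef is traded on the carcass, not the live animal, so the break-even model
prices gain on a carcass basis. The entry carcass weight of a feeder calf is
predicted from its shrunk body weight (SBW, kg live) with the linear
conversion

    CW = 0.694 * SBW - 38.43   [kg carcass]

valid only above the positive root SBW = 38.43/0.694 ~ 55.37 kg (any real
feeder calf is far above it). No shrink adjustment is applied: the cohort
mean entry weight is used as SBW directly.

Cohort-level carcass gain is normally taken from measured data rather than
recomputed via this conversion — the study's per-cohort gains come from
per-animal records and are not consistent with applying the conversion to
cohort means — but the conversion is exposed for new inputs and for the
synthetic generator, which uses it to keep its animals internally
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, UndefinedRatioError

__all__ = [
    "CarcassConversion",
    "DEFAULT_CONVERSION",
    "entry_carcass_weight",
    "carcass_adg",
    "carcass_fcr",
]


@dataclass(frozen=True)
class CarcassConversion:
    """Linear SBW -> entry carcass weight conversion, CW = slope*SBW + intercept."""

    slope: float = 0.694
    intercept: float = -38.43

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError("conversion slope must be > 0")

    @property
    def min_live_weight(self) -> float:
        """SBW at which predicted CW crosses zero (domain lower bound)."""
        return -self.intercept / self.slope


DEFAULT_CONVERSION = CarcassConversion()


def entry_carcass_weight(sbw: float, conv: CarcassConversion = DEFAULT_CONVERSION) -> float:
    """Predicted carcass weight (kg) at feedlot entry from live SBW (kg)."""
    if sbw <= conv.min_live_weight:
        raise DomainError(
            f"SBW {sbw} kg is at or below the conversion's positive root "
            f"({conv.min_live_weight:.3f} kg); predicted carcass weight would be <= 0")
    return conv.slope * sbw + conv.intercept


def carcass_adg(gain: float, dof: float) -> float:
    """Carcass average daily gain (kg/d) over ``dof`` days on feed."""
    if dof <= 0:
        raise DomainError(f"days on feed must be > 0, got {dof}")
    return gain / dof


def carcass_fcr(total_intake: float, gain: float) -> float:
    """Carcass feed conversion ratio: kg feed per kg carcass gain."""
    if gain <= 0:
        raise UndefinedRatioError(
            f"carcass FCR undefined for non-positive gain ({gain} kg)")
    return total_intake / gain
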