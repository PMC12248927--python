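"""Domain types and I/O for feedlot production and economic inputs.

The unit of analysis is the *cohort*: one production-profile (PP) class of
feeder calves finished on one diet for a fixed feeding period. Each cohort
carries its production trait summaries (mean and 95% CI over the n animals)
and the diet fed; the economic layer prices those traits.

PP classes are the phenotype-based growth-potential categories used at
feedlot intake: PP 1 above-average, PP 2 average (the pooled union of the
PP 2+ and PP 2- sub-classes), PP 3 below-average. Diets are a low-, medium-
and high-production formulation (LPD/MPD/HPD; 13/14/15% crude protein,
10.6/11.3/12.0 MJ/kg metabolizable energy).

The module also ships the built-in study dataset: nine cohorts
(PP 1/2/3 x LPD/MPD/HPD, 142 days on feed) plus the printed reference
economics table used for cross-checking, so the whole pipeline runs with no
external files.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import _stats
from .errors import CohortValidationError, DomainError, SchemaError

__all__ = [
    "PPClass",
    "DietName",
    "DietSpec",
    "TraitSummary",
    "CohortProduction",
    "EconParams",
    "DIET_NUTRITION",
    "STUDY_DIETS",
    "COHORT_CSV_COLUMNS",
    "builtin_table1",
    "builtin_table2",
    "read_cohorts",
    "write_cohorts",
    "pool_pp2",
]


class PPClass(str, enum.Enum):
    """Production-profile class of a feeder calf (phenotypic growth potential)."""

    PP1 = "PP1"
    PP2_PLUS = "PP2+"
    PP2_MINUS = "PP2-"
    PP2 = "PP2"  # pooled union of PP2+ and PP2-; the class used in model tables
    PP3 = "PP3"

    @classmethod
    def parse(cls, text: str) -> "PPClass":
        aliases = {
            "pp2plus": cls.PP2_PLUS,
            "pp2minus": cls.PP2_MINUS,
            "pp2pooled": cls.PP2,
            "pp2+": cls.PP2_PLUS,
            "pp2-": cls.PP2_MINUS,
        }
        key = text.strip().replace(" ", "").lower()
        if key in aliases:
            return aliases[key]
        try:
            return cls(key.upper())
        except ValueError:
            raise DomainError(f"unknown production profile class: {text!r}") from None


class DietName(str, enum.Enum):
    LPD = "LPD"
    MPD = "MPD"
    HPD = "HPD"


#: Crude protein (% DM) and metabolizable energy (MJ/kg) of each formulation.
DIET_NUTRITION: Mapping[DietName, tuple[float, float]] = {
    DietName.LPD: (13.0, 10.6),
    DietName.MPD: (14.0, 11.3),
    DietName.HPD: (15.0, 12.0),
}


class DietSpec(BaseModel):
    """A finishing diet: formulation identity plus its as-fed cost."""

    model_config = ConfigDict(frozen=True)

    name: DietName
    crude_protein: float = Field(gt=0, description="crude protein, % of DM")
    metabolizable_energy: float = Field(gt=0, description="ME, MJ/kg")
    cost_per_kg: float = Field(gt=0, description="feed cost, ZAR/kg as fed")

    @classmethod
    def of(cls, name: DietName | str, cost_per_kg: float) -> "DietSpec":
        name = DietName(name)
        cp, me = DIET_NUTRITION[name]
        return cls(name=name, crude_protein=cp, metabolizable_energy=me,
                   cost_per_kg=cost_per_kg)


#: The study's diets at the experimental facility's actual feed costs (ZAR/kg).
STUDY_DIETS: Mapping[DietName, DietSpec] = {
    DietName.LPD: DietSpec.of(DietName.LPD, 4.73),
    DietName.MPD: DietSpec.of(DietName.MPD, 5.10),
    DietName.HPD: DietSpec.of(DietName.HPD, 6.10),
}


class TraitSummary(BaseModel):
    """Mean of a production trait with its 95% confidence interval."""

    model_config = ConfigDict(frozen=True)

    mean: float
    ci_low: float
    ci_high: float

    @model_validator(mode="after")
    def _ordered(self) -> "TraitSummary":
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"CI must bracket the mean: {self.ci_low} <= {self.mean} <= {self.ci_high}"
            )
        return self

    @classmethod
    def point(cls, mean: float) -> "TraitSummary":
        """Zero-width summary (a known constant)."""
        return cls(mean=mean, ci_low=mean, ci_high=mean)

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float, n: int) -> "TraitSummary":
        """Build a t-based 95% CI from an animal-level SD and group size."""
        hw = _stats.halfwidth_from_sd(sd, n)
        return cls(mean=mean, ci_low=mean - hw, ci_high=mean + hw)

    @property
    def halfwidth(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0

    def sd(self, n: int) -> float:
        """Animal-level sample SD implied by the CI (t-based, n-1 df)."""
        return _stats.sd_from_halfwidth(self.halfwidth, n)

    def scaled(self, factor: float) -> "TraitSummary":
        if factor < 0:
            raise DomainError("scale factor must be >= 0")
        return TraitSummary(mean=self.mean * factor, ci_low=self.ci_low * factor,
                            ci_high=self.ci_high * factor)


class CohortProduction(BaseModel):
    """Production summary of one PP x diet cohort over the feeding period.

    Weights are kg; carcass traits are on the carcass (not live) basis:
    ``carcass_weight`` is the exit carcass weight, ``carcass_gain`` the
    carcass weight added over the period, ``carcass_adg`` the daily carcass
    gain and ``carcass_fcr`` kg feed per kg carcass gain. ``daily_intake``
    is kg feed/animal/day.
    """

    model_config = ConfigDict(frozen=True)

    pp: PPClass
    diet: DietSpec
    n: int = Field(ge=1)
    entry_weight: TraitSummary
    carcass_weight: TraitSummary
    carcass_adg: TraitSummary
    carcass_fcr: TraitSummary
    daily_intake: TraitSummary
    carcass_gain: TraitSummary
    days_on_feed: int = Field(gt=0)

    @model_validator(mode="after")
    def _invariants(self) -> "CohortProduction":
        for name in ("entry_weight", "carcass_weight", "carcass_adg",
                     "carcass_fcr", "daily_intake", "carcass_gain"):
            if getattr(self, name).mean <= 0:
                raise ValueError(f"trait mean must be > 0: {name}")
        if self.carcass_gain.mean >= self.carcass_weight.mean:
            raise ValueError("carcass gain must be below exit carcass weight")
        return self

    @property
    def key(self) -> tuple[PPClass, DietName]:
        return (self.pp, self.diet.name)


class EconParams(BaseModel):
    """Economic parameters of the break-even model.

    Financing is simple (non-compounded) pro-rata interest over the feeding
    period: a principal P financed for ``days_on_feed`` days accrues
    ``P * rate * days/basis``. The full purchase price and half the feed bill
    are financed by default, the practice the model assumes for feedlots that
    buy calves on credit and purchase feed continuously through the period.

    ``feed_interest_rate_override`` exists to mirror the study's displayed
    feeding-cost row, which carries a 10%/yr rate while the cost/profit chain
    is internally consistent only at the headline 11.75%/yr; the canonical
    model uses ``annual_interest_rate`` everywhere else.
    """

    model_config = ConfigDict(frozen=True)

    live_price: float = Field(default=33.25, gt=0, description="ZAR/kg live weight")
    carcass_price: float = Field(default=55.00, gt=0, description="ZAR/kg carcass")
    annual_interest_rate: float = Field(default=0.1175, ge=0, description="fraction/yr")
    feed_financed_fraction: float = Field(default=0.5, ge=0, le=1)
    purchase_financed_fraction: float = Field(default=1.0, ge=0, le=1)
    days_on_feed: int = Field(default=142, gt=0)
    day_count_basis: int = Field(default=365)
    feed_interest_rate_override: float | None = Field(default=0.10, ge=0)

    @field_validator("day_count_basis")
    @classmethod
    def _basis(cls, v: int) -> int:
        if v not in (360, 365):
            raise ValueError("day_count_basis must be 360 or 365")
        return v

    @property
    def feed_display_rate(self) -> float:
        """Rate used for the *displayed* feeding-cost row (B)."""
        if self.feed_interest_rate_override is None:
            return self.annual_interest_rate
        return self.feed_interest_rate_override

    @classmethod
    def from_file(cls, path: str | Path) -> "EconParams":
        """Load parameters from a YAML or JSON config keyed as the fields."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise SchemaError(f"config must be a mapping of EconParams fields: {path}")
        try:
            return cls(**data)
        except pydantic.ValidationError as exc:
            raise SchemaError(f"invalid economic parameters in {path}: {exc}") from exc


# --------------------------------------------------------------------------
# Built-in study dataset
# --------------------------------------------------------------------------

# Nine cohorts, 142 days on feed. Trait cells are (mean, ci_low, ci_high).
# The PP1/HPD carcass-weight mean is 319.1: the source table's cell is
# typographically garbled, but 319.1 is confirmed by the reference economics
# (income 319.1 x 55.00 = 17,550.50 = printed profit 251.35 + printed cost
# 17,299.15).
_TABLE1_ROWS: tuple = (
    # pp, diet, n, entry_wt, carcass_wt, cadg, cfcr, daily_intake, gain
    ("PP3", "LPD", 9,  (199.2, 186.1, 212.3), (231.1, 220.7, 241.5),
     (0.84, 0.79, 0.90), (10.62, 9.69, 11.55), (8.69, 7.09, 10.28), (119.5, 111.5, 127.5)),
    ("PP2", "LPD", 17, (212.7, 204.1, 221.3), (269.2, 255.1, 283.4),
     (1.04, 0.96, 1.13), (10.29, 9.67, 10.90), (10.74, 9.64, 11.85), (148.3, 136.8, 159.8)),
    ("PP1", "LPD", 8,  (224.6, 212.6, 236.7), (285.8, 267.6, 304.0),
     (1.10, 1.01, 1.20), (9.82, 9.75, 9.89), (11.19, 10.03, 12.36), (156.6, 143.3, 169.8)),
    ("PP3", "MPD", 9,  (200.0, 181.4, 218.6), (252.6, 232.7, 272.5),
     (1.00, 0.92, 1.06), (9.81, 9.20, 10.42), (9.70, 9.51, 9.89), (140.5, 130.6, 150.3)),
    ("PP2", "MPD", 16, (211.7, 200.2, 223.2), (285.2, 270.0, 300.5),
     (1.16, 1.08, 1.24), (9.04, 8.63, 9.45), (10.28, 9.71, 10.85), (165.0, 153.3, 176.7)),
    ("PP1", "MPD", 9,  (229.4, 213.3, 245.6), (301.1, 286.8, 315.3),
     (1.19, 1.10, 1.27), (9.18, 8.36, 10.00), (11.03, 10.35, 11.71), (168.5, 156.7, 180.3)),
    ("PP3", "HPD", 9,  (205.1, 187.4, 222.8), (258.7, 241.2, 276.2),
     (1.01, 0.91, 1.10), (9.40, 7.34, 11.49), (8.81, 8.48, 9.14), (143.0, 129.1, 156.9)),
    ("PP2", "HPD", 18, (215.8, 207.4, 224.3), (294.0, 280.0, 306.0),
     (1.20, 1.13, 1.28), (8.59, 8.17, 9.01), (10.35, 9.65, 11.05), (170.8, 160.4, 181.3)),
    ("PP1", "HPD", 9,  (225.4, 212.0, 239.0), (319.1, 305.1, 333.1),
     (1.33, 1.27, 1.40), (8.03, 7.53, 8.54), (10.69, 9.95, 11.43), (189.3, 179.8, 198.8)),
)

_STUDY_DOF = 142

# Printed reference economics for the nine cohorts (same row order as
# _TABLE1_ROWS), used for cross-checks and reference-based comparisons.
# Row B carries the 10%/yr feed financing rate of the source display; the
# cost chain C/F/G is consistent with feed financed at 11.75%/yr.
# The PP1/HPD income cell is stored as 17,550.50 (= 319.1 x 55.00, and
# = printed F + printed C); the source prints 17,550.00, inconsistent with
# its own profit row by 0.50.
_TABLE2_ROWS: Mapping[str, tuple[float, ...]] = {
    "A": (6926.17, 7395.57, 7809.33, 6953.99, 7360.80, 7976.22, 7131.31, 7503.35, 7837.14),
    "B": (5951.52, 7355.50, 7663.69, 7152.96, 7580.66, 8133.73, 7772.01, 9130.75, 9430.51),
    "C": (12897.56, 14775.63, 15498.61, 14130.83, 14966.77, 16137.11, 14929.28, 16664.41, 17299.15),
    "D": (12710.50, 14806.00, 15719.00, 13893.00, 15686.00, 16560.50, 14228.50, 16170.00, 17550.50),
    "E": (49.80, 49.60, 48.94, 50.91, 45.94, 48.27, 54.35, 53.46, 49.82),
    "F": (-187.06, 30.37, 220.39, -237.83, 719.23, 423.39, -700.78, -494.41, 251.35),
    "G": (-1.45, 0.21, 1.42, -1.68, 4.81, 2.62, -4.69, -2.97, 1.45),
}


def builtin_table1() -> list[CohortProduction]:
    """The nine built-in study cohorts (PP 1/2/3 x LPD/MPD/HPD, 142 DOF)."""
    cohorts = []
    for pp, diet, n, ew, cw, cadg, cfcr, dmi, gain in _TABLE1_ROWS:
        cohorts.append(CohortProduction(
            pp=PPClass(pp),
            diet=STUDY_DIETS[DietName(diet)],
            n=n,
            entry_weight=_ts(ew),
            carcass_weight=_ts(cw),
            carcass_adg=_ts(cadg),
            carcass_fcr=_ts(cfcr),
            daily_intake=_ts(dmi),
            carcass_gain=_ts(gain),
            days_on_feed=_STUDY_DOF,
        ))
    return cohorts


def builtin_table2() -> dict[str, dict[tuple[PPClass, DietName], float]]:
    """Printed reference economics, keyed row letter -> (pp, diet) -> ZAR.

    Rows: A purchase cost, B feeding cost (financed at the displayed 10%/yr),
    C total carcass cost, D carcass income, E carcass feed cost of gain
    (ZAR/kg), F profit, G profit margin (%).
    """
    keys = [(PPClass(r[0]), DietName(r[1])) for r in _TABLE1_ROWS]
    return {row: dict(zip(keys, vals)) for row, vals in _TABLE2_ROWS.items()}


def _ts(triple: Sequence[float]) -> TraitSummary:
    m, lo, hi = triple
    return TraitSummary(mean=m, ci_low=lo, ci_high=hi)


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

COHORT_CSV_COLUMNS = [
    "pp", "diet", "n",
    "entry_wt_mean", "entry_wt_lo", "entry_wt_hi",
    "carc_wt_mean", "carc_wt_lo", "carc_wt_hi",
    "cadg_mean", "cadg_lo", "cadg_hi",
    "cfcr_mean", "cfcr_lo", "cfcr_hi",
    "dmi_mean", "dmi_lo", "dmi_hi",
    "gain_mean", "gain_lo", "gain_hi",
    "dof", "diet_cost",
]

_TRAIT_PREFIXES = {
    "entry_weight": "entry_wt",
    "carcass_weight": "carc_wt",
    "carcass_adg": "cadg",
    "carcass_fcr": "cfcr",
    "daily_intake": "dmi",
    "carcass_gain": "gain",
}


def read_cohorts(path: str | Path) -> list[CohortProduction]:
    """Read cohort rows from a comma-separated UTF-8 file.

    One row per cohort; CI bounds in their own columns. A pooled PP2 row is
    accepted like any other class label.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV {path} is missing column(s): {', '.join(missing)}")
    cohorts = []
    for idx, row in df.iterrows():
        try:
            traits = {
                field: TraitSummary(mean=row[f"{pre}_mean"], ci_low=row[f"{pre}_lo"],
                                    ci_high=row[f"{pre}_hi"])
                for field, pre in _TRAIT_PREFIXES.items()
            }
            cohorts.append(CohortProduction(
                pp=PPClass.parse(str(row["pp"])),
                diet=DietSpec.of(str(row["diet"]).strip(), float(row["diet_cost"])),
                n=int(row["n"]),
                days_on_feed=int(row["dof"]),
                **traits,
            ))
        except (pydantic.ValidationError, ValueError, DomainError) as exc:
            raise CohortValidationError(f"invalid cohort at row {idx}: {exc}") from exc
    return cohorts


def write_cohorts(cohorts: Iterable[CohortProduction], path: str | Path) -> None:
    """Write cohorts in the schema read by :func:`read_cohorts`."""
    records = []
    for c in cohorts:
        rec: dict = {"pp": c.pp.value, "diet": c.diet.name.value, "n": c.n}
        for field, pre in _TRAIT_PREFIXES.items():
            ts: TraitSummary = getattr(c, field)
            rec[f"{pre}_mean"] = ts.mean
            rec[f"{pre}_lo"] = ts.ci_low
            rec[f"{pre}_hi"] = ts.ci_high
        rec["dof"] = c.days_on_feed
        rec["diet_cost"] = c.diet.cost_per_kg
        records.append(rec)
    pd.DataFrame.from_records(records, columns=COHORT_CSV_COLUMNS).to_csv(
        path, index=False)


# --------------------------------------------------------------------------
# PP2 pooling
# --------------------------------------------------------------------------

def pool_pp2(plus: CohortProduction, minus: CohortProduction) -> CohortProduction:
    """Pool the PP 2+ and PP 2- sub-classes into the PP 2 cohort.

    Means are n-weighted; the pooled SD combines within- and between-group
    sums of squares assuming the two groups are independent samples (the raw
    per-animal data are not available), and the pooled CI is rebuilt on the
    pooled n. Total n and n-weighted trait sums are conserved exactly.
    """
    if plus.diet != minus.diet:
        raise DomainError(
            f"cannot pool across diets: {plus.diet.name.value} vs {minus.diet.name.value}")
    if plus.days_on_feed != minus.days_on_feed:
        raise DomainError("cannot pool cohorts with different days on feed")
    n1, n2 = plus.n, minus.n
    n = n1 + n2
    traits = {}
    for field in _TRAIT_PREFIXES:
        t1: TraitSummary = getattr(plus, field)
        t2: TraitSummary = getattr(minus, field)
        mean = (n1 * t1.mean + n2 * t2.mean) / n
        s1, s2 = t1.sd(n1), t2.sd(n2)
        ss = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2
              + n1 * (t1.mean - mean) ** 2 + n2 * (t2.mean - mean) ** 2)
        sd = math.sqrt(ss / (n - 1))
        traits[field] = TraitSummary.from_mean_sd(mean, sd, n)
    return CohortProduction(
        pp=PPClass.PP2, diet=plus.diet, n=n, days_on_feed=plus.days_on_feed, **traits)
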