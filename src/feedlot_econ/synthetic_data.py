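"""Synthetic pen-level feedlot trials with the study's design structure.

The generator emulates the experimental layout the economics were built on:
four production-profile classes (PP 1, PP 2+, PP 2-, PP 3) of 27 animals
each, housed per class in three solitary pens and six pens of four, pens
randomized to the three diets (three pens per diet) *after* the animals are
ranked and blocked by entry weight — and 142 days on feed. Every stage of
the pipeline (cohort summarization, grid economics, uncertainty) can then
be exercised without any external data.

Animal records are internally consistent with the entry-carcass
conversion: entry carcass weight is predicted from the drawn live weight,
and exit carcass weight = entry carcass weight + drawn carcass gain.

Entry weight is drawn per PP class (the n-weighted pool of that class's
diet cells): weight ranking and pen formation happen before diets are
assigned, so entry weight cannot depend on diet. Daily intake and carcass
gain are drawn per (PP, diet) cell, optionally jointly with a Gaussian
correlation so tests can probe the independence assumption of the
uncertainty module. PP 2+ and PP 2- share the pooled PP 2 generators with
a symmetric mean offset on gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import halfwidth_from_sd
from .carcass_model import DEFAULT_CONVERSION, CarcassConversion, entry_carcass_weight
from .errors import DomainError, SchemaError
from .production_data import (
    CohortProduction,
    DietName,
    DietSpec,
    PPClass,
    STUDY_DIETS,
    TraitSummary,
    builtin_table1,
)
from .uncertainty import TraitDistribution, sd_from_ci

__all__ = [
    "AnimalRecord",
    "CellGenerators",
    "TrialDesign",
    "design_from_table1",
    "generate_trial",
    "summarize_to_cohorts",
    "write_records",
    "read_records",
    "RECORD_CSV_COLUMNS",
]

Aggregation = Literal["mean_of_ratios", "ratio_of_means"]

#: The study layout: per PP class, three solitary pens and six pens of four.
STUDY_PEN_SIZES: tuple[int, ...] = (1, 1, 1, 4, 4, 4, 4, 4, 4)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class AnimalRecord:
    """One synthetic animal's trial outcome."""

    animal_id: str
    pp: PPClass
    diet: DietName
    pen_id: str
    entry_weight: float        # kg live, at feedlot entry
    exit_carcass_weight: float  # kg carcass, at slaughter
    total_intake: float        # kg feed over the period
    days_on_feed: int

    def __post_init__(self) -> None:
        if min(self.entry_weight, self.exit_carcass_weight, self.total_intake) <= 0:
            raise DomainError(f"animal {self.animal_id}: all quantities must be > 0")
        if self.days_on_feed <= 0:
            raise DomainError(f"animal {self.animal_id}: days_on_feed must be > 0")


@dataclass(frozen=True)
class CellGenerators:
    """Trait generators of one (PP, diet) cell."""

    daily_intake: TraitDistribution
    carcass_gain: TraitDistribution


@dataclass(frozen=True)
class TrialDesign:
    """Design of one synthetic trial.

    ``n_per_class`` animals per PP class are partitioned into
    ``pen_sizes`` pens (the sizes must sum to ``n_per_class``) and the pens
    are split evenly across ``diets``. ``intake_gain_correlation`` is the
    Gaussian correlation between an animal's intake and gain draws (0 =
    the independence the uncertainty module assumes). ``pp2_gain_offset``
    is the symmetric fractional shift splitting PP 2+ / PP 2- around the
    pooled PP 2 gain mean. ``dropout_fraction`` removes animals at random
    before slaughter (the study reports cell sizes below the allocated
    counts without describing exclusions; the default keeps everyone).
    """

    pp_classes: tuple[PPClass, ...]
    diets: tuple[DietSpec, ...]
    n_per_class: int
    pen_sizes: tuple[int, ...]
    entry_weight: Mapping[PPClass, TraitDistribution]
    cells: Mapping[tuple[PPClass, DietName], CellGenerators]
    days_on_feed: int = 142
    intake_gain_correlation: float = 0.5
    pp2_gain_offset: float = 0.03
    dropout_fraction: float = 0.0
    seed: int = 0
    conversion: CarcassConversion = field(default=DEFAULT_CONVERSION)

    def __post_init__(self) -> None:
        if sum(self.pen_sizes) != self.n_per_class:
            raise DomainError(
                f"pen sizes {self.pen_sizes} sum to {sum(self.pen_sizes)}, "
                f"not n_per_class={self.n_per_class}")
        if len(self.pen_sizes) % len(self.diets) != 0:
            raise DomainError(
                f"{len(self.pen_sizes)} pens cannot be split evenly over "
                f"{len(self.diets)} diets")
        if not -1.0 < self.intake_gain_correlation < 1.0:
            raise DomainError("intake_gain_correlation must lie in (-1, 1)")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise DomainError("dropout_fraction must lie in [0, 1)")


def design_from_table1(seed: int = 0,
                       n_per_class: int = 27,
                       pen_sizes: Sequence[int] = STUDY_PEN_SIZES,
                       intake_gain_correlation: float = 0.0,
                       pp2_gain_offset: float = 0.03,
                       dropout_fraction: float = 0.0,
                       family: str = "normal") -> TrialDesign:
    """Study-conditions design, parameterized from the built-in cohorts.

    Animal-level SDs are back-converted from the cohort CIs; PP 2+ and
    PP 2- reuse the pooled PP 2 cell generators (with the gain offset
    applied at generation time); entry weight per class pools the class's
    three diet cells with n-weights. Defaults are the study conditions:
    27 animals per class in 3x1 + 6x4 pens, 142 days on feed, independent
    intake and gain.
    """
    cohorts = {c.key: c for c in builtin_table1()}
    entry: dict[PPClass, TraitDistribution] = {}
    cells: dict[tuple[PPClass, DietName], CellGenerators] = {}
    generated = (PPClass.PP1, PPClass.PP2_PLUS, PPClass.PP2_MINUS, PPClass.PP3)
    for pp in generated:
        table_pp = PPClass.PP2 if pp in (PPClass.PP2_PLUS, PPClass.PP2_MINUS) else pp
        cls_cohorts = [cohorts[(table_pp, d)] for d in DietName]
        n_tot = sum(c.n for c in cls_cohorts)
        mean = sum(c.n * c.entry_weight.mean for c in cls_cohorts) / n_tot
        # n-weighted RMS of the per-cell animal SDs (between-cell spread in
        # entry weight reflects allocation, not the class population)
        sd = float(np.sqrt(sum(c.n * sd_from_ci(c.entry_weight, c.n) ** 2
                               for c in cls_cohorts) / n_tot))
        entry[pp] = TraitDistribution(mean=mean, sd=sd, family=family)
        for d in DietName:
            c = cohorts[(table_pp, d)]
            cells[(pp, d)] = CellGenerators(
                daily_intake=TraitDistribution(
                    mean=c.daily_intake.mean, sd=sd_from_ci(c.daily_intake, c.n),
                    family=family),
                carcass_gain=TraitDistribution(
                    mean=c.carcass_gain.mean, sd=sd_from_ci(c.carcass_gain, c.n),
                    family=family),
            )
    return TrialDesign(
        pp_classes=generated,
        diets=tuple(STUDY_DIETS[d] for d in DietName),
        n_per_class=n_per_class,
        pen_sizes=tuple(pen_sizes),
        entry_weight=entry,
        cells=cells,
        intake_gain_correlation=intake_gain_correlation,
        pp2_gain_offset=pp2_gain_offset,
        dropout_fraction=dropout_fraction,
        seed=seed,
    )


def _gain_offset_factor(design: TrialDesign, pp: PPClass) -> float:
    if pp is PPClass.PP2_PLUS:
        return 1.0 + design.pp2_gain_offset
    if pp is PPClass.PP2_MINUS:
        return 1.0 - design.pp2_gain_offset
    return 1.0


def _draw_positive(rng: np.random.Generator, dist: TraitDistribution, size: int,
                   lower: float = 0.0) -> np.ndarray:
    """Draw ``size`` values strictly above ``lower``, redrawing rejects."""
    out = dist.sample(rng, size)
    for _ in range(_MAX_REDRAWS):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = dist.sample(rng, int(bad.sum()))
    raise DomainError(f"could not draw values above {lower} from {dist}")


def _draw_intake_gain(rng: np.random.Generator, gens: CellGenerators, size: int,
                      rho: float, gain_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Jointly draw (daily intake, carcass gain) with Gaussian correlation.

    With ``rho == 0`` each trait uses its own (possibly lognormal) sampler;
    a nonzero correlation is implemented on the normal scale only.
    """
    gain_dist = replace(gens.carcass_gain, mean=gens.carcass_gain.mean * gain_factor)
    if rho == 0.0:
        return (_draw_positive(rng, gens.daily_intake, size),
                _draw_positive(rng, gain_dist, size))
    intake = np.empty(size)
    gain = np.empty(size)
    todo = np.arange(size)
    for _ in range(_MAX_REDRAWS):
        m = len(todo)
        z1 = rng.standard_normal(m)
        z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(m)
        intake[todo] = gens.daily_intake.mean + gens.daily_intake.sd * z1
        gain[todo] = gain_dist.mean + gain_dist.sd * z2
        bad = (intake[todo] <= 0) | (gain[todo] <= 0)
        todo = todo[bad]
        if len(todo) == 0:
            return intake, gain
    raise DomainError("could not draw positive intake/gain pairs")


def generate_trial(design: TrialDesign) -> list[AnimalRecord]:
    """Generate one trial: draw, rank, pen, assign diets, and feed out.

    Per PP class, entry weights are drawn for all ``n_per_class`` animals,
    animals are ranked by weight and blocked into pens of the (shuffled)
    design sizes in rank order, and pens are then assigned at random to the
    diets, evenly. Intake and gain are drawn per animal from the cell
    generators. Deterministic under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    records: list[AnimalRecord] = []
    min_entry = design.conversion.min_live_weight
    for pp in design.pp_classes:
        entries = _draw_positive(rng, design.entry_weight[pp], design.n_per_class,
                                 lower=min_entry)
        order = np.argsort(-entries)  # heaviest first
        sizes = rng.permutation(np.array(design.pen_sizes))
        pens: list[np.ndarray] = []
        start = 0
        for s in sizes:
            pens.append(order[start:start + s])
            start += s
        per_diet = len(pens) // len(design.diets)
        diet_idx = rng.permutation(np.repeat(np.arange(len(design.diets)), per_diet))
        diet_of_pen = [design.diets[i] for i in diet_idx]
        for pen_idx, (members, diet) in enumerate(zip(pens, diet_of_pen)):
            gens = design.cells[(pp, diet.name)]
            intake, gain = _draw_intake_gain(
                rng, gens, len(members), design.intake_gain_correlation,
                _gain_offset_factor(design, pp))
            keep = (rng.random(len(members)) >= design.dropout_fraction
                    if design.dropout_fraction > 0 else np.ones(len(members), bool))
            for j, animal in enumerate(members):
                if not keep[j]:
                    continue
                entry = float(entries[animal])
                records.append(AnimalRecord(
                    animal_id=f"{pp.value}-{animal + 1:03d}",
                    pp=pp,
                    diet=diet.name,
                    pen_id=f"{pp.value}-pen{pen_idx + 1:02d}",
                    entry_weight=entry,
                    exit_carcass_weight=entry_carcass_weight(entry, design.conversion)
                    + float(gain[j]),
                    total_intake=float(intake[j]) * design.days_on_feed,
                    days_on_feed=design.days_on_feed,
                ))
    return records


def _trait_summary(values: np.ndarray) -> TraitSummary:
    mean = float(np.mean(values))
    n = len(values)
    if n < 2:
        warnings.warn("cell with a single unit: CI reported as zero-width",
                      stacklevel=3)
        return TraitSummary.point(mean)
    sd = float(np.std(values, ddof=1))
    hw = halfwidth_from_sd(sd, n)
    return TraitSummary(mean=mean, ci_low=mean - hw, ci_high=mean + hw)


def summarize_to_cohorts(records: Iterable[AnimalRecord],
                         aggregation: Aggregation = "mean_of_ratios",
                         diets: Mapping[DietName, DietSpec] = STUDY_DIETS,
                         conversion: CarcassConversion = DEFAULT_CONVERSION,
                         ) -> list[CohortProduction]:
    """Aggregate animal records into per-(PP, diet) cohort summaries.

    Weights, intake and gain are summarized over animals with t-based 95%
    CIs. The ratio traits follow the chosen aggregation: ``mean_of_ratios``
    (default) computes carcass ADG and FCR per pen and averages over pens
    — the convex pen-level ratio makes this sit above the cell-total ratio
    whenever pens vary (Jensen gap) — while ``ratio_of_means`` computes
    them from cell totals and keeps the per-pen CI as the spread estimate.
    Cells of a single unit get zero-width CIs and a warning.
    """
    if aggregation not in ("mean_of_ratios", "ratio_of_means"):
        raise DomainError(f"unknown aggregation: {aggregation!r}")
    records = list(records)
    if not records:
        raise DomainError("no records to summarize")
    by_cell: dict[tuple[PPClass, DietName], list[AnimalRecord]] = {}
    for r in records:
        by_cell.setdefault((r.pp, r.diet), []).append(r)

    cohorts = []
    for (pp, diet), cell in sorted(by_cell.items(), key=lambda kv: (kv[0][0].value,
                                                                    kv[0][1].value)):
        dofs = {r.days_on_feed for r in cell}
        if len(dofs) != 1:
            raise DomainError(f"cell {pp.value}/{diet.value} mixes days on feed: {dofs}")
        dof = dofs.pop()
        entry = np.array([r.entry_weight for r in cell])
        exit_cw = np.array([r.exit_carcass_weight for r in cell])
        intake_total = np.array([r.total_intake for r in cell])
        gain = exit_cw - np.array([entry_carcass_weight(w, conversion) for w in entry])

        by_pen: dict[str, list[int]] = {}
        for i, r in enumerate(cell):
            by_pen.setdefault(r.pen_id, []).append(i)
        pen_adg, pen_fcr = [], []
        for idx in by_pen.values():
            idx = np.asarray(idx)
            pen_gain = float(gain[idx].sum())
            if pen_gain <= 0:
                raise DomainError(f"pen with non-positive total gain in {pp.value}/{diet.value}")
            pen_adg.append(pen_gain / (len(idx) * dof))
            pen_fcr.append(float(intake_total[idx].sum()) / pen_gain)
        adg_summary = _trait_summary(np.array(pen_adg))
        fcr_summary = _trait_summary(np.array(pen_fcr))
        if aggregation == "ratio_of_means":
            total_gain = float(gain.sum())
            adg_summary = _shift_to(adg_summary, total_gain / (len(cell) * dof))
            fcr_summary = _shift_to(fcr_summary, float(intake_total.sum()) / total_gain)

        cohorts.append(CohortProduction(
            pp=pp,
            diet=diets[diet],
            n=len(cell),
            entry_weight=_trait_summary(entry),
            carcass_weight=_trait_summary(exit_cw),
            carcass_adg=adg_summary,
            carcass_fcr=fcr_summary,
            daily_intake=_trait_summary(intake_total / dof),
            carcass_gain=_trait_summary(gain),
            days_on_feed=dof,
        ))
    return cohorts


def _shift_to(summary: TraitSummary, mean: float) -> TraitSummary:
    """Re-center a summary on a new point estimate, keeping its halfwidth."""
    hw = summary.halfwidth
    return TraitSummary(mean=mean, ci_low=min(mean - hw, mean), ci_high=max(mean + hw, mean))


# --------------------------------------------------------------------------
# Animal-record CSV I/O
# --------------------------------------------------------------------------

RECORD_CSV_COLUMNS = ["animal_id", "pp", "diet", "pen_id", "entry_weight",
                      "exit_carcass_weight", "total_intake", "days_on_feed"]


def write_records(records: Iterable[AnimalRecord], path: str | Path) -> None:
    pd.DataFrame.from_records(
        [{**r.__dict__, "pp": r.pp.value, "diet": r.diet.value} for r in records],
        columns=RECORD_CSV_COLUMNS,
    ).to_csv(path, index=False)


def read_records(path: str | Path) -> list[AnimalRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORD_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"record CSV {path} is missing column(s): {', '.join(missing)}")
    return [
        AnimalRecord(
            animal_id=str(row.animal_id),
            pp=PPClass.parse(str(row.pp)),
            diet=DietName(str(row.diet)),
            pen_id=str(row.pen_id),
            entry_weight=float(row.entry_weight),
            exit_carcass_weight=float(row.exit_carcass_weight),
            total_intake=float(row.total_intake),
            days_on_feed=int(row.days_on_feed),
        )
        for row in df.itertuples(index=False)
    ]
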