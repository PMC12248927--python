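"""Evaluate the PP x diet grid and derive the comparative statements.

A :class:`ScenarioTable` is the ledger of every cohort in a trial: one
A-G :class:`~feedlot_econ.econ_model.EconResult` per (production profile,
diet) cell. On top of it sit the decision questions a feedlot manager asks:
which diet is best for each PP class under a chosen metric, and how much
does switching a class's diet improve its profit margin relative to the
current norm.

Relative margin change is computed on *absolute* margins,

    100 * (|G_baseline| - |G_candidate|) / |G_baseline|,

so that a shrinking loss reads as a positive improvement exactly like a
growing gain.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .econ_model import EconResult, evaluate_cohort, financing_multiplier
from .errors import DomainError, DuplicateCellError, UndefinedRatioError
from .production_data import (
    CohortProduction,
    DietName,
    EconParams,
    PPClass,
    STUDY_DIETS,
    builtin_table1,
    builtin_table2,
)

__all__ = [
    "ScenarioTable",
    "evaluate_grid",
    "best_diet_per_pp",
    "relative_margin_change",
    "render_table2",
    "table_to_dataframe",
    "reference_scenario_table",
]

_ROW_LABELS = {
    "A": "A: Purchase cost (ZAR)",
    "B": "B: Feeding cost (ZAR)",
    "C": "C: Carcass cost per animal (ZAR)",
    "D": "D: Carcass income per animal (ZAR)",
    "E": "E: Carcass feed cost of gain (ZAR/kg carcass)",
    "F": "F: Profit/loss per animal (ZAR)",
    "G": "G: Profit margin (%)",
}

_RESULT_ROW_FIELDS = {
    "A": "purchase_cost_A",
    "B": "feed_cost_B",
    "C": "total_cost_C",
    "D": "income_D",
    "E": "cfcog_E",
    "F": "profit_F",
    "G": "margin_G",
}

#: Column display order: diets cheap-to-dear, classes low-to-high potential.
_DIET_ORDER = (DietName.LPD, DietName.MPD, DietName.HPD)
_PP_ORDER = (PPClass.PP3, PPClass.PP2_MINUS, PPClass.PP2_PLUS, PPClass.PP2, PPClass.PP1)


@dataclass(frozen=True)
class ScenarioTable:
    """One evaluated economics grid: (pp, diet) -> EconResult, plus the params."""

    cells: Mapping[tuple[PPClass, DietName], EconResult]
    params: EconParams

    def cell(self, pp: PPClass | str, diet: DietName | str) -> EconResult:
        key = (PPClass.parse(pp) if isinstance(pp, str) else pp,
               DietName(diet))
        try:
            return self.cells[key]
        except KeyError:
            raise DomainError(f"no cohort evaluated for cell {key[0].value}/{key[1].value}") from None

    def pp_classes(self) -> list[PPClass]:
        seen = {pp for pp, _ in self.cells}
        return [pp for pp in _PP_ORDER if pp in seen]

    def diets(self) -> list[DietName]:
        seen = {d for _, d in self.cells}
        return [d for d in _DIET_ORDER if d in seen]


def evaluate_grid(cohorts: Iterable[CohortProduction], params: EconParams,
                  gain_source: str = "data") -> ScenarioTable:
    """Run the A-G ledger for every cohort; (pp, diet) keys must be unique."""
    cells: dict[tuple[PPClass, DietName], EconResult] = {}
    for cohort in cohorts:
        if cohort.key in cells:
            raise DuplicateCellError(
                f"duplicate cohort for cell {cohort.pp.value}/{cohort.diet.name.value}")
        cells[cohort.key] = evaluate_cohort(cohort, params, gain_source=gain_source)
    if not cells:
        raise DomainError("no cohorts to evaluate")
    return ScenarioTable(cells=cells, params=params)


def best_diet_per_pp(table: ScenarioTable, metric: str = "profit_F"
                     ) -> dict[PPClass, DietName]:
    """Best diet for each PP class under a metric.

    ``profit_F`` and ``margin_G`` are maximized; ``cfcog_E`` (cost of gain)
    is minimized. Ties break toward the cheaper diet, then lexicographic
    diet name.
    """
    if metric not in ("profit_F", "margin_G", "cfcog_E"):
        raise DomainError(f"unknown metric: {metric!r}")
    sign = -1.0 if metric == "cfcog_E" else 1.0
    best: dict[PPClass, DietName] = {}
    for pp in table.pp_classes():
        candidates = []
        for (cpp, diet), res in table.cells.items():
            if cpp != pp:
                continue
            cost = STUDY_DIETS[diet].cost_per_kg if diet in STUDY_DIETS else 0.0
            candidates.append((-sign * getattr(res, metric), cost, diet.value, diet))
        candidates.sort()
        best[pp] = candidates[0][3]
    return best


def relative_margin_change(table: ScenarioTable, pp: PPClass | str,
                           diet_a: DietName | str, diet_b: DietName | str) -> float:
    """Relative improvement (%) of candidate diet ``a`` over baseline ``b``.

    Positive means the candidate improves the margin — a loss shrinks or a
    gain grows. Computed on unrounded absolute margins.
    """
    g_a = table.cell(pp, diet_a).margin_G
    g_b = table.cell(pp, diet_b).margin_G
    if g_b == 0:
        raise UndefinedRatioError("baseline margin is exactly zero; relative change undefined")
    return 100.0 * (abs(g_b) - abs(g_a)) / abs(g_b)


def table_to_dataframe(table: ScenarioTable) -> pd.DataFrame:
    """Rows A-G x cells, unrounded, columns labelled ``<DIET> <PP>``."""
    cols = {}
    for diet in table.diets():
        for pp in table.pp_classes():
            if (pp, diet) in table.cells:
                res = table.cells[(pp, diet)]
                cols[f"{diet.value} {pp.value}"] = [
                    getattr(res, field) for field in _RESULT_ROW_FIELDS.values()]
    return pd.DataFrame(cols, index=list(_RESULT_ROW_FIELDS))


def render_table2(table: ScenarioTable, fmt: str = "text") -> str:
    """Format the grid as the study-style A-G report.

    Currency and percentages are rounded to 2 decimals at presentation time
    only (the model never rounds internally); the minus sign is ASCII. Row B
    is financed at the displayed override rate when one is configured, which
    the footnote line records. ``fmt`` is ``text`` or ``csv``.
    """
    df = table_to_dataframe(table)
    shown = df.map(lambda v: f"{v:.2f}")
    shown.loc["G"] = df.loc["G"].map(lambda v: f"{v:.2f}%")
    shown.index = [_ROW_LABELS[r] for r in df.index]
    if fmt == "csv":
        buf = io.StringIO()
        shown.to_csv(buf, index_label="row")
        return buf.getvalue()
    if fmt != "text":
        raise DomainError(f"unknown render format: {fmt!r}")
    lines = [shown.to_string()]
    rate = table.params.feed_display_rate
    if table.params.feed_interest_rate_override is not None:
        lines.append(
            f"Note: row B financed at the displayed {100 * rate:.2f}%/yr rate; "
            f"rows C/F/G finance feed at the canonical "
            f"{100 * table.params.annual_interest_rate:.2f}%/yr.")
    return "\n".join(lines) + "\n"


def reference_scenario_table(params: EconParams | None = None) -> ScenarioTable:
    """ScenarioTable holding the *printed* reference economics.

    Cells carry the study's published A-G values rather than values
    recomputed from cohort means, so comparative statements can be made on
    the same numbers the study reports (the recomputed grid differs by the
    rounding of the printed production inputs). Break-even prices and the
    base feed cost are back-derived from the printed cells.
    """
    params = params or EconParams()
    ref = builtin_table2()
    cohorts = {c.key: c for c in builtin_table1()}
    mult_b = financing_multiplier(params.feed_display_rate, params.days_on_feed,
                                  params.day_count_basis, params.feed_financed_fraction)
    mult_p = financing_multiplier(params.annual_interest_rate, params.days_on_feed,
                                  params.day_count_basis, params.purchase_financed_fraction)
    cells = {}
    for key, cohort in cohorts.items():
        a = ref["A"][key]
        b = ref["B"][key]
        c = ref["C"][key]
        d = ref["D"][key]
        cells[key] = EconResult(
            purchase_cost_A=a,
            feed_cost_B=b,
            total_cost_C=c,
            income_D=d,
            cfcog_E=ref["E"][key],
            profit_F=ref["F"][key],
            margin_G=ref["G"][key],
            base_feed_cost=b / mult_b,
            # F = 0 when purchase price absorbs D minus the financed feed (C - A):
            breakeven_live_price=(d - (c - a)) / (cohort.entry_weight.mean * mult_p),
            breakeven_carcass_price=c / cohort.carcass_weight.mean,
        )
    return ScenarioTable(cells=cells, params=params)
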