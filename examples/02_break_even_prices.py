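"""Break-even purchase and sale prices per cohort.

For each cohort the ledger is inverted in closed form: the live purchase
price (ZAR/kg) and the carcass sale price (ZAR/kg) at which profit is
exactly zero, everything else held at study conditions. A break-even live
price above the market's 33.25 means the cohort could have been bought
dearer and still broken even; below means it was overpaid. The calf:beef
price ratio (market guideline: below ~55%) is printed for context.
"""

from feedlot_econ import (
    EconParams,
    builtin_table1,
    calf_beef_price_ratio,
    evaluate_cohort,
)

params = EconParams()
print(f"Market prices: live {params.live_price:.2f}, carcass "
      f"{params.carcass_price:.2f} ZAR/kg -> calf:beef ratio "
      f"{calf_beef_price_ratio(params.live_price, params.carcass_price):.1f}%"
      " (guideline: < 55%)\n")

print(f"{'cohort':<10}{'breakeven live':>16}{'breakeven carcass':>19}{'profit':>12}")
for cohort in builtin_table1():
    res = evaluate_cohort(cohort, params)
    print(f"{cohort.pp.value}/{cohort.diet.name.value:<6}"
          f"{res.breakeven_live_price:>16.2f}"
          f"{res.breakeven_carcass_price:>19.2f}"
          f"{res.profit_F:>12.2f}")
print("\nLoss-making cohorts (negative profit) have a break-even live price")
print("below 33.25 ZAR/kg: they only pay off if procured cheaper.")
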