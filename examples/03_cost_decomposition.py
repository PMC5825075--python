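"""DRG variable/fixed cost split and excess-cost attribution for one DRG.

Only subcategories that scale with days in hospital (ward nursing, pharmacy,
hotel, ...) are 'variable'; one-off theatre/ED/prosthesis costs are 'fixed'
and never enter the per-day rate.  Episodes staying strictly longer than the
DRG's average overnight LOS are costed extra_days x daily variable cost.
"""

import pandas as pd

from excesscost.cost import ALL_SUBCATEGORIES, add_cost_totals, excess_cost, select_above_average

ref = pd.DataFrame([{"drg": "D1", "avg_overnight_los": 5.0, "cost_weight": 1.3,
                     **{k: 0.0 for k in ALL_SUBCATEGORIES},
                     "ward nursing": 3200.0, "pharmacy": 800.0, "hotel": 1000.0,
                     "operating rooms": 2500.0}])
ref = add_cost_totals(ref)
row = ref.iloc[0]
print(f"variable total ${row['variable_total']:,.0f}, fixed total ${row['fixed_total']:,.0f}")
print(f"daily variable cost ${row['daily_variable_cost']:,.0f}/day "
      f"(variable total / {row['avg_overnight_los']:.0f}-day average stay)")

episodes = pd.DataFrame(
    {
        "episode_id": ["E1", "E2", "E3"],
        "drg": ["D1"] * 3,
        "los_days": [8, 5, 3],
    }
)
records = excess_cost(episodes, ref)
print(records[["episode_id", "extra_days", "extra_cost", "above_average"]].to_string(index=False))
print(f"regression sample: {len(select_above_average(records))} of {len(records)} episodes")
# E1 stayed 3 days beyond the average: 3 x $1,000 = $3,000 extra.  E2 equals
# the average (not 'longer than') and E3 is below; both cost $0 extra and
# are excluded from the regression sample.
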