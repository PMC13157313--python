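"""Aggregate the reference survey's monthly sales into consumption tables.

Sales are converted to grams of active ingredient and grouped by drug
and by route of administration; shares are percentages of the category
total over a 26-trading-day month.
"""

from vetamu import Category, build_consumption_table
from vetamu.reference import PERIOD_DAYS, reference_sales_estimates

ests = reference_sales_estimates()
anth = [e for e in ests if e.category is Category.ANTHELMINTIC]
ab = [e for e in ests if e.category is Category.ANTIBIOTIC]

by_drug = build_consumption_table(anth, ("drug",), PERIOD_DAYS)
print("anthelmintics by drug (g/month and % share):")
print(by_drug.frame.round(2).to_string())
print(
    f"\nalbendazole alone is {by_drug.share('albendazole'):.1f}% of the "
    f"{by_drug.total_grams:,.0f} g anthelmintic month "
    f"({by_drug.daily_total_g:,.0f} g/day)."
)

by_route = build_consumption_table(ab, ("route",), PERIOD_DAYS)
print("\nantibiotics by route:")
print(by_route.frame.round(2).to_string())
print(
    f"\ninjectables carry {by_route.share('injection'):.1f}% of antibiotic "
    "mass; orals are dominated by poultry-targeted powders."
)
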