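"""Estimate units sold from repeated stock counts at one outlet.

Sales over the audit window are opening stock minus closing stock,
corrected for recorded additions and disposals — a telescoping sum, so
the visit spacing does not matter as long as corrections are logged.
"""

import datetime

from vetamu import AuditVisit, estimate_units_sold

d = datetime.date(2024, 3, 1)
visits = [
    AuditVisit("outlet_C", "oxytet-250", d, stock_units=100),
    AuditVisit(
        "outlet_C",
        "oxytet-250",
        d + datetime.timedelta(days=3),
        stock_units=55,
        additions_since_last=0,
    ),
    AuditVisit(
        "outlet_C",
        "oxytet-250",
        d + datetime.timedelta(days=7),
        stock_units=40,
        additions_since_last=20,
        disposals_since_last=5,
    ),
]

units = estimate_units_sold(visits)
print(f"stock 100 -> 55 -> 40, with 20 packs restocked and 5 disposed")
print(f"estimated packs sold over the week: {units:.0f}")
print(
    "i.e. 100 - 40 + 20 - 5 = 75; the intermediate visit adds information "
    "about timing but does not change the total."
)
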