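"""Run the whole pipeline on the bundled reference survey.

Equivalent to `vetamu reference --out-dir in && vetamu report --config
run.yaml`; writes compliance, origin, consumption, biomass and AMU
reports and prints the headline numbers.
"""

import tempfile
from pathlib import Path

from vetamu import RunConfig, run_pipeline
from vetamu.reference import PERIOD_DAYS, write_reference_bundle

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    bundle = write_reference_bundle(tmp / "in")
    report = run_pipeline(
        RunConfig(
            products_csv=bundle / "products.csv",
            visits_csv=bundle / "visits.csv",
            inspections_csv=bundle / "inspections.csv",
            census_yaml=bundle / "census.yaml",
            conversions_yaml=bundle / "conversions.yaml",
            out_dir=tmp / "out",
            period_days=PERIOD_DAYS,
        )
    )

amu = report["amu"]
comp = report["compliance"]
print(f"samples inspected: {comp['n_samples']}, "
      f"noncompliant: {comp['noncompliance_pct']:.0f}%")
print(f"daily antibiotic mass:   {amu['daily_g_by_category']['antibiotic']:8.1f} g")
print(f"daily anthelmintic mass: {amu['daily_g_by_category']['anthelmintic']:8.1f} g")
print(f"PCU denominator:         {amu['pcu_kg']:,.0f} kg")
print(f"daily mg per PCU:        {amu['daily_mg_per_pcu']:.3f} mg/kg")
print(
    "\nThe mg/PCU figure normalizes consumption by the biomass at risk of "
    "treatment, making it comparable across regions with different herds."
)
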