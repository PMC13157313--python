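"""Compute livestock biomass, the PCU denominator, and mg/PCU.

Species formulas: cattle herd uses an age-class-weighted mean weight;
sheep/goats add slaughter throughput to retained breeding stock
(census - slaughtered/1.5 cycles, at 75 kg); poultry count 1 kg per
mature bird.  The published surveillance denominator (a wider national
extrapolation) is carried as a constant for the normalized metric.
"""

from vetamu import amu_per_pcu, total_pcu
from vetamu.reference import (
    DAILY_ANTIBIOTIC_G,
    TOTAL_PCU_KG,
    reference_census,
)

inputs, pcu_constant = reference_census()
result = total_pcu(inputs)

print("local census biomass (kg):")
for sp, kg in sorted(result.per_species_kg.items(), key=lambda kv: -kv[1]):
    print(f"  {sp.value:<8} {kg:>12,.0f}  ({result.shares_pct[sp]:5.2f}%)")
print(f"  total    {result.total_pcu_kg:>12,.0f}")

mg_per_pcu = amu_per_pcu(DAILY_ANTIBIOTIC_G * 1000.0, pcu_constant)
print(
    f"\ndaily antibiotic mass {DAILY_ANTIBIOTIC_G:,.0f} g over the "
    f"surveillance denominator {TOTAL_PCU_KG:,.0f} kg"
)
print(f"=> {mg_per_pcu:.3f} mg of active ingredient per kg of biomass")
print(
    "Cattle dominate biomass despite poultry dominating head counts, "
    "which is why the denominator choice matters for route-restricted "
    "metrics."
)
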