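"""Score the bundled 44-sample survey against the visual-inspection checklist.

A sample is compliant only if it passes every packaging, labelling and
physical criterion; per-criterion failure counts are column sums.
"""

from vetamu import Category, compliance_summary
from vetamu.reference import reference_inspection_samples

summary = compliance_summary(reference_inspection_samples())

print(summary.to_frame().round(1).to_string())
ab = summary.by_category[Category.ANTIBIOTIC]
print(
    f"\n{ab.n_noncompliant}/{ab.n_samples} antibiotic samples "
    f"({ab.noncompliance_pct:.0f}%) fail at least one criterion; "
    f"overall noncompliance {summary.noncompliance_pct:.0f}% of "
    f"{summary.n_samples} samples."
)
print(
    "The worst criterion is the missing dose statement "
    f"({summary.failure_pct('api_dose_stated'):.1f}% of all samples)."
)
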