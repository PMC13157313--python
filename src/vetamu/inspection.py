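"""Visual-inspection checklist scoring and compliance summaries.

Desk-level medicine quality screening: each sample is checked against a
fixed checklist of packaging/labelling criteria (active-ingredient name
on the pack, leaflet present, dose stated, expiry date, manufacturer
name and address, batch number) and physical criteria (shape, colour,
size, breaks/cracks, contamination).  A sample is *compliant* only if it
passes every criterion; a single failure makes it noncompliant.

Summaries report per-criterion failure counts (column sums over
samples), the number of noncompliant samples, and percentages both
within each therapeutic category and over the full sample set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import Category
from .errors import ConfigError

__all__ = [
    "PACKAGING_CRITERIA",
    "PHYSICAL_CRITERIA",
    "ALL_CRITERIA",
    "InspectionSample",
    "ScoreResult",
    "CategoryCompliance",
    "ComplianceSummary",
    "score_sample",
    "compliance_summary",
    "read_inspections_csv",
    "write_inspections_csv",
]

#: Labelling/traceability criteria recorded on the external packaging.
PACKAGING_CRITERIA: tuple[str, ...] = (
    "api_name_on_pack",
    "leaflet_present",
    "api_dose_stated",
    "expiry_date_stated",
    "manufacturer_name_address",
    "batch_number",
)

#: Physical product characteristics.
PHYSICAL_CRITERIA: tuple[str, ...] = (
    "shape",
    "color",
    "size",
    "breaks_cracks",
    "contamination",
)

ALL_CRITERIA: tuple[str, ...] = PACKAGING_CRITERIA + PHYSICAL_CRITERIA


@dataclass(frozen=True)
class InspectionSample:
    """Pass/fail vector for one sampled product.

    ``criteria`` maps criterion id -> True (pass) / False (fail) and must
    cover the full criterion set; physical criteria omitted at
    construction default to pass, since surveys that record only
    packaging criteria implicitly found no physical defects.
    """

    sample_id: str
    category: Category
    criteria: Mapping[str, bool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        crit = dict(self.criteria)
        unknown = set(crit) - set(ALL_CRITERIA)
        if unknown:
            raise ConfigError(
                f"{self.sample_id}: unknown criteria {sorted(unknown)}"
            )
        missing = set(PACKAGING_CRITERIA) - set(crit)
        if missing:
            raise ConfigError(
                f"{self.sample_id}: missing packaging criteria {sorted(missing)}"
            )
        for c in PHYSICAL_CRITERIA:
            crit.setdefault(c, True)
        object.__setattr__(self, "criteria", crit)


@dataclass(frozen=True)
class ScoreResult:
    failures: frozenset[str]
    compliant: bool


def score_sample(sample: InspectionSample) -> ScoreResult:
    """Score one sample: compliant iff it fails no criterion."""
    failures = frozenset(c for c, ok in sample.criteria.items() if not ok)
    return ScoreResult(failures=failures, compliant=not failures)


@dataclass(frozen=True)
class CategoryCompliance:
    """Compliance statistics for one therapeutic category."""

    n_samples: int
    failure_counts: dict[str, int]
    n_noncompliant: int

    @property
    def noncompliance_pct(self) -> float:
        return 100.0 * self.n_noncompliant / self.n_samples


@dataclass(frozen=True)
class ComplianceSummary:
    """Checklist summary over a sample set, stratified by category.

    Percentage rows use the full ``n_samples`` denominator; per-category
    noncompliance uses that category's sample count.
    """

    n_samples: int
    by_category: dict[Category, CategoryCompliance]
    failure_counts: dict[str, int] = field(default_factory=dict)
    n_noncompliant: int = 0

    @property
    def noncompliance_pct(self) -> float:
        return 100.0 * self.n_noncompliant / self.n_samples

    def failure_pct(self, criterion: str) -> float:
        return 100.0 * self.failure_counts[criterion] / self.n_samples

    def to_frame(self) -> pd.DataFrame:
        """Summary table: one row per category plus overall count/% rows."""
        cols = list(ALL_CRITERIA)
        rows = {}
        for cat, cc in self.by_category.items():
            rows[f"{cat.value} (n={cc.n_samples})"] = {
                "total_noncompliant": cc.n_noncompliant,
                **{c: cc.failure_counts[c] for c in cols},
            }
        rows["overall noncompliance"] = {
            "total_noncompliant": self.n_noncompliant,
            **{c: self.failure_counts[c] for c in cols},
        }
        rows["overall percentage"] = {
            "total_noncompliant": self.noncompliance_pct,
            **{c: self.failure_pct(c) for c in cols},
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_noncompliant": self.n_noncompliant,
            "noncompliance_pct": self.noncompliance_pct,
            "failure_counts": dict(self.failure_counts),
            "failure_pct": {c: self.failure_pct(c) for c in ALL_CRITERIA},
            "by_category": {
                cat.value: {
                    "n_samples": cc.n_samples,
                    "n_noncompliant": cc.n_noncompliant,
                    "noncompliance_pct": cc.noncompliance_pct,
                    "failure_counts": dict(cc.failure_counts),
                }
                for cat, cc in self.by_category.items()
            },
        }


def compliance_summary(samples: Sequence[InspectionSample]) -> ComplianceSummary:
    """Summarize checklist results over a non-empty sample list.

    Failure counts are column sums; the noncompliant count is the number
    of samples with at least one failure (so it is always >= the largest
    single-criterion count and <= the sum of counts).
    """
    if not samples:
        raise ConfigError("compliance_summary requires a non-empty sample list")
    by_cat: dict[Category, list[InspectionSample]] = {}
    for s in samples:
        by_cat.setdefault(s.category, []).append(s)

    def _stats(group: Sequence[InspectionSample]) -> CategoryCompliance:
        counts = {c: 0 for c in ALL_CRITERIA}
        n_bad = 0
        for s in group:
            res = score_sample(s)
            if not res.compliant:
                n_bad += 1
            for c in res.failures:
                counts[c] += 1
        return CategoryCompliance(
            n_samples=len(group), failure_counts=counts, n_noncompliant=n_bad
        )

    per_cat = {cat: _stats(group) for cat, group in by_cat.items()}
    total_counts = {
        c: sum(cc.failure_counts[c] for cc in per_cat.values()) for c in ALL_CRITERIA
    }
    return ComplianceSummary(
        n_samples=len(samples),
        by_category=per_cat,
        failure_counts=total_counts,
        n_noncompliant=sum(cc.n_noncompliant for cc in per_cat.values()),
    )


def write_inspections_csv(
    samples: Iterable[InspectionSample], path: str | Path
) -> None:
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "category": s.category.value}
        for c in ALL_CRITERIA:
            row[c] = "pass" if s.criteria[c] else "fail"
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", "category", *ALL_CRITERIA]).to_csv(
        path, index=False
    )


def read_inspections_csv(path: str | Path) -> list[InspectionSample]:
    """Read ``inspections.csv``; physical-criteria columns may be absent."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "category", *PACKAGING_CRITERIA}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    crit_cols = [c for c in ALL_CRITERIA if c in df.columns]
    out = []
    for row in df.to_dict("records"):
        criteria = {}
        for c in crit_cols:
            val = row[c].strip().lower()
            if val not in ("pass", "fail"):
                raise ConfigError(
                    f"{path}: sample {row['sample_id']}: criterion {c} must be "
                    f"pass/fail, got {row[c]!r}"
                )
            criteria[c] = val == "pass"
        out.append(
            InspectionSample(
                sample_id=row["sample_id"],
                category=Category(row["category"]),
                criteria=criteria,
            )
        )
    return out
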