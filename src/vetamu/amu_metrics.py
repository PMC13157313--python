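"""Consumption metrics: nDDDvet, mg per PCU, category splits, origins.

Two normalized metrics are computed from total active-ingredient mass:

* ``nDDDvet`` — number of defined daily doses for animals, i.e. total
  active substance (mg) divided by the DDDvet (mg), the assumed average
  maintenance dose for the drug's main indication and route;
* ``mg per PCU`` — total active substance (mg) divided by total animal
  biomass (kg), the headline biomass-normalized consumption figure.

Route-restricted mg/PCU (e.g. oral products over a poultry-only
biomass) takes a caller-chosen numerator subset and biomass subset; no
route-to-species pairing is hard-coded, because which species plausibly
consumed a route is a study-specific judgement.

Internal values are kept at full precision; rounding to a printed
precision belongs to the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .catalog import Category, ProductRecord
from .errors import ConfigError

__all__ = [
    "n_dddvet",
    "amu_per_pcu",
    "category_split",
    "origin_summary",
    "OriginSummary",
    "AMUReport",
    "build_amu_report",
]


def n_dddvet(total_active_mg: float, dddvet_mg: float) -> float:
    """Number of defined daily doses: total mg used / DDDvet mg.

    Returned unrounded; a fractional number of doses is meaningful.
    """
    if dddvet_mg <= 0:
        raise ConfigError(f"DDDvet must be > 0 mg, got {dddvet_mg}")
    if total_active_mg < 0:
        raise ConfigError("total_active_mg must be >= 0")
    return total_active_mg / dddvet_mg


def amu_per_pcu(total_antimicrobial_mg: float, pcu_kg: float) -> float:
    """Antimicrobial use per population correction unit, mg per kg biomass."""
    if pcu_kg <= 0:
        raise ConfigError(f"pcu_kg must be > 0, got {pcu_kg}")
    if total_antimicrobial_mg < 0:
        raise ConfigError("total_antimicrobial_mg must be >= 0")
    return total_antimicrobial_mg / pcu_kg


def category_split(masses: Mapping[str, float]) -> dict[str, float]:
    """Percentage share per key of a mass breakdown (e.g. daily grams).

    share = value / sum x 100, unrounded; at least one value must be
    positive.
    """
    if not masses:
        raise ConfigError("category_split requires at least one entry")
    if any(v < 0 for v in masses.values()):
        raise ConfigError("masses must be >= 0")
    total = sum(masses.values())
    if total <= 0:
        raise ConfigError("at least one mass must be positive")
    return {k: 100.0 * v / total for k, v in masses.items()}


@dataclass(frozen=True)
class OriginSummary:
    """Sample counts by country of origin, overall and per category."""

    counts: dict[tuple[str, Category], int]
    n_products: int

    def country_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (country, _), n in self.counts.items():
            out[country] = out.get(country, 0) + n
        return out

    def country_pct(self) -> dict[str, float]:
        return {
            c: 100.0 * n / self.n_products for c, n in self.country_counts().items()
        }

    def category_total(self, category: Category) -> int:
        return sum(
            n for (_, cat), n in self.counts.items() if cat is Category(category)
        )

    def to_dict(self) -> dict:
        return {
            "n_products": self.n_products,
            "counts": [
                {"country": c, "category": cat.value, "n": n}
                for (c, cat), n in sorted(
                    self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
                )
            ],
            "country_pct": self.country_pct(),
        }


def origin_summary(catalog: Sequence[ProductRecord]) -> OriginSummary:
    """Count products per (origin country, category), one count per
    distinct product_id (combination products count once)."""
    if not catalog:
        raise ConfigError("origin_summary requires a non-empty catalog")
    seen: dict[str, tuple[str, Category]] = {}
    for p in catalog:
        key = (p.origin_country, p.category)
        if p.product_id in seen and seen[p.product_id] != key:
            raise ConfigError(
                f"product {p.product_id!r} has inconsistent origin/category"
            )
        seen[p.product_id] = key
    counts: dict[tuple[str, Category], int] = {}
    for key in seen.values():
        counts[key] = counts.get(key, 0) + 1
    return OriginSummary(counts=counts, n_products=len(seen))


@dataclass(frozen=True)
class AMUReport:
    """Aggregated consumption report for one reporting period.

    Masses are totals over the period (mg); ``daily_g`` divides by
    ``period_days``; ``mg_per_pcu`` is the exact ratio of total
    antimicrobial mass to ``pcu_kg``.  Subset metrics (per route, per
    category) use the corresponding numerator over a caller-chosen
    biomass.
    """

    period_days: float
    total_mg_by_category: dict[str, float]
    total_mg_by_route: dict[str, float]
    pcu_kg: float
    mg_per_pcu: float
    daily_mg_per_pcu: float = 0.0
    daily_g_by_category: dict[str, float] = field(default_factory=dict)
    category_shares_pct: dict[str, float] = field(default_factory=dict)
    mg_per_pcu_by_route: dict[str, float] = field(default_factory=dict)
    n_dddvet_by_drug: dict[str, float] = field(default_factory=dict)
    origin: OriginSummary | None = None

    def to_dict(self) -> dict:
        return {
            "period_days": self.period_days,
            "total_mg_by_category": dict(self.total_mg_by_category),
            "total_mg_by_route": dict(self.total_mg_by_route),
            "daily_g_by_category": dict(self.daily_g_by_category),
            "category_shares_pct": dict(self.category_shares_pct),
            "pcu_kg": self.pcu_kg,
            "mg_per_pcu": self.mg_per_pcu,
            "daily_mg_per_pcu": self.daily_mg_per_pcu,
            "mg_per_pcu_by_route": dict(self.mg_per_pcu_by_route),
            "n_dddvet_by_drug": dict(self.n_dddvet_by_drug),
            "origin": self.origin.to_dict() if self.origin else None,
        }


def build_amu_report(
    total_mg_by_category: Mapping[str, float],
    total_mg_by_route: Mapping[str, float],
    pcu_kg: float,
    period_days: float,
    antimicrobial_categories: Sequence[str] = ("antibiotic",),
    dddvet_totals: Mapping[str, tuple[float, float]] | None = None,
    route_biomass_kg: Mapping[str, float] | None = None,
    origin: OriginSummary | None = None,
) -> AMUReport:
    """Assemble an :class:`AMUReport`.

    ``mg_per_pcu`` uses the summed mass of ``antimicrobial_categories``
    (by surveillance convention the antibiotic mass, anthelmintics being
    reported separately); ``daily_mg_per_pcu`` normalizes the average
    daily mass instead, the convention used when consumption is quoted
    as a daily figure.  ``dddvet_totals`` maps drug -> (total mg,
    DDDvet mg); ``route_biomass_kg`` maps route -> biomass denominator
    for route-restricted mg/PCU (computed on the daily route mass).
    """
    if period_days <= 0:
        raise ConfigError("period_days must be > 0")
    missing = [c for c in antimicrobial_categories if c not in total_mg_by_category]
    if missing:
        raise ConfigError(f"categories {missing} absent from totals")
    numerator_mg = sum(total_mg_by_category[c] for c in antimicrobial_categories)
    daily_g = {
        c: mg / 1000.0 / period_days for c, mg in total_mg_by_category.items()
    }
    return AMUReport(
        period_days=float(period_days),
        total_mg_by_category=dict(total_mg_by_category),
        total_mg_by_route=dict(total_mg_by_route),
        pcu_kg=float(pcu_kg),
        mg_per_pcu=amu_per_pcu(numerator_mg, pcu_kg),
        daily_mg_per_pcu=amu_per_pcu(numerator_mg / period_days, pcu_kg),
        daily_g_by_category=daily_g,
        category_shares_pct=category_split(total_mg_by_category),
        mg_per_pcu_by_route={
            r: amu_per_pcu(total_mg_by_route.get(r, 0.0) / period_days, b)
            for r, b in (route_biomass_kg or {}).items()
        },
        n_dddvet_by_drug={
            d: n_dddvet(mg, ddd) for d, (mg, ddd) in (dddvet_totals or {}).items()
        },
        origin=origin,
    )
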