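"""Retail-audit sales estimation and consumption aggregation.

Sales at an outlet are estimated from repeated stock counts: units sold
over the audit period equal opening stock minus closing stock, corrected
for any stock added or disposed of between visits (a telescoping sum, so
the estimate is independent of the visit schedule when additions and
disposals are fully logged).  Unit sales are converted to grams of
active ingredient through the product catalog and aggregated into
consumption tables by drug, class, route of administration, or outlet.

A negative estimate (stock grew by more than recorded additions explain)
indicates under-reported additions or over-counted stock; it is retained
and flagged rather than clipped, because reporting error is a real
feature of field audit data.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import Category, ConversionTable, ProductRecord, Route, api_mass_per_pack
from .errors import AuditError, ConfigError

__all__ = [
    "AuditVisit",
    "SalesEstimate",
    "ConsumptionTable",
    "estimate_units_sold",
    "sales_to_api_grams",
    "make_sales_estimates",
    "build_consumption_table",
    "read_visits_csv",
    "write_visits_csv",
    "DEFAULT_PERIOD_DAYS",
]

logger = logging.getLogger(__name__)

#: Default reporting-period length in days used to derive daily figures
#: from a monthly consumption table (a trading month of ~26 days).
DEFAULT_PERIOD_DAYS: float = 26.0


@dataclass(frozen=True)
class AuditVisit:
    """One stock observation for an outlet-product.

    ``additions_since_last`` / ``disposals_since_last`` cover the
    interval since the previous visit and must be 0 on the first visit.
    """

    outlet_id: str
    product_id: str
    visit_date: datetime.date
    stock_units: int
    additions_since_last: int = 0
    disposals_since_last: int = 0

    def __post_init__(self) -> None:
        if self.stock_units < 0:
            raise AuditError(f"stock_units must be >= 0, got {self.stock_units}")
        if self.additions_since_last < 0 or self.disposals_since_last < 0:
            raise AuditError("additions/disposals must be >= 0")


@dataclass(frozen=True)
class SalesEstimate:
    """Estimated sales for one outlet-product(-route) over one period.

    ``route`` lives on the estimate, not the product, so a product sold
    by several routes contributes separately to each route row.
    """

    outlet_id: str
    product_id: str
    period_start: datetime.date
    period_end: datetime.date
    units_sold: float
    api_grams: float
    route: Route
    drug_label: str
    drug_class: str
    category: Category

    @property
    def negative_flag(self) -> bool:
        """True when the audit implies negative sales (reporting error)."""
        return self.units_sold < 0


def estimate_units_sold(visits: Sequence[AuditVisit]) -> float:
    """Units sold between the first and last visit of an audit series.

    ``first_stock - last_stock + sum(additions) - sum(disposals)``.
    Requires >= 2 visits for a single outlet-product in strictly
    increasing date order.  A negative result is returned as-is (and
    logged); the caller decides how to treat it.
    """
    if len(visits) < 2:
        raise AuditError("need at least 2 visits to estimate sales")
    keys = {(v.outlet_id, v.product_id) for v in visits}
    if len(keys) != 1:
        raise AuditError(f"visits mix outlet-products: {sorted(keys)}")
    dates = [v.visit_date for v in visits]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise AuditError("visit dates must be strictly increasing")
    additions = sum(v.additions_since_last for v in visits[1:])
    disposals = sum(v.disposals_since_last for v in visits[1:])
    units = visits[0].stock_units - visits[-1].stock_units + additions - disposals
    if units < 0:
        outlet, product = next(iter(keys))
        logger.warning(
            "negative estimated sales (%s) for outlet %s product %s; "
            "additions likely under-reported",
            units,
            outlet,
            product,
        )
    return float(units)


def sales_to_api_grams(
    units_sold: float, product: ProductRecord, table: ConversionTable
) -> float:
    """Grams of active ingredient in ``units_sold`` retail packs."""
    if units_sold < 0:
        raise AuditError(f"units_sold must be >= 0, got {units_sold}")
    return units_sold * api_mass_per_pack(product, table)


def make_sales_estimates(
    visits: Iterable[AuditVisit],
    catalog: Mapping[str, Sequence[ProductRecord]],
    table: ConversionTable,
    route_of_sale: Mapping[str, Route] | None = None,
) -> list[SalesEstimate]:
    """Estimate sales for every outlet-product series in ``visits``.

    ``catalog`` maps product_id to its records (several for combination
    products; each contributes its own active-ingredient mass).
    ``route_of_sale`` optionally overrides the route attributed to a
    product's sales; otherwise single-route products use their route and
    multi-route products raise, since the split cannot be inferred from
    stock counts alone.
    """
    series: dict[tuple[str, str], list[AuditVisit]] = {}
    for v in visits:
        series.setdefault((v.outlet_id, v.product_id), []).append(v)
    out: list[SalesEstimate] = []
    for (outlet_id, product_id), vs in sorted(series.items()):
        vs = sorted(vs, key=lambda v: v.visit_date)
        units = estimate_units_sold(vs)
        try:
            records = catalog[product_id]
        except KeyError:
            raise ConfigError(f"product {product_id!r} not in catalog") from None
        for product in records:
            if route_of_sale and product_id in route_of_sale:
                route = route_of_sale[product_id]
            elif len(product.routes) == 1:
                route = next(iter(product.routes))
            else:
                raise ConfigError(
                    f"product {product_id!r} has several routes; supply "
                    "route_of_sale to attribute its sales"
                )
            # negative units propagate a signed mass so the flag is visible
            grams = units * api_mass_per_pack(product, table)
            out.append(
                SalesEstimate(
                    outlet_id=outlet_id,
                    product_id=product_id,
                    period_start=vs[0].visit_date,
                    period_end=vs[-1].visit_date,
                    units_sold=units,
                    api_grams=grams,
                    route=route,
                    drug_label=product.display_label,
                    drug_class=product.drug_class,
                    category=product.category,
                )
            )
    return out


_GROUP_FIELDS = {
    "drug": "drug_label",
    "class": "drug_class",
    "route": "route",
    "outlet": "outlet_id",
    "category": "category",
}


@dataclass(frozen=True)
class ConsumptionTable:
    """Aggregated consumption in grams over one reporting period.

    ``frame`` is indexed by the grouping dimensions with columns
    ``grams``, ``pct_share`` and ``daily_g``.  The total and the shares
    are exact before any display rounding; shares per table sum to 100.
    """

    frame: pd.DataFrame
    group_by: tuple[str, ...]
    period_days: float
    total_grams: float

    @property
    def daily_total_g(self) -> float:
        return self.total_grams / self.period_days

    def share(self, *key) -> float:
        """Percentage share of one group (key in group_by order)."""
        k = key[0] if len(key) == 1 else tuple(key)
        return float(self.frame.loc[k, "pct_share"])

    def grams(self, *key) -> float:
        k = key[0] if len(key) == 1 else tuple(key)
        return float(self.frame.loc[k, "grams"])

    def to_dict(self) -> dict:
        records = []
        for key, row in self.frame.iterrows():
            key_tuple = key if isinstance(key, tuple) else (key,)
            rec = dict(zip(self.group_by, [str(k) for k in key_tuple]))
            rec.update(
                grams=float(row["grams"]),
                pct_share=float(row["pct_share"]),
                daily_g=float(row["daily_g"]),
            )
            records.append(rec)
        return {
            "group_by": list(self.group_by),
            "period_days": self.period_days,
            "total_grams": self.total_grams,
            "daily_total_g": self.daily_total_g,
            "rows": records,
        }


def build_consumption_table(
    estimates: Sequence[SalesEstimate],
    group_by: Sequence[str] = ("class", "drug"),
    period_days: float = DEFAULT_PERIOD_DAYS,
) -> ConsumptionTable:
    """Aggregate sales estimates into a consumption table.

    Grams are summed per group; each group's percentage share is
    group/total x 100; ``daily_g`` divides by ``period_days``.  The
    grand total is invariant to the grouping chosen.
    """
    if period_days <= 0:
        raise ConfigError(f"period_days must be > 0, got {period_days}")
    if not estimates:
        raise ConfigError("no sales estimates to aggregate")
    unknown = [g for g in group_by if g not in _GROUP_FIELDS]
    if unknown:
        raise ConfigError(
            f"unknown group_by dimensions {unknown}; "
            f"choose from {sorted(_GROUP_FIELDS)}"
        )
    rows = []
    for e in estimates:
        rec = {dim: getattr(e, _GROUP_FIELDS[dim]) for dim in group_by}
        for dim in group_by:
            if isinstance(rec[dim], (Route, Category)):
                rec[dim] = rec[dim].value
        rec["grams"] = e.api_grams
        rows.append(rec)
    df = pd.DataFrame(rows)
    grouped = df.groupby(list(group_by), sort=True)["grams"].sum().to_frame()
    total = float(grouped["grams"].sum())
    if total != 0:
        grouped["pct_share"] = 100.0 * grouped["grams"] / total
    else:
        grouped["pct_share"] = 0.0
    grouped["daily_g"] = grouped["grams"] / period_days
    return ConsumptionTable(
        frame=grouped,
        group_by=tuple(group_by),
        period_days=float(period_days),
        total_grams=total,
    )


_VISIT_COLUMNS = [
    "outlet_id",
    "product_id",
    "visit_date",
    "stock_units",
    "additions_since_last",
    "disposals_since_last",
]


def write_visits_csv(visits: Iterable[AuditVisit], path) -> None:
    rows = [
        {
            "outlet_id": v.outlet_id,
            "product_id": v.product_id,
            "visit_date": v.visit_date.isoformat(),
            "stock_units": v.stock_units,
            "additions_since_last": v.additions_since_last,
            "disposals_since_last": v.disposals_since_last,
        }
        for v in visits
    ]
    pd.DataFrame(rows, columns=_VISIT_COLUMNS).to_csv(path, index=False)


def read_visits_csv(path) -> list[AuditVisit]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ConfigError(f"{path}: no audit visits")
    return [
        AuditVisit(
            outlet_id=r.outlet_id,
            product_id=r.product_id,
            visit_date=datetime.date.fromisoformat(r.visit_date),
            stock_units=int(r.stock_units),
            additions_since_last=int(r.additions_since_last),
            disposals_since_last=int(r.disposals_since_last),
        )
        for r in df.itertuples(index=False)
    ]
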