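"""Product catalog: data model, strength parsing, and mass conversions.

A marketed veterinary medicine is described by a :class:`ProductRecord`;
combination products (e.g. a penicillin-streptomycin injectable) are one
record per active ingredient sharing a ``product_id``, so masses can be
aggregated per ingredient or per combination display label.

Strengths declared in international units (IU) are converted to
milligrams through a configured :class:`ConversionTable`; IU-per-mg
factors are substance-specific standards (e.g. benzylpenicillin sodium:
1 IU = 0.0006 mg) and are configuration, never guessed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigError, UnitError, UnknownSubstanceError

__all__ = [
    "Category",
    "StrengthUnit",
    "Route",
    "ProductRecord",
    "ConversionTable",
    "DEFAULT_CLASS_CATEGORIES",
    "DEFAULT_IU_FACTORS",
    "iu_to_mg",
    "api_mass_per_pack",
    "read_products_csv",
    "write_products_csv",
]


class Category(str, enum.Enum):
    ANTIBIOTIC = "antibiotic"
    ANTHELMINTIC = "anthelmintic"


class StrengthUnit(str, enum.Enum):
    MG = "mg"
    G = "g"
    IU = "IU"
    PERCENT_W_V = "percent_w_v"  # g per 100 mL
    PERCENT_W_W = "percent_w_w"  # g per 100 g


class Route(str, enum.Enum):
    ORAL = "oral"
    INJECTION = "injection"
    EXTERNAL = "external"


#: Drug class -> therapeutic category, covering the classes encountered in
#: East African retail markets.  Extend via ``class_categories`` arguments.
DEFAULT_CLASS_CATEGORIES: dict[str, Category] = {
    # antibiotics
    "oxytetracycline": Category.ANTIBIOTIC,
    "tetracycline": Category.ANTIBIOTIC,
    "sulfonamide": Category.ANTIBIOTIC,
    "beta-lactam": Category.ANTIBIOTIC,
    "beta-lactam/aminoglycoside": Category.ANTIBIOTIC,
    "aminoglycoside": Category.ANTIBIOTIC,
    "fluoroquinolone": Category.ANTIBIOTIC,
    "macrolide": Category.ANTIBIOTIC,
    # anthelmintics
    "benzimidazole": Category.ANTHELMINTIC,
    "imidazothiazole": Category.ANTHELMINTIC,
    "salicylanilide": Category.ANTHELMINTIC,
    "macrocyclic lactone": Category.ANTHELMINTIC,
}

#: Default IU -> mg factors (international reference standards for the
#: penicillin-type substances commonly labelled in IU).
DEFAULT_IU_FACTORS: dict[str, float] = {
    "benzylpenicillin": 0.0006,
    "procaine benzylpenicillin": 0.001,
    "benzathine benzylpenicillin": 0.00075,
    "streptomycin": 0.00125,
}


@dataclass(frozen=True)
class ProductRecord:
    """One marketed product (one active ingredient of it, for combinations).

    ``strength_value`` is the declared amount of ``api_name`` per
    ``per_quantity_value`` dose units (tablet, mL, g of powder ...);
    ``pack_size`` is the number of dose units per retail pack.
    """

    product_id: str
    trade_name: str
    is_generic: bool
    category: Category
    drug_class: str
    api_name: str
    strength_value: float
    strength_unit: StrengthUnit
    per_quantity_value: float
    per_quantity_unit: str
    pack_size: float
    routes: frozenset[Route]
    origin_country: str
    #: reporting label; combination products share one label (e.g.
    #: "penicillin-streptomycin") so their ingredients aggregate to one row
    display_label: str = ""

    def __post_init__(self) -> None:
        if not self.display_label:
            object.__setattr__(self, "display_label", self.api_name)
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "strength_unit", StrengthUnit(self.strength_unit))
        object.__setattr__(
            self, "routes", frozenset(Route(r) for r in self.routes)
        )
        if self.strength_value <= 0:
            raise ConfigError(f"{self.product_id}: strength_value must be > 0")
        if self.per_quantity_value <= 0:
            raise ConfigError(f"{self.product_id}: per_quantity_value must be > 0")
        if self.pack_size <= 0:
            raise ConfigError(f"{self.product_id}: pack_size must be > 0")
        if not self.routes:
            raise ConfigError(f"{self.product_id}: routes must be non-empty")

    def validate_class(
        self, class_categories: Mapping[str, Category] | None = None
    ) -> None:
        """Check drug_class is known and consistent with the category."""
        table = (
            DEFAULT_CLASS_CATEGORIES if class_categories is None else class_categories
        )
        try:
            expected = table[self.drug_class]
        except KeyError:
            raise ConfigError(
                f"{self.product_id}: unknown drug class {self.drug_class!r}"
            ) from None
        if Category(expected) is not self.category:
            raise ConfigError(
                f"{self.product_id}: class {self.drug_class!r} is "
                f"{Category(expected).value}, record says {self.category.value}"
            )


@dataclass(frozen=True)
class ConversionTable:
    """IU->mg factors and DDDvet doses, keyed explicitly.

    ``dddvet`` maps (api_name, species, route) to the defined daily dose
    in mg per kg live weight per day.  Unknown keys raise; there is no
    fallback value.
    """

    iu_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IU_FACTORS)
    )
    dddvet: Mapping[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, f in self.iu_factors.items():
            if f <= 0:
                raise ConfigError(f"IU factor for {name!r} must be > 0, got {f}")
        for key, d in self.dddvet.items():
            if d <= 0:
                raise ConfigError(f"DDDvet for {key!r} must be > 0, got {d}")

    def iu_factor(self, api_name: str) -> float:
        try:
            return self.iu_factors[api_name]
        except KeyError:
            raise UnknownSubstanceError(
                f"no IU->mg factor configured for {api_name!r}"
            ) from None

    def dddvet_mg_per_kg(self, api_name: str, species: str, route: str) -> float:
        key = (api_name, species, route)
        try:
            return self.dddvet[key]
        except KeyError:
            raise UnknownSubstanceError(
                f"no DDDvet configured for {key!r}"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConversionTable":
        """Load ``iu_factors`` and ``dddvet`` sections from a YAML file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        iu = dict(raw.get("iu_factors", {}))
        ddd = {
            (r["api_name"], r["species"], r["route"]): float(r["mg_per_kg_per_day"])
            for r in raw.get("dddvet", [])
        }
        return cls(iu_factors=iu, dddvet=ddd)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "iu_factors": dict(self.iu_factors),
            "dddvet": [
                {
                    "api_name": k[0],
                    "species": k[1],
                    "route": k[2],
                    "mg_per_kg_per_day": v,
                }
                for k, v in self.dddvet.items()
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def iu_to_mg(amount_iu: float, api_name: str, table: ConversionTable) -> float:
    """Convert an amount in international units to milligrams.

    Linear in ``amount_iu``; raises :class:`UnknownSubstanceError` when no
    factor is configured for ``api_name``.
    """
    if amount_iu < 0:
        raise UnitError(f"amount_iu must be >= 0, got {amount_iu}")
    return amount_iu * table.iu_factor(api_name)


def api_mass_per_pack(product: ProductRecord, table: ConversionTable) -> float:
    """Grams of active ingredient in one retail pack.

    The declared strength per dose unit is converted to mg, multiplied by
    the pack size and expressed in grams.  Percent w/v is read as g per
    100 mL (dose unit: mL); percent w/w as g per 100 g (dose unit: g of
    product).
    """
    unit = product.strength_unit
    per_unit = product.strength_value / product.per_quantity_value
    if unit is StrengthUnit.MG:
        mg_per_dose_unit = per_unit
    elif unit is StrengthUnit.G:
        mg_per_dose_unit = per_unit * 1000.0
    elif unit is StrengthUnit.IU:
        mg_per_dose_unit = iu_to_mg(per_unit, product.api_name, table)
    elif unit in (StrengthUnit.PERCENT_W_V, StrengthUnit.PERCENT_W_W):
        # strength_value % of each mL (w/v) or g (w/w) is API: 1% == 10 mg per unit
        mg_per_dose_unit = per_unit * 10.0
    else:  # pragma: no cover - enum is closed
        raise UnitError(f"unsupported strength unit {unit!r}")
    return mg_per_dose_unit * product.pack_size / 1000.0


_CSV_COLUMNS = [
    "product_id",
    "trade_name",
    "is_generic",
    "category",
    "drug_class",
    "api_name",
    "strength_value",
    "strength_unit",
    "per_quantity_value",
    "per_quantity_unit",
    "pack_size",
    "routes",
    "origin_country",
    "display_label",
]


def write_products_csv(products: Iterable[ProductRecord], path: str | Path) -> None:
    rows = []
    for p in products:
        rows.append(
            {
                "product_id": p.product_id,
                "trade_name": p.trade_name,
                "is_generic": p.is_generic,
                "category": p.category.value,
                "drug_class": p.drug_class,
                "api_name": p.api_name,
                "strength_value": repr(p.strength_value),
                "strength_unit": p.strength_unit.value,
                "per_quantity_value": repr(p.per_quantity_value),
                "per_quantity_unit": p.per_quantity_unit,
                "pack_size": repr(p.pack_size),
                "routes": "|".join(sorted(r.value for r in p.routes)),
                "origin_country": p.origin_country,
                "display_label": p.display_label,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_products_csv(path: str | Path) -> list[ProductRecord]:
    """Read ``products.csv``; round-trips with :func:`write_products_csv`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProductRecord(
                product_id=row.product_id,
                trade_name=row.trade_name,
                is_generic=row.is_generic == "True",
                category=Category(row.category),
                drug_class=row.drug_class,
                api_name=row.api_name,
                strength_value=float(row.strength_value),
                strength_unit=StrengthUnit(row.strength_unit),
                per_quantity_value=float(row.per_quantity_value),
                per_quantity_unit=row.per_quantity_unit,
                pack_size=float(row.pack_size),
                routes=frozenset(Route(r) for r in row.routes.split("|")),
                origin_country=row.origin_country,
                display_label=row.display_label,
            )
        )
    return out
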