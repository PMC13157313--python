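"""Bundled reference survey dataset.

A published retail-audit survey of veterinary antimicrobials in a
mid-sized Ethiopian city: 44 sampled products (22 antibiotics, 22
anthelmintics) from licensed retail outlets, one trading month of
audited sales by drug and route of administration, sample origins by
manufacturing country, and the municipal livestock census.  The dataset
lets every pipeline stage be exercised against published headline
figures without access to the original field records.

Data notes
----------
* The published antibiotic injection column lists per-drug masses whose
  sum exceeds the published column total by exactly 160 g, while every
  published percentage is consistent with the column *totals*.  The
  totals therefore take precedence here: the 160 g is charged to the
  penicillin-streptomycin combination row, the one row whose published
  share is itself internally inconsistent.
* The monthly-to-daily ratio implied by the published daily and monthly
  masses fixes the reporting period at 26 trading days.
* The published surveillance denominator (total PCU of 40,615,099 kg)
  rests on a national slaughter extrapolation whose inputs are not
  published; it is carried as an externally supplied constant, while the
  per-species census drives head-count shares and biomass ordering.
* Cattle age-class weights and proportions were not published; the
  census config ships plausible demonstration values (100/200/300 kg at
  20/30/50%), as do the sheep and goat slaughter throughputs.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

from .biomass import Species, SpeciesBiomassInput, write_census_yaml
from .catalog import (
    Category,
    ConversionTable,
    ProductRecord,
    Route,
    StrengthUnit,
    write_products_csv,
)
from .inspection import PACKAGING_CRITERIA, InspectionSample, write_inspections_csv
from .sales_audit import AuditVisit, SalesEstimate, write_visits_csv
from .synthetic_data import make_inspection_fixture

__all__ = [
    "PERIOD_DAYS",
    "TOTAL_PCU_KG",
    "DAILY_ANTIBIOTIC_G",
    "DAILY_ANTHELMINTIC_G",
    "ANTHELMINTIC_MONTHLY_G",
    "ANTIBIOTIC_MONTHLY_G",
    "ORIGIN_COUNTS",
    "INSPECTION_FAILURE_COUNTS",
    "INSPECTION_UNION",
    "N_SAMPLES_PER_CATEGORY",
    "CENSUS_COUNTS",
    "OUTLET_WEIGHTS",
    "reference_inspection_samples",
    "reference_sales_estimates",
    "reference_catalog",
    "reference_census",
    "write_reference_bundle",
]

#: Trading days per reporting month (fixed by the published daily/monthly ratio).
PERIOD_DAYS: float = 26.0

#: Externally supplied surveillance denominator (kg of food-producing biomass).
TOTAL_PCU_KG: float = 40_615_099.0

#: Published average daily active-ingredient masses (g/day).
DAILY_ANTIBIOTIC_G: float = 4547.0
DAILY_ANTHELMINTIC_G: float = 3073.0

#: Monthly anthelmintic sales, grams of active ingredient:
#: (drug class, drug, route, grams).
ANTHELMINTIC_MONTHLY_G: tuple[tuple[str, str, Route, float], ...] = (
    ("salicylanilide", "oxyclozanide", Route.ORAL, 13_696.75),
    ("imidazothiazole", "levamisole", Route.ORAL, 2_812.78),
    ("imidazothiazole", "tetramisole", Route.ORAL, 9_343.65),
    ("benzimidazole", "fenbendazole", Route.ORAL, 4_402.74),
    ("benzimidazole", "albendazole", Route.ORAL, 44_780.50),
    ("macrocyclic lactone", "ivermectin", Route.ORAL, 33.36),
    ("macrocyclic lactone", "ivermectin", Route.INJECTION, 281.50),
    ("benzimidazole", "triclabendazole", Route.ORAL, 4_886.85),
)

#: Monthly antibiotic sales, grams of active ingredient (combination
#: row reconciled to the published column totals; see module notes).
ANTIBIOTIC_MONTHLY_G: tuple[tuple[str, str, Route, float], ...] = (
    ("oxytetracycline", "oxytetracycline", Route.ORAL, 36_125.50),
    ("oxytetracycline", "oxytetracycline", Route.INJECTION, 24_192.10),
    ("oxytetracycline", "oxytetracycline", Route.EXTERNAL, 30.47),
    ("sulfonamide", "sulfadimidine", Route.ORAL, 7_992.00),
    ("sulfonamide", "sulfadimidine", Route.INJECTION, 13_589.33),
    ("beta-lactam/aminoglycoside", "penicillin-streptomycin", Route.INJECTION, 33_600.00),
    ("fluoroquinolone", "enrofloxacin", Route.INJECTION, 80.00),
    ("aminoglycoside", "gentamicin", Route.INJECTION, 570.00),
    ("beta-lactam", "procaine benzylpenicillin", Route.INJECTION, 709.20),
    ("macrolide", "tylosin", Route.INJECTION, 1_170.00),
)

#: Sample counts by (origin country, category).
ORIGIN_COUNTS: dict[tuple[str, Category], int] = {
    ("China", Category.ANTIBIOTIC): 13,
    ("China", Category.ANTHELMINTIC): 13,
    ("Holland", Category.ANTIBIOTIC): 5,
    ("India", Category.ANTIBIOTIC): 2,
    ("India", Category.ANTHELMINTIC): 9,
    ("Belgium", Category.ANTIBIOTIC): 2,
}

#: Per-criterion failure counts among the antibiotic samples (the
#: anthelmintic samples passed every criterion).
INSPECTION_FAILURE_COUNTS: dict[str, int] = {
    "api_name_on_pack": 7,
    "leaflet_present": 6,
    "api_dose_stated": 10,
    "expiry_date_stated": 8,
    "manufacturer_name_address": 9,
    "batch_number": 8,
}
#: Number of antibiotic samples failing at least one criterion.
INSPECTION_UNION: int = 11
N_SAMPLES_PER_CATEGORY: int = 22

#: Municipal census head counts (draft animals and swine are not food
#: producing).
CENSUS_COUNTS: dict[str, int] = {
    "poultry": 1_224_503,
    "cattle": 120_866,
    "goat": 51_405,
    "sheep": 49_377,
    "draft": 3_836,
    "swine": 200,
}

#: Published per-outlet sales shares (%) by category; outlet K sold no
#: anthelmintics (absent, distinct from zero).
OUTLET_WEIGHTS: dict[Category, dict[str, float]] = {
    Category.ANTIBIOTIC: {
        "A": 18.16, "B": 16.0, "C": 32.0, "D": 2.0, "E": 1.4, "F": 4.3,
        "G": 4.68, "H": 0.84, "I": 5.3, "J": 15.0, "K": 0.25,
    },
    Category.ANTHELMINTIC: {
        "A": 10.25, "B": 7.69, "C": 26.37, "D": 2.10, "E": 6.02,
        "F": 23.68, "G": 16.45, "H": 2.88, "I": 2.03, "J": 1.88,
    },
}

_CAT_PREFIX = {Category.ANTIBIOTIC: "ab", Category.ANTHELMINTIC: "ah"}

_PERIOD_START = datetime.date(2024, 3, 1)
_PERIOD_END = datetime.date(2024, 3, 27)

#: Pack abstraction used in the reconstructed audit records: each
#: reference "unit" carries 10 mg of active ingredient, so every
#: published two-decimal gram value maps to an integer unit count.
_UNIT_MG = 10.0


def _allocate_units(total_units: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder integer allocation of units across outlets."""
    wsum = sum(weights.values())
    exact = {o: total_units * w / wsum for o, w in weights.items()}
    base = {o: int(v) for o, v in exact.items()}
    short = total_units - sum(base.values())
    order = sorted(weights, key=lambda o: exact[o] - base[o], reverse=True)
    for o in order[:short]:
        base[o] += 1
    return base


def _row_products() -> list[tuple[str, str, str, Route, float, list[ProductRecord]]]:
    """One product (id) per published sales row; the combination row is
    two records sharing a product_id and a display label."""
    rows = []
    i = 0
    for cls, drug, route, grams in ANTHELMINTIC_MONTHLY_G + ANTIBIOTIC_MONTHLY_G:
        i += 1
        cat = (
            Category.ANTHELMINTIC
            if (cls, drug, route, grams) in ANTHELMINTIC_MONTHLY_G
            else Category.ANTIBIOTIC
        )
        pid = f"{_CAT_PREFIX[cat]}{i:03d}"
        if drug == "penicillin-streptomycin":
            records = [
                ProductRecord(
                    product_id=pid,
                    trade_name=f"PenStrep-{pid}",
                    is_generic=False,
                    category=cat,
                    drug_class=cls,
                    api_name=api,
                    strength_value=_UNIT_MG / 2,
                    strength_unit=StrengthUnit.MG,
                    per_quantity_value=1.0,
                    per_quantity_unit="dose unit",
                    pack_size=1.0,
                    routes=frozenset({route}),
                    origin_country="China",
                    display_label=drug,
                )
                for api in ("benzylpenicillin", "streptomycin")
            ]
        else:
            records = [
                ProductRecord(
                    product_id=pid,
                    trade_name=f"{drug.capitalize()}-{pid}",
                    is_generic=False,
                    category=cat,
                    drug_class=cls,
                    api_name=drug,
                    strength_value=_UNIT_MG,
                    strength_unit=StrengthUnit.MG,
                    per_quantity_value=1.0,
                    per_quantity_unit="dose unit",
                    pack_size=1.0,
                    routes=frozenset({route}),
                    origin_country="China",
                    display_label=drug,
                )
            ]
        rows.append((cls, drug, pid, route, grams, records))
    return rows


def reference_sales_estimates() -> list[SalesEstimate]:
    """Published monthly sales as per-outlet estimates.

    Each drug-route row's mass is spread over the outlets with the
    published outlet weights (largest-remainder in 10 mg units, so row
    totals are preserved exactly)."""
    out = []
    for cls, drug, pid, route, grams, records in _row_products():
        cat = records[0].category
        units = round(grams * 1000.0 / _UNIT_MG)
        for outlet, n in _allocate_units(units, OUTLET_WEIGHTS[cat]).items():
            if n == 0:
                continue
            out.append(
                SalesEstimate(
                    outlet_id=outlet,
                    product_id=pid,
                    period_start=_PERIOD_START,
                    period_end=_PERIOD_END,
                    units_sold=float(n),
                    api_grams=n * _UNIT_MG / 1000.0,
                    route=route,
                    drug_label=drug,
                    drug_class=cls,
                    category=cat,
                )
            )
    return out


def reference_catalog() -> list[ProductRecord]:
    """The 44 sampled products with origins matching the published
    country-of-origin counts.

    The products appearing in the audited sales rows come first; the
    remainder are additional sampled presentations of the same drugs.
    Origins are assigned deterministically within each category to hit
    the published counts exactly."""
    sales_rows = _row_products()
    by_cat: dict[Category, list[ProductRecord]] = {
        Category.ANTIBIOTIC: [],
        Category.ANTHELMINTIC: [],
    }
    combo_members: dict[str, list[ProductRecord]] = {}
    for _, _, pid, _, _, records in sales_rows:
        by_cat[records[0].category].append(records[0])
        if len(records) > 1:
            combo_members[pid] = records[1:]
    # pad each category to 22 distinct sampled products
    pad_specs = {
        Category.ANTIBIOTIC: ("oxytetracycline", "oxytetracycline", Route.ORAL),
        Category.ANTHELMINTIC: ("benzimidazole", "albendazole", Route.ORAL),
    }
    for cat, members in by_cat.items():
        cls, drug, route = pad_specs[cat]
        j = 0
        while len(members) < N_SAMPLES_PER_CATEGORY:
            j += 1
            pid = f"{_CAT_PREFIX[cat]}x{j:02d}"
            members.append(
                ProductRecord(
                    product_id=pid,
                    trade_name=f"{drug.capitalize()}-extra-{j}",
                    is_generic=j <= 1,
                    category=cat,
                    drug_class=cls,
                    api_name=drug,
                    strength_value=_UNIT_MG,
                    strength_unit=StrengthUnit.MG,
                    per_quantity_value=1.0,
                    per_quantity_unit="dose unit",
                    pack_size=1.0,
                    routes=frozenset({route}),
                    origin_country="China",
                )
            )
    out = []
    for cat, members in by_cat.items():
        origins = []
        for (country, c), n in sorted(ORIGIN_COUNTS.items()):
            if c is cat:
                origins += [country] * n
        assert len(origins) == len(members)
        for p, country in zip(members, origins):
            p = ProductRecord(
                **{
                    **p.__dict__,
                    "origin_country": country,
                    "routes": p.routes,
                }
            )
            out.append(p)
            for extra in combo_members.get(p.product_id, []):
                out.append(
                    ProductRecord(
                        **{
                            **extra.__dict__,
                            "origin_country": country,
                            "routes": extra.routes,
                        }
                    )
                )
    return out


def reference_inspection_samples() -> list[InspectionSample]:
    """44 checklist samples reproducing the published failure-count
    columns: 11 of 22 antibiotic samples fail at least one criterion;
    all 22 anthelmintic samples pass everything."""
    bad = make_inspection_fixture(
        INSPECTION_FAILURE_COUNTS,
        INSPECTION_UNION,
        N_SAMPLES_PER_CATEGORY,
        category=Category.ANTIBIOTIC,
        id_prefix="AB",
    )
    good = make_inspection_fixture(
        {c: 0 for c in PACKAGING_CRITERIA},
        0,
        N_SAMPLES_PER_CATEGORY,
        category=Category.ANTHELMINTIC,
        id_prefix="AH",
    )
    return bad + good


def reference_census() -> tuple[list[SpeciesBiomassInput], float]:
    """Census inputs plus the externally supplied total-PCU denominator."""
    inputs = [
        SpeciesBiomassInput(
            species=Species.CATTLE,
            census_population=CENSUS_COUNTS["cattle"],
            age_class_weights=(100.0, 200.0, 300.0),
            age_class_proportions=(0.2, 0.3, 0.5),
        ),
        SpeciesBiomassInput(
            species=Species.SHEEP,
            census_population=CENSUS_COUNTS["sheep"],
            n_slaughtered=3_000,
            age_class_weights=(18.0, 27.0, 30.0),
        ),
        SpeciesBiomassInput(
            species=Species.GOAT,
            census_population=CENSUS_COUNTS["goat"],
            n_slaughtered=10_000,
            age_class_weights=(15.0, 25.0, 30.0),
        ),
        SpeciesBiomassInput(
            species=Species.POULTRY,
            census_population=CENSUS_COUNTS["poultry"],
        ),
        SpeciesBiomassInput(
            species=Species.OTHER,
            census_population=CENSUS_COUNTS["draft"] + CENSUS_COUNTS["swine"],
            food_producing=False,
        ),
    ]
    return inputs, TOTAL_PCU_KG


def reference_visits() -> list[AuditVisit]:
    """Two-visit audit series per outlet-product reconstructing the
    published sales exactly (opening stock sold out by the final visit)."""
    visits = []
    for est in reference_sales_estimates():
        visits.append(
            AuditVisit(
                outlet_id=est.outlet_id,
                product_id=est.product_id,
                visit_date=est.period_start,
                stock_units=int(est.units_sold),
            )
        )
        visits.append(
            AuditVisit(
                outlet_id=est.outlet_id,
                product_id=est.product_id,
                visit_date=est.period_end,
                stock_units=0,
            )
        )
    return visits


def write_reference_bundle(out_dir: str | Path) -> Path:
    """Materialize the reference survey as a pipeline input bundle:
    ``products.csv``, ``visits.csv``, ``inspections.csv``,
    ``census.yaml`` and ``conversions.yaml``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_products_csv(reference_catalog(), out / "products.csv")
    write_visits_csv(reference_visits(), out / "visits.csv")
    write_inspections_csv(reference_inspection_samples(), out / "inspections.csv")
    inputs, pcu = reference_census()
    write_census_yaml(inputs, out / "census.yaml", total_pcu_override_kg=pcu)
    ConversionTable().to_yaml(out / "conversions.yaml")
    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump({"period_days": PERIOD_DAYS}, fh)
    return out
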