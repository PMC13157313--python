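"""Synthetic survey data with known ground truth.

Generates each input the pipeline consumes, with the truth recorded so
every stage is testable end to end without external data:

* a product catalog spanning the antibiotic and anthelmintic classes
  and routes seen in East African retail markets;
* outlet stock trajectories under daily Poisson demand (truncated at
  available stock) with threshold restocking and occasional disposals,
  observed through periodic audit visits — the true units sold per
  outlet-product are returned alongside the visit records;
* inspection samples constructed to hit an exact per-criterion
  failure-count vector and an exact number of noncompliant samples;
* a livestock census configuration for a mid-sized town.

Optional reporting noise under-reports stock additions by a fraction
``f`` (binomial thinning), which biases the audit estimator downward by
``f x (true additions)`` in expectation — the distortion field audits
actually suffer from.

All randomness flows from one seeded generator; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .biomass import SpeciesBiomassInput, Species, write_census_yaml
from .catalog import (
    Category,
    ConversionTable,
    ProductRecord,
    Route,
    StrengthUnit,
    write_products_csv,
)
from .errors import ConfigError, InfeasibleFixtureError
from .inspection import (
    ALL_CRITERIA,
    PACKAGING_CRITERIA,
    InspectionSample,
    write_inspections_csv,
)
from .sales_audit import AuditVisit, write_visits_csv

__all__ = [
    "SimulationConfig",
    "make_catalog",
    "simulate_audit",
    "make_inspection_fixture",
    "census_template",
    "write_bundle",
]

# (drug class, api, category, route, strength mg per dose unit, pack size)
_PRODUCT_TEMPLATES = [
    ("oxytetracycline", "oxytetracycline", Category.ANTIBIOTIC, Route.ORAL, 200.0, 50),
    ("oxytetracycline", "oxytetracycline", Category.ANTIBIOTIC, Route.INJECTION, 100.0, 100),
    ("sulfonamide", "sulfadimidine", Category.ANTIBIOTIC, Route.ORAL, 500.0, 20),
    ("aminoglycoside", "gentamicin", Category.ANTIBIOTIC, Route.INJECTION, 40.0, 100),
    ("fluoroquinolone", "enrofloxacin", Category.ANTIBIOTIC, Route.INJECTION, 100.0, 50),
    ("macrolide", "tylosin", Category.ANTIBIOTIC, Route.INJECTION, 200.0, 50),
    ("benzimidazole", "albendazole", Category.ANTHELMINTIC, Route.ORAL, 300.0, 100),
    ("benzimidazole", "fenbendazole", Category.ANTHELMINTIC, Route.ORAL, 250.0, 100),
    ("salicylanilide", "oxyclozanide", Category.ANTHELMINTIC, Route.ORAL, 600.0, 50),
    ("imidazothiazole", "levamisole", Category.ANTHELMINTIC, Route.ORAL, 150.0, 100),
    ("macrocyclic lactone", "ivermectin", Category.ANTHELMINTIC, Route.INJECTION, 10.0, 20),
    ("macrocyclic lactone", "ivermectin", Category.ANTHELMINTIC, Route.ORAL, 5.0, 50),
]

_ORIGINS = ["China", "India", "Holland", "Belgium"]

_CAT_PREFIX = {Category.ANTIBIOTIC: "ab", Category.ANTHELMINTIC: "ah"}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the audit simulator.

    Defaults emulate the study design the pipeline targets: a two-week
    audit window visited every 2-3 days across a handful of licensed
    outlets, with low per-product daily sales.
    """

    seed: int = 0
    n_outlets: int = 5
    n_products_per_category: int = 6
    period_days: int = 14
    visit_interval_days: int = 3
    mean_daily_sales: float = 3.0
    initial_stock: int = 80
    restock_threshold: int = 20
    restock_batch: int = 60
    disposal_prob: float = 0.02
    underreport_additions_frac: float = 0.0
    start_date: datetime.date = datetime.date(2024, 3, 1)

    def __post_init__(self) -> None:
        if self.mean_daily_sales < 0 or self.disposal_prob < 0:
            raise ConfigError("rates must be >= 0")
        if not 0 <= self.underreport_additions_frac <= 1:
            raise ConfigError("underreport_additions_frac must be in [0, 1]")
        if self.period_days < 1 or self.visit_interval_days < 1:
            raise ConfigError("period_days and visit_interval_days must be >= 1")


def make_catalog(config: SimulationConfig) -> list[ProductRecord]:
    """Deterministic product catalog cycling through the class templates."""
    rng = np.random.default_rng(config.seed + 1)
    out = []
    counters = {Category.ANTIBIOTIC: 0, Category.ANTHELMINTIC: 0}
    idx = 0
    while min(counters.values()) < config.n_products_per_category:
        cls, api, cat, route, strength, pack = _PRODUCT_TEMPLATES[
            idx % len(_PRODUCT_TEMPLATES)
        ]
        idx += 1
        if counters[cat] >= config.n_products_per_category:
            continue
        counters[cat] += 1
        pid = f"{_CAT_PREFIX[cat]}{counters[cat]:03d}"
        out.append(
            ProductRecord(
                product_id=pid,
                trade_name=f"{api.capitalize()}-{pid}",
                is_generic=bool(rng.random() < 0.1),
                category=cat,
                drug_class=cls,
                api_name=api,
                strength_value=strength,
                strength_unit=StrengthUnit.MG,
                per_quantity_value=1.0,
                per_quantity_unit="dose unit",
                pack_size=float(pack),
                routes=frozenset({route}),
                origin_country=_ORIGINS[int(rng.integers(len(_ORIGINS)))],
            )
        )
    return out


def simulate_audit(
    config: SimulationConfig, catalog: Sequence[ProductRecord] | None = None
) -> tuple[list[AuditVisit], dict[tuple[str, str], int]]:
    """Simulate stock trajectories and audit visits.

    Returns the visit records and the true units sold per
    (outlet_id, product_id).  Stock obeys
    ``stock_next = stock - sales + restocks - disposals`` with sales
    truncated at available stock; visits fall on day 0, every
    ``visit_interval_days`` thereafter, and the final day.
    """
    if catalog is None:
        catalog = make_catalog(config)
    rng = np.random.default_rng(config.seed)
    visit_days = sorted(
        set(range(0, config.period_days, config.visit_interval_days))
        | {config.period_days}
    )
    visits: list[AuditVisit] = []
    truth: dict[tuple[str, str], int] = {}
    for o in range(config.n_outlets):
        outlet_id = f"outlet_{chr(ord('A') + o)}"
        for product in catalog:
            stock = config.initial_stock
            total_sold = 0
            add_since, disp_since = 0, 0
            day_events = {}
            for day in range(config.period_days + 1):
                if day > 0:
                    demand = int(rng.poisson(config.mean_daily_sales))
                    sold = min(demand, stock)
                    stock -= sold
                    total_sold += sold
                    if config.disposal_prob and rng.random() < config.disposal_prob:
                        d = min(stock, int(rng.integers(1, 4)))
                        stock -= d
                        disp_since += d
                    if stock <= config.restock_threshold:
                        stock += config.restock_batch
                        add_since += config.restock_batch
                if day in visit_days:
                    f = config.underreport_additions_frac
                    reported_add = (
                        int(rng.binomial(add_since, 1.0 - f)) if f > 0 else add_since
                    )
                    visits.append(
                        AuditVisit(
                            outlet_id=outlet_id,
                            product_id=product.product_id,
                            visit_date=config.start_date
                            + datetime.timedelta(days=day),
                            stock_units=stock,
                            additions_since_last=reported_add if day else 0,
                            disposals_since_last=disp_since if day else 0,
                        )
                    )
                    add_since, disp_since = 0, 0
                day_events[day] = stock
            truth[(outlet_id, product.product_id)] = total_sold
    return visits, truth


def make_inspection_fixture(
    target_vector: Mapping[str, int] | Sequence[int],
    union_size: int,
    n_samples: int,
    category: Category = Category.ANTIBIOTIC,
    id_prefix: str = "S",
) -> list[InspectionSample]:
    """Samples whose per-criterion failure counts equal ``target_vector``
    and whose number of noncompliant samples equals ``union_size``.

    Feasible iff ``max(counts) <= union_size <= sum(counts)`` (with
    union 0 for an all-zero vector) and ``union_size <= n_samples``.
    Construction is deterministic: each criterion's failures are placed
    cyclically over the first ``union_size`` samples, so every
    noncompliant sample receives at least one failure and no criterion
    hits a sample twice.
    """
    if isinstance(target_vector, Mapping):
        vec = dict(target_vector)
    else:
        if len(target_vector) > len(PACKAGING_CRITERIA):
            raise InfeasibleFixtureError(
                f"vector longer than criterion set ({len(target_vector)})"
            )
        vec = dict(zip(PACKAGING_CRITERIA, target_vector))
    unknown = set(vec) - set(ALL_CRITERIA)
    if unknown:
        raise InfeasibleFixtureError(f"unknown criteria {sorted(unknown)}")
    if any(c < 0 for c in vec.values()):
        raise InfeasibleFixtureError("failure counts must be >= 0")
    total = sum(vec.values())
    peak = max(vec.values(), default=0)
    if union_size > n_samples:
        raise InfeasibleFixtureError(
            f"union_size {union_size} exceeds n_samples {n_samples}"
        )
    if total == 0:
        if union_size != 0:
            raise InfeasibleFixtureError(
                "all-zero vector requires union_size 0"
            )
    elif not peak <= union_size <= total:
        raise InfeasibleFixtureError(
            f"need max(counts)={peak} <= union_size={union_size} "
            f"<= sum(counts)={total}"
        )
    fails: list[set[str]] = [set() for _ in range(n_samples)]
    pointer = 0
    for criterion in ALL_CRITERIA:
        count = vec.get(criterion, 0)
        for _ in range(count):
            fails[pointer % union_size].add(criterion)
            pointer += 1
    # cyclic placement can still leave gaps when counts cluster; patch by
    # moving a failure from a multi-failure sample to an empty one
    empties = [i for i in range(union_size) if not fails[i]]
    rich = [i for i in range(union_size) if len(fails[i]) > 1]
    for i in empties:
        j = rich.pop()
        moved = sorted(fails[j])[0]
        fails[j].discard(moved)
        fails[i].add(moved)
        if len(fails[j]) > 1:
            rich.append(j)
    samples = []
    for i in range(n_samples):
        criteria = {c: c not in fails[i] for c in ALL_CRITERIA}
        samples.append(
            InspectionSample(
                sample_id=f"{id_prefix}{i + 1:03d}",
                category=category,
                criteria=criteria,
            )
        )
    return samples


def census_template() -> list[SpeciesBiomassInput]:
    """Census scenario for a mid-sized Ethiopian town.

    Counts follow a municipal livestock census (poultry-dominated in
    heads, cattle-dominated in biomass); age-class weights use the
    regional sheep/goat values and plausible cattle weights, and
    slaughter throughput uses round local-abattoir figures.  Intended as
    a demonstration configuration, not a reconstruction of any one
    surveillance denominator.
    """
    return [
        SpeciesBiomassInput(
            species=Species.CATTLE,
            census_population=120_866,
            age_class_weights=(100.0, 200.0, 300.0),
            age_class_proportions=(0.2, 0.3, 0.5),
        ),
        SpeciesBiomassInput(
            species=Species.SHEEP,
            census_population=49_377,
            n_slaughtered=3_000,
            age_class_weights=(18.0, 27.0, 30.0),
        ),
        SpeciesBiomassInput(
            species=Species.GOAT,
            census_population=51_405,
            n_slaughtered=10_000,
            age_class_weights=(15.0, 25.0, 30.0),
        ),
        SpeciesBiomassInput(
            species=Species.POULTRY,
            census_population=1_224_503,
            chicks_excluded=0,
        ),
    ]


def write_bundle(
    out_dir: str | Path,
    config: SimulationConfig,
    inspection_target: Mapping[str, int] | Sequence[int] = (1, 1, 2, 1, 1, 1),
    inspection_union: int = 3,
    n_inspection_per_category: int = 22,
) -> dict:
    """Write a complete simulated input bundle.

    Emits ``products.csv``, ``visits.csv``, ``inspections.csv``,
    ``census.yaml`` and ``truth.json`` into ``out_dir`` and returns the
    truth mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = make_catalog(config)
    visits, truth = simulate_audit(config, catalog)
    bad = make_inspection_fixture(
        inspection_target,
        inspection_union,
        n_inspection_per_category,
        category=Category.ANTIBIOTIC,
        id_prefix="AB",
    )
    good = make_inspection_fixture(
        {c: 0 for c in PACKAGING_CRITERIA},
        0,
        n_inspection_per_category,
        category=Category.ANTHELMINTIC,
        id_prefix="AH",
    )
    write_products_csv(catalog, out / "products.csv")
    write_visits_csv(visits, out / "visits.csv")
    write_inspections_csv(bad + good, out / "inspections.csv")
    write_census_yaml(census_template(), out / "census.yaml")
    ConversionTable().to_yaml(out / "conversions.yaml")
    truth_json = {
        f"{o}:{p}": int(n) for (o, p), n in sorted(truth.items())
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
    return truth_json
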