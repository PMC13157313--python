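"""Audit simulator and inspection-fixture generator."""

import filecmp

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetamu import (
    Category,
    ConversionTable,
    InfeasibleFixtureError,
    SimulationConfig,
    compliance_summary,
    estimate_units_sold,
    make_catalog,
    make_inspection_fixture,
    simulate_audit,
    write_bundle,
)
from vetamu.inspection import PACKAGING_CRITERIA


def _series(visits):
    out = {}
    for v in visits:
        out.setdefault((v.outlet_id, v.product_id), []).append(v)
    return {
        k: sorted(vs, key=lambda v: v.visit_date) for k, vs in out.items()
    }


class TestSimulateAudit:
    def test_zero_sales_rate_keeps_stock_constant(self):
        cfg = SimulationConfig(seed=1, mean_daily_sales=0.0, disposal_prob=0.0)
        visits, truth = simulate_audit(cfg)
        for key, vs in _series(visits).items():
            stocks = {v.stock_units for v in vs}
            assert len(stocks) == 1
            assert estimate_units_sold(vs) == 0
            assert truth[key] == 0

    def test_noiseless_estimator_recovers_truth_exactly(self):
        cfg = SimulationConfig(seed=7)
        visits, truth = simulate_audit(cfg)
        assert truth  # every outlet-product present
        for key, vs in _series(visits).items():
            assert estimate_units_sold(vs) == truth[key]

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        interval=st.integers(1, 7),
        period=st.integers(2, 21),
    )
    def test_recovery_holds_for_arbitrary_visit_schedules(
        self, seed, interval, period
    ):
        cfg = SimulationConfig(
            seed=seed,
            n_outlets=1,
            n_products_per_category=1,
            period_days=period,
            visit_interval_days=interval,
            mean_daily_sales=6.0,
            initial_stock=25,
            restock_threshold=10,
            restock_batch=30,
        )
        visits, truth = simulate_audit(cfg)
        for key, vs in _series(visits).items():
            assert estimate_units_sold(vs) == truth[key]

    def test_fixed_seed_bundle_is_byte_identical(self, tmp_path):
        files = [
            "products.csv",
            "visits.csv",
            "inspections.csv",
            "census.yaml",
            "truth.json",
        ]
        write_bundle(tmp_path / "a", SimulationConfig(seed=11))
        write_bundle(tmp_path / "b", SimulationConfig(seed=11))
        for f in files:
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False)

    def test_underreported_additions_bias_matches_theory(self):
        """Thinning reported additions by f biases the estimator by
        -f x (true additions) in expectation; checked by Monte Carlo
        against a 3-standard-error band."""
        f = 0.3
        residuals = []
        for s in range(120):
            cfg = SimulationConfig(
                seed=20_000 + s,
                n_outlets=1,
                n_products_per_category=1,
                period_days=14,
                mean_daily_sales=6.0,
                initial_stock=30,
                restock_threshold=15,
                restock_batch=30,
                disposal_prob=0.0,
                underreport_additions_frac=f,
            )
            visits, truth = simulate_audit(cfg)
            for key, vs in _series(visits).items():
                est = estimate_units_sold(vs)
                first, last = vs[0].stock_units, vs[-1].stock_units
                disp = sum(v.disposals_since_last for v in vs[1:])
                true_adds = truth[key] - first + last + disp
                # residual = observed bias minus theoretical expectation
                residuals.append((est - truth[key]) + f * true_adds)
        residuals = np.asarray(residuals, dtype=float)
        se = residuals.std(ddof=1) / np.sqrt(len(residuals))
        assert abs(residuals.mean()) <= 3 * se + 1e-9

    def test_catalog_spans_both_categories_and_routes(self):
        catalog = make_catalog(SimulationConfig(seed=0))
        cats = {p.category for p in catalog}
        routes = {r for p in catalog for r in p.routes}
        assert cats == {Category.ANTIBIOTIC, Category.ANTHELMINTIC}
        assert len(routes) >= 2
        for p in catalog:
            p.validate_class()


class TestInspectionFixture:
    def test_reference_vector_gives_half_noncompliance(self):
        samples = make_inspection_fixture(
            {
                "api_name_on_pack": 7,
                "leaflet_present": 6,
                "api_dose_stated": 10,
                "expiry_date_stated": 8,
                "manufacturer_name_address": 9,
                "batch_number": 8,
            },
            union_size=11,
            n_samples=22,
        )
        summary = compliance_summary(samples)
        assert summary.noncompliance_pct == pytest.approx(50.0)
        assert summary.failure_counts["api_dose_stated"] == 10

    def test_all_zero_vector_all_compliant(self):
        samples = make_inspection_fixture(
            {c: 0 for c in PACKAGING_CRITERIA}, 0, 5
        )
        assert compliance_summary(samples).n_noncompliant == 0

    def test_saturated_single_criterion(self):
        samples = make_inspection_fixture((3,), union_size=3, n_samples=3)
        summary = compliance_summary(samples)
        assert summary.n_noncompliant == 3
        assert summary.failure_counts["api_name_on_pack"] == 3

    @pytest.mark.parametrize(
        "vector, union, n",
        [
            ((5, 0, 0, 0, 0, 0), 6, 10),  # union exceeds total failures
            ((2, 2, 0, 0, 0, 0), 5, 10),  # union exceeds total failures
            ((5, 1, 0, 0, 0, 0), 4, 10),  # union below largest column
            ((1, 1, 1, 1, 1, 1), 7, 6),  # union exceeds sample count
        ],
    )
    def test_infeasible_targets_rejected(self, vector, union, n):
        with pytest.raises(InfeasibleFixtureError):
            make_inspection_fixture(vector, union, n)

    @settings(derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_feasible_targets_always_realized(self, data):
        """Construction then re-summation: any vector with
        max <= union <= sum is realized with exact column sums and
        exactly `union` noncompliant samples."""
        vector = data.draw(
            st.lists(st.integers(0, 8), min_size=6, max_size=6), label="vector"
        )
        total, peak = sum(vector), max(vector)
        if total == 0:
            union = 0
        else:
            union = data.draw(st.integers(peak, total), label="union")
        n = data.draw(st.integers(max(union, 1), union + 10), label="n")
        samples = make_inspection_fixture(vector, union, n)
        assert len(samples) == n
        summary = compliance_summary(samples)
        realized = [
            summary.failure_counts[c] for c in PACKAGING_CRITERIA
        ]
        assert realized == vector
        assert summary.n_noncompliant == union


def test_simulated_sales_convert_through_catalog(tmp_path):
    """End-to-end mass bookkeeping: truth units x pack mass equals the
    grams the estimator pipeline reports, product by product."""
    from vetamu import api_mass_per_pack, make_sales_estimates, read_visits_csv
    from vetamu import read_products_csv

    write_bundle(tmp_path, SimulationConfig(seed=5))
    catalog = read_products_csv(tmp_path / "products.csv")
    by_id = {}
    for p in catalog:
        by_id.setdefault(p.product_id, []).append(p)
    table = ConversionTable()
    ests = make_sales_estimates(
        read_visits_csv(tmp_path / "visits.csv"), by_id, table
    )
    for e in ests:
        (product,) = by_id[e.product_id]
        assert e.api_grams == pytest.approx(
            e.units_sold * api_mass_per_pack(product, table)
        )
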