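"""Species biomass formulas and the total PCU."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetamu import (
    ConfigError,
    Species,
    SpeciesBiomassInput,
    bovine_census_biomass,
    census_count_shares,
    poultry_biomass,
    slaughtered_biomass,
    smallstock_live_biomass,
    total_pcu,
)
from vetamu.reference import CENSUS_COUNTS, reference_census


class TestSlaughteredBiomass:
    def test_zero_animals(self):
        assert slaughtered_biomass(0, 250.0) == 0.0

    def test_cattle_product(self):
        assert slaughtered_biomass(1_000, 250.0) == 250_000.0

    def test_smallstock_standard_weight(self):
        # 20 kg is the standard slaughter weight for sheep and goats
        assert slaughtered_biomass(3_000, 20.0) == 60_000.0


class TestBovineCensusBiomass:
    def test_degenerate_single_class(self):
        assert bovine_census_biomass(10, [100.0], [1.0]) == 1_000.0

    def test_weighted_sum(self):
        assert bovine_census_biomass(
            120_866, [100.0, 200.0, 300.0], [0.2, 0.3, 0.5]
        ) == pytest.approx(27_799_180.0)

    def test_doubling_census_doubles_biomass(self):
        one = bovine_census_biomass(50_000, [120.0, 250.0], [0.4, 0.6])
        two = bovine_census_biomass(100_000, [120.0, 250.0], [0.4, 0.6])
        assert two == pytest.approx(2 * one)

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ConfigError):
            bovine_census_biomass(10, [100.0, 200.0], [1.0])

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            bovine_census_biomass(10, [100.0, 200.0], [0.5, 0.4])


class TestSmallstockLiveBiomass:
    def test_no_slaughter_limit(self):
        assert smallstock_live_biomass(20.0, 0, 1_000) == 1_000 * 75.0

    def test_direct_evaluation(self):
        # 20 kg x 3000 + (49,377 - 3000/1.5) x 75 kg
        assert smallstock_live_biomass(20.0, 3_000, 49_377) == pytest.approx(
            3_613_275.0
        )

    def test_breeding_weight_zero_leaves_slaughtered_term(self):
        assert smallstock_live_biomass(
            20.0, 3_000, 49_377, breeding_weight=0.0
        ) == 60_000.0

    def test_division_applies_to_slaughter_count_only(self):
        # doubling cycles halves only the subtracted term
        lo = smallstock_live_biomass(0.0, 3_000, 10_000, breeding_cycles=1.5)
        hi = smallstock_live_biomass(0.0, 3_000, 10_000, breeding_cycles=3.0)
        assert hi - lo == pytest.approx((3_000 / 1.5 - 3_000 / 3.0) * 75.0)

    def test_negative_retained_population_rejected(self):
        with pytest.raises(ConfigError):
            smallstock_live_biomass(20.0, 9_000, 100)


class TestPoultryBiomass:
    def test_no_chicks_full_census(self):
        assert poultry_biomass(1_224_503) == 1_224_503.0

    def test_all_chicks_zero(self):
        assert poultry_biomass(500, 500) == 0.0

    def test_unit_weight_scales(self):
        assert poultry_biomass(1_000, 0, unit_weight=2.0) == 2 * poultry_biomass(
            1_000
        )

    def test_chicks_exceeding_total_rejected(self):
        with pytest.raises(ConfigError):
            poultry_biomass(100, 200)


@settings(derandomize=True, max_examples=40)
@given(
    n=st.integers(0, 10**6),
    w=st.floats(0.1, 500, allow_nan=False),
    k=st.integers(1, 9),
)
def test_biomass_homogeneous_of_degree_one(n, w, k):
    """Scaling counts or weights by k scales every formula by k."""
    assert slaughtered_biomass(n * k, w) == pytest.approx(
        k * slaughtered_biomass(n, w), rel=1e-12
    )
    assert slaughtered_biomass(n, w * k) == pytest.approx(
        k * slaughtered_biomass(n, w), rel=1e-12
    )
    assert poultry_biomass(n * k, 0, w) == pytest.approx(
        k * poultry_biomass(n, 0, w), rel=1e-12
    )
    assert bovine_census_biomass(n * k, [w, 2 * w], [0.5, 0.5]) == pytest.approx(
        k * bovine_census_biomass(n, [w, 2 * w], [0.5, 0.5]), rel=1e-12
    )


class TestTotalPCU:
    def test_single_species_full_share(self):
        result = total_pcu(
            [SpeciesBiomassInput(species=Species.POULTRY, census_population=100)]
        )
        assert result.shares_pct[Species.POULTRY] == 100.0
        assert result.total_pcu_kg == 100.0

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigError):
            total_pcu([])

    def test_duplicate_species_rejected(self):
        inp = SpeciesBiomassInput(species=Species.POULTRY, census_population=10)
        with pytest.raises(ConfigError):
            total_pcu([inp, inp])

    def test_total_equals_bruteforce_species_sum(self):
        """Oracle: recompute each species formula inline and sum."""
        inputs, _ = reference_census()
        result = total_pcu(inputs)
        expected = (
            bovine_census_biomass(
                CENSUS_COUNTS["cattle"], [100.0, 200.0, 300.0], [0.2, 0.3, 0.5]
            )
            + smallstock_live_biomass(20.0, 3_000, CENSUS_COUNTS["sheep"])
            + smallstock_live_biomass(20.0, 10_000, CENSUS_COUNTS["goat"])
            + poultry_biomass(CENSUS_COUNTS["poultry"])
        )
        assert result.total_pcu_kg == pytest.approx(expected)
        assert sum(result.shares_pct.values()) == pytest.approx(100.0)

    def test_reference_biomass_ordering(self):
        """Cattle dominate biomass, then sheep, then goats, then poultry,
        even though poultry dominate head counts."""
        inputs, _ = reference_census()
        per = total_pcu(inputs).per_species_kg
        assert (
            per[Species.CATTLE]
            > per[Species.SHEEP]
            > per[Species.GOAT]
            > per[Species.POULTRY]
        )

    def test_breeding_weight_affects_only_retained_term(self):
        """Swapping the breeding weight changes the retained-population
        term and nothing else."""
        base = SpeciesBiomassInput(
            species=Species.SHEEP,
            census_population=49_377,
            n_slaughtered=3_000,
            breeding_standard_weight=75.0,
        )
        alt = SpeciesBiomassInput(
            species=Species.SHEEP,
            census_population=49_377,
            n_slaughtered=3_000,
            breeding_standard_weight=60.0,
        )
        retained = 49_377 - 3_000 / 1.5
        assert base.biomass_kg() - alt.biomass_kg() == pytest.approx(
            retained * (75.0 - 60.0)
        )


def test_census_head_count_shares_food_producing():
    inputs, _ = reference_census()
    shares = census_count_shares(inputs, food_only=True)
    assert shares[Species.POULTRY] == pytest.approx(84.67, abs=0.05)
    all_shares = census_count_shares(inputs, food_only=False)
    assert all_shares[Species.POULTRY] < shares[Species.POULTRY]
    assert sum(all_shares.values()) == pytest.approx(100.0)
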