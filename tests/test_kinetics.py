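"""Rate laws: governing nucleotide, site affinities, event rates."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtgrowth import (
    CALIBRATED_PARAMS,
    GDP,
    GMPCPP,
    ILLUSTRATIVE_PARAMS,
    INTERFACE_ACTING,
    SELF_ACTING,
    ContactClass,
    KineticParams,
    LatticeState,
    SolutionState,
    Subunit,
    association_rate,
    dissociation_rate,
    exchange_event_rate,
    governing_nucleotide,
    sample_incoming_nucleotide,
    site_KD,
)
from mtgrowth.kinetics import sample_replacement_nucleotide


class TestGoverningNucleotide:
    @pytest.fixture
    def gdp_on_cpp(self, blunt_plus):
        blunt_plus.columns[0].append(Subunit(GDP))
        return blunt_plus

    def test_plus_interface_acting_uses_buried_nucleotide(self, gdp_on_cpp):
        assert governing_nucleotide(gdp_on_cpp, 0, INTERFACE_ACTING) == GMPCPP

    def test_plus_self_acting_uses_own_nucleotide(self, gdp_on_cpp):
        assert governing_nucleotide(gdp_on_cpp, 0, SELF_ACTING) == GDP

    def test_minus_modes_equivalent(self, minus_config):
        state = LatticeState.blunt_seed(minus_config)
        state.columns[0].append(Subunit(GDP))
        assert governing_nucleotide(state, 0, SELF_ACTING) == GDP
        assert governing_nucleotide(state, 0, INTERFACE_ACTING) == GDP


class TestSiteKD:
    def test_calibrated_values(self):
        p = CALIBRATED_PARAMS
        assert site_KD(ContactClass(1), GMPCPP, p) == pytest.approx(0.025)
        assert site_KD(ContactClass(1), GDP, p) == pytest.approx(87.0)
        assert site_KD(ContactClass(2), GMPCPP, p) == pytest.approx(0.025**2 / 86.0)

    def test_bucket_matches_free_energy_sum_oracle(self):
        """Independent oracle: sum bond free energies and exponentiate.

        One longitudinal bond fixes dG_long = ln(KD_long); each lateral
        bond contributes dG_lat = ln(KD_corner / KD_long).
        """
        p = CALIBRATED_PARAMS
        dg_lat = math.log(p.kd_corner / p.kd_long)
        for b in (0, 0.5, 1, 1.5, 2):
            expected = math.exp(math.log(p.kd_long) + b * dg_lat)
            assert site_KD(ContactClass(b), GMPCPP, p) == pytest.approx(expected)

    @given(
        kd_long=st.floats(1.0, 1e4),
        corner_factor=st.floats(1e-5, 0.99),
        weaken=st.floats(1.5, 1e4),
        b=st.sampled_from([0.0, 0.5, 1.0, 1.5]),
    )
    def test_monotonicity(self, kd_long, corner_factor, weaken, b):
        """Weak nucleotide never binds tighter; extra laterals never loosen."""
        p = KineticParams(
            kd_long=kd_long,
            kd_corner=kd_long * corner_factor,
            kd_long_gdp=kd_long * weaken,
            kd_corner_gdp=kd_long * corner_factor * weaken,
        )
        cls, cls_more = ContactClass(b), ContactClass(b + 0.5)
        assert site_KD(cls, GDP, p) >= site_KD(cls, GMPCPP, p)
        assert site_KD(cls_more, GMPCPP, p) <= site_KD(cls, GMPCPP, p)


class TestEventRates:
    def test_association_examples(self):
        assert association_rate(
            ILLUSTRATIVE_PARAMS, SolutionState(tubulin_total=1.0), "plus"
        ) == pytest.approx(1.0)
        assert association_rate(
            CALIBRATED_PARAMS, SolutionState(tubulin_total=1.25), "plus"
        ) == pytest.approx(0.925)
        assert association_rate(
            CALIBRATED_PARAMS, SolutionState(tubulin_total=0.0), "plus"
        ) == 0.0

    def test_dissociation_uses_end_specific_kon(self):
        p = CALIBRATED_PARAMS
        assert dissociation_rate(p, "plus", 0.025) == pytest.approx(0.0185)
        assert dissociation_rate(p, "plus", 3.0e5) == pytest.approx(2.22e5)
        assert dissociation_rate(p, "minus", 86.0) == pytest.approx(26.66)

    def test_exchange_rates(self):
        p = KineticParams(k_exchange_gdp=0.4)
        assert exchange_event_rate(Subunit(GDP), p) == pytest.approx(0.4)
        assert exchange_event_rate(Subunit(GMPCPP), p) == pytest.approx(5.0)
        p0 = KineticParams(k_exchange_gdp=0.0)
        assert exchange_event_rate(Subunit(GMPCPP), p0) == 0.0


class TestNucleotideSampling:
    def test_degenerate_fractions(self, rng):
        all_cpp = SolutionState(tubulin_total=1.0, frac_gdp_tubulin=0.0)
        all_gdp = SolutionState(tubulin_total=1.0, frac_gdp_tubulin=1.0)
        assert all(sample_incoming_nucleotide(all_cpp, rng) == GMPCPP for _ in range(50))
        assert all(sample_incoming_nucleotide(all_gdp, rng) == GDP for _ in range(50))

    def test_gdp_share_within_binomial_ci(self, rng):
        sol = SolutionState(tubulin_total=1.0, frac_gdp_tubulin=0.25)
        n = 100_000
        share = sum(sample_incoming_nucleotide(sol, rng) == GDP for _ in range(n)) / n
        assert abs(share - 0.25) < 3 * math.sqrt(0.25 * 0.75 / n)

    def test_replacement_uses_free_nucleotide_fraction(self, rng):
        sol = SolutionState(tubulin_total=1.0, frac_gdp_tubulin=0.9, free_frac_gdp=0.0)
        assert all(
            sample_replacement_nucleotide(sol, rng) == GMPCPP for _ in range(50)
        )


class TestParams:
    def test_weakening_factor_mismatch_warns(self):
        with pytest.warns(UserWarning, match="GDP weakening"):
            KineticParams(kd_long_gdp=3.0e5, kd_corner_gdp=30.0)

    def test_table_round_trip(self, tmp_path):
        path = tmp_path / "params.json"
        CALIBRATED_PARAMS.to_json(path)
        assert KineticParams.from_json(path) == CALIBRATED_PARAMS

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kon_plus": 0.0},
            {"kd_corner": -1.0},
            {"k_exchange_gdp": -0.1},
            {"mechanism": "both"},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)

    def test_solution_validation(self):
        with pytest.raises(ValueError):
            SolutionState(tubulin_total=-1.0)
        with pytest.raises(ValueError):
            SolutionState(tubulin_total=1.0, frac_gdp_tubulin=1.5)
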