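"""Lattice geometry, seam pairing, site classification and serialization."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtgrowth import (
    GDP,
    GMPCPP,
    GTP,
    LatticeConfig,
    LatticeState,
    Subunit,
    classify_site,
    exchange_eligible,
    interfacial_nucleotide,
    lateral_bonds,
    lateral_neighbors,
    tip_row,
)


def add(state, pf, nucleotide=GMPCPP):
    state.columns[pf].append(Subunit(nucleotide))


class TestTipRow:
    def test_fresh_blunt_seed(self, blunt_plus):
        assert all(tip_row(blunt_plus, pf) == 5 for pf in range(13))

    def test_association_and_dissociation_inverse(self, blunt_plus):
        add(blunt_plus, 3)
        assert tip_row(blunt_plus, 3) == 6
        assert all(tip_row(blunt_plus, pf) == 5 for pf in range(13) if pf != 3)
        blunt_plus.columns[3].pop()
        assert tip_row(blunt_plus, 3) == 5


class TestSeamPairing:
    def test_non_seam_same_row(self):
        cfg = LatticeConfig(seam_offset_rows=2)
        assert lateral_neighbors(cfg, 5, 10) == [(4, 10), (6, 10)]

    def test_integer_seam_plus_and_minus_mirror(self):
        # last protofilament, row 10, offset 2: partner (0, 12) at the plus
        # end and (0, 8) at the minus end (mirrored sign)
        cfg = LatticeConfig(seam_offset_rows=2, polarity="plus")
        assert (0, 12) in lateral_neighbors(cfg, 12, 10)
        cfg_m = LatticeConfig(seam_offset_rows=2, polarity="minus")
        assert (0, 8) in lateral_neighbors(cfg_m, 12, 10)

    def test_half_integer_seam_gives_two_half_partners(self):
        cfg = LatticeConfig()  # default offset 1.5
        seam = [b for b in lateral_bonds(cfg, 12, 10) if b[0] == 0]
        assert sorted(seam) == [(0, 11, 0.5), (0, 12, 0.5)]

    @given(
        pf=st.integers(0, 12),
        row=st.integers(5, 30),
        offset=st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0]),
        polarity=st.sampled_from(["plus", "minus"]),
    )
    def test_pairing_is_an_involution(self, pf, row, offset, polarity):
        """If B is among A's weighted partners, A is among B's with equal weight."""
        cfg = LatticeConfig(seam_offset_rows=offset, polarity=polarity)
        for q, r, w in lateral_bonds(cfg, pf, row):
            back = {(qq, rr): ww for qq, rr, ww in lateral_bonds(cfg, q, r)}
            assert back.get((pf, row)) == w

    def test_single_protofilament_has_no_partners(self):
        cfg = LatticeConfig(n_protofilaments=1)
        assert lateral_neighbors(cfg, 0, 3) == []


class TestClassifySite:
    def test_blunt_candidate_is_longitudinal_only(self, blunt_plus):
        # candidate sites beyond a blunt end have no extended neighbors
        assert classify_site(blunt_plus, 5, 6).value == "longitudinal_only"

    def test_corner_and_bucket(self, blunt_plus):
        add(blunt_plus, 4)
        assert classify_site(blunt_plus, 5, 6).value == "corner"
        add(blunt_plus, 6)
        assert classify_site(blunt_plus, 5, 6).value == "bucket"

    def test_invalid_site_raises(self, blunt_plus):
        with pytest.raises(ValueError, match="neither terminal"):
            classify_site(blunt_plus, 5, 3)

    @given(
        heights=st.lists(st.integers(1, 10), min_size=13, max_size=13),
        pf=st.integers(0, 12),
        candidate=st.booleans(),
        polarity=st.sampled_from(["plus", "minus"]),
    )
    def test_matches_brute_force_occupancy_scan(self, heights, pf, candidate, polarity):
        """Oracle: re-derive the lateral bond count by scanning raw occupancy."""
        cfg = LatticeConfig(polarity=polarity)
        state = LatticeState(
            config=cfg,
            columns=[
                [Subunit(GMPCPP, locked=(r == 0)) for r in range(h)] for h in heights
            ],
        )
        row = heights[pf] - 1 + (1 if candidate else 0)
        expected = 0.0
        for q, r, w in lateral_bonds(cfg, pf, row):
            if 0 <= r < heights[q]:
                expected += w
        assert classify_site(state, pf, row).n_lateral == min(expected, 2.0)


class TestInterfacialNucleotide:
    def test_plus_terminal_gdp_atop_gmpcpp(self, blunt_plus):
        add(blunt_plus, 2, GDP)
        assert interfacial_nucleotide(blunt_plus, 2) == GMPCPP

    def test_minus_terminal_gdp_is_its_own_interface(self, minus_config):
        state = LatticeState.blunt_seed(minus_config)
        add(state, 2, GDP)
        assert interfacial_nucleotide(state, 2) == GDP

    def test_uniform_gmpcpp_column(self, blunt_plus):
        assert interfacial_nucleotide(blunt_plus, 0) == GMPCPP


class TestExchangeEligible:
    def test_plus_all_tips(self, blunt_plus):
        assert exchange_eligible(blunt_plus) == set(range(13))

    def test_minus_always_empty(self, minus_config):
        state = LatticeState.blunt_seed(minus_config)
        assert exchange_eligible(state) == set()

    def test_eroded_column_excluded(self, blunt_plus):
        blunt_plus.columns[7] = blunt_plus.columns[7][:1]  # down to locked base
        assert exchange_eligible(blunt_plus) == set(range(13)) - {7}


class TestStateAndConfig:
    def test_mean_length_increases_8_13ths_per_association(self, blunt_plus):
        assert blunt_plus.mean_length_nm() == 0.0
        add(blunt_plus, 0)
        assert blunt_plus.mean_length_nm() == pytest.approx(8.0 / 13.0)

    def test_json_round_trip(self, blunt_plus):
        add(blunt_plus, 4, GDP)
        add(blunt_plus, 9, GTP)
        restored = LatticeState.from_json(blunt_plus.to_json())
        assert restored.polarity == blunt_plus.polarity
        assert [
            [s.nucleotide for s in col] for col in restored.columns
        ] == [[s.nucleotide for s in col] for col in blunt_plus.columns]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_protofilaments": 0},
            {"dimer_length_nm": 0},
            {"seed_rows": 0},
            {"polarity": "sideways"},
            {"seam_offset_rows": 0.3},
            {"seam_offset_rows": -1},
        ],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            LatticeConfig(**kwargs)
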