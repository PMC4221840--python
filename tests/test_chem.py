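"""Nominal-mass and fragment-ion arithmetic."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waxgc.chem import (
    ChainSpecies,
    InvalidSpeciesError,
    IonType,
    SpeciesClass,
    Triglyceride,
    UnsupportedSpeciesError,
    WrongClassError,
    acid_fragment_mz,
    enumerate_esters,
    ester_from_parts,
    fragment_set,
    nominal_mass,
    parse_chain,
    parse_ester,
    triglyceride_fragment_mzs,
)


def acid(n, d=0):
    return ChainSpecies(SpeciesClass.FATTY_ACID, n, d)


def alcohol(n, d=0):
    return ChainSpecies(SpeciesClass.FATTY_ALCOHOL, n, d)


class TestNominalMass:
    @pytest.mark.parametrize(
        "species, expected",
        [
            (acid(18), 284),  # stearic acid C18H36O2
            (acid(16), 256),  # palmitic acid
            (alcohol(16), 242),  # cetyl alcohol C16H34O
            (acid(18, 1), 282),  # oleic: one double bond removes H2
            (ChainSpecies(SpeciesClass.HYDROCARBON, 27), 380),  # C27H56
            (ChainSpecies(SpeciesClass.HYDROCARBON, 31), 436),  # C31H64
            (ChainSpecies(SpeciesClass.STEROL, 27), 386),  # cholesterol backbone
            (ChainSpecies(SpeciesClass.FATTY_ACID, 18, 0, 1), 300),  # hydroxy acid
        ],
    )
    def test_chain_masses(self, species, expected):
        assert nominal_mass(species) == expected

    def test_behenyl_stearate_is_592(self):
        ester = ester_from_parts(alcohol(22), acid(18))
        assert nominal_mass(ester) == 592
        assert ester.total_carbons == 40

    def test_ester_condensation_identity(self):
        """Ester mass is acid + alcohol - water for every enumerated pair."""
        for ester in enumerate_esters(54, (16, 32), (16, 38)):
            assert (
                nominal_mass(ester)
                == nominal_mass(ester.acid) + nominal_mass(ester.alcohol) - 18
            )

    def test_triglyceride_masses(self):
        assert nominal_mass(Triglyceride.from_label("PPP")) == 806
        assert nominal_mass(Triglyceride.from_label("PPO")) == 832
        assert Triglyceride.from_label("PPP").total_carbons == 51

    def test_invalid_carbon_count(self):
        with pytest.raises(InvalidSpeciesError):
            ChainSpecies(SpeciesClass.FATTY_ACID, 0)

    def test_impossible_unsaturation(self):
        with pytest.raises(InvalidSpeciesError):
            ChainSpecies(SpeciesClass.FATTY_ACID, 4, 3)


class TestAcidFragmentSeries:
    @pytest.mark.parametrize(
        "n, mz",
        [(16, 257), (18, 285), (20, 313), (22, 341), (24, 369),
         (26, 397), (28, 425), (30, 453), (32, 481)],
    )
    def test_printed_series(self, n, mz):
        """The nine diagnostic ions of the saturated C16-C32 acids."""
        assert acid_fragment_mz(acid(n)) == mz
        assert mz == 14 * n + 33

    def test_unsaturated_acid(self):
        assert acid_fragment_mz(acid(18, 1)) == 283

    def test_rejects_non_acids(self):
        with pytest.raises(WrongClassError):
            acid_fragment_mz(alcohol(18))


class TestFragmentSet:
    def test_behenyl_stearate_ions(self):
        ions = {
            (i.ion_type, i.mz)
            for i in fragment_set(ester_from_parts(alcohol(22), acid(18)))
        }
        assert (IonType.ACID_ACYLIUM_PLUS_H, 285) in ions
        assert (IonType.ACYLIUM, 267) in ions
        assert (IonType.ACID_ALKYL, 239) in ions
        assert (IonType.MOLECULAR_ION, 592) in ions
        assert len(ions) >= 5

    def test_no_duplicate_type_mz_pairs(self):
        ions = fragment_set(ester_from_parts(alcohol(30), acid(24)))
        pairs = [(i.ion_type, i.mz) for i in ions]
        assert len(pairs) == len(set(pairs))

    @pytest.mark.parametrize("alc_n", [16, 22, 28, 34])
    def test_acid_side_independent_of_alcohol(self, alc_n):
        acid_types = {
            IonType.ACID_ACYLIUM_PLUS_H, IonType.ACYLIUM, IonType.ACID_ALKYL
        }
        ref = {
            (i.ion_type, i.mz)
            for i in fragment_set(ester_from_parts(alcohol(22), acid(18)))
            if i.ion_type in acid_types
        }
        other = {
            (i.ion_type, i.mz)
            for i in fragment_set(ester_from_parts(alcohol(alc_n), acid(18)))
            if i.ion_type in acid_types
        }
        assert ref == other

    def test_branched_and_hydroxy_not_modeled(self):
        branched = ChainSpecies(SpeciesClass.FATTY_ACID, 18, branched=True)
        with pytest.raises(UnsupportedSpeciesError):
            fragment_set(ester_from_parts(alcohol(22), branched))
        hydroxy = ChainSpecies(SpeciesClass.FATTY_ALCOHOL, 22, hydroxyl_count=1)
        with pytest.raises(UnsupportedSpeciesError):
            fragment_set(ester_from_parts(hydroxy, acid(18)))

    def test_tag_diagnostics_resolve_ppp_from_ppo(self):
        ppp = triglyceride_fragment_mzs(Triglyceride.from_label("PPP"))
        ppo = triglyceride_fragment_mzs(Triglyceride.from_label("PPO"))
        assert ppp[IonType.MOLECULAR_ION] == [806]
        assert ppo[IonType.MOLECULAR_ION] == [832]
        assert 551 in ppp[IonType.ALCOHOL_ESTER]  # loss of palmitoyloxy


class TestEnumerateEsters:
    def test_c54_candidate_space(self):
        cands = enumerate_esters(54, (16, 32), (16, 38), even_only=True)
        assert len(cands) == 9
        assert [e.acid.carbon_count for e in cands] == list(range(16, 33, 2))

    def test_odd_total_with_even_chains_is_empty(self):
        assert enumerate_esters(33, (16, 32), (16, 38), even_only=True) == []

    def test_forced_single_candidate(self):
        cands = enumerate_esters(40, (18, 18), (22, 22))
        assert len(cands) == 1
        assert nominal_mass(cands[0]) == 592

    @given(
        total=st.integers(20, 80),
        a_lo=st.integers(8, 30),
        a_span=st.integers(0, 14),
        o_lo=st.integers(8, 30),
        o_span=st.integers(0, 14),
        even=st.booleans(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_count_matches_double_loop_oracle(self, total, a_lo, a_span, o_lo, o_span, even):
        a_hi, o_hi = a_lo + a_span, o_lo + o_span
        count = 0
        for n in range(a_lo, a_hi + 1):
            for m in range(o_lo, o_hi + 1):
                if n + m != total:
                    continue
                if even and (n % 2 or m % 2):
                    continue
                count += 1
        assert len(enumerate_esters(total, (a_lo, a_hi), (o_lo, o_hi), even)) == count


class TestShorthand:
    @given(n=st.integers(1, 60), d=st.integers(0, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_chain_shorthand_round_trip(self, n, d):
        if d > n / 2:
            return
        species = ChainSpecies(SpeciesClass.FATTY_ACID, n, d)
        assert parse_chain(species.shorthand) == species

    def test_ester_shorthand(self):
        ester = parse_ester("C22:0xC18:0")
        assert ester.alcohol.carbon_count == 22
        assert ester.acid.carbon_count == 18
        assert parse_ester(ester.shorthand) == ester

    def test_unparseable(self):
        with pytest.raises(InvalidSpeciesError):
            parse_chain("18:0")

    def test_tag_label_mismatch(self):
        chains = tuple(ChainSpecies(SpeciesClass.FATTY_ACID, 16) for _ in range(3))
        with pytest.raises(InvalidSpeciesError):
            Triglyceride(acyl_chains=chains, label="PPO")
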