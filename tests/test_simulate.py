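"""Reference profiles and the forward simulator."""
import warnings

import numpy as np
import pytest

from waxgc.chem import SpeciesClass
from waxgc.peaks import compute_tic, extract_eic, integrate
from waxgc.profiles import (
    BUILTIN_NAMES,
    CatalogError,
    ReferenceProfile,
    builtin_profile,
)
from waxgc.simulate import (
    Run,
    Scan,
    SimulationConfig,
    SimulationError,
    generate_run,
    write_run,
)
from waxgc.io import read_run
from waxgc.chem import ChainSpecies, ester_from_parts

from conftest import make_run


class TestBuiltinProfiles:
    @pytest.mark.parametrize("name", BUILTIN_NAMES)
    def test_loads_and_normalizes(self, name):
        profile = builtin_profile(name)
        total = sum(w for _, w in profile.all_species())
        assert total == pytest.approx(1.0, abs=1e-12)
        assert all(w >= 0 for _, w in profile.all_species())

    @pytest.mark.parametrize(
        "name, lo, hi",
        [("lanolin", 48, 52), ("beeswax", 40, 48), ("jojoba", 38, 44),
         ("shellac", 44, 50), ("carnauba", 50, 56), ("rice_bran", 50, 56),
         ("montan", 50, 56)],
    )
    def test_ester_carbon_ranges(self, name, lo, hi):
        carbons = builtin_profile(name).ester_carbon_numbers
        assert min(carbons) == lo and max(carbons) == hi
        assert all(c % 2 == 0 for c in carbons)

    def test_lanolin_has_sterol_interferent(self):
        profile = builtin_profile("lanolin")
        assert any(
            s.species_class is SpeciesClass.STEROL for s, _ in profile.interferents
        )

    def test_candelilla_is_hydrocarbon_dominated(self):
        profile = builtin_profile("candelilla")
        assert not profile.ester_species
        hydro = sum(
            w for s, w in profile.interferents
            if s.species_class is SpeciesClass.HYDROCARBON
        )
        assert hydro == pytest.approx(1.0)

    def test_rice_bran_c54_acid_split(self):
        """The C54 acid weights embed the printed 28/69 composition."""
        profile = builtin_profile("rice_bran")
        c54 = [(e, w) for e, w in profile.ester_species if e.total_carbons == 54]
        total = sum(w for _, w in c54)
        split = {e.acid.shorthand: w / total for e, w in c54}
        assert split["C22:0"] == pytest.approx(0.28, abs=1e-9)
        assert split["C24:0"] == pytest.approx(0.69, abs=1e-9)

    def test_urushi_ppo_enriched_relative_to_japan_wax(self):
        def ppo_over_ppp(name):
            weights = {t.label: w for t, w in builtin_profile(name).triglycerides}
            return weights["PPO"] / weights["PPP"]

        assert ppo_over_ppp("urushi") > ppo_over_ppp("japan_wax")

    def test_unknown_name(self):
        with pytest.raises(CatalogError):
            builtin_profile("paraffin")


class TestGenerateRun:
    def test_same_seed_is_bit_identical(self):
        a = make_run("carnauba", seed=13)
        b = make_run("carnauba", seed=13)
        assert len(a.scans) == len(b.scans)
        for sa, sb in zip(a.scans, b.scans):
            assert sa.rt == sb.rt
            assert (sa.mz == sb.mz).all()
            assert (sa.intensity == sb.intensity).all()

    def test_noiseless_apexes_match_rt_model(self, carnauba_noiseless, rt_model):
        tic = compute_tic(carnauba_noiseless)
        profile = builtin_profile("carnauba")
        for carbon in profile.ester_carbon_numbers:
            expected_rt = rt_model.predict(carbon)
            window = np.abs(tic.rt - expected_rt) <= 0.3
            apex = tic.rt[window][np.argmax(tic.intensity[window])]
            assert apex == pytest.approx(expected_rt, abs=0.011)

    def test_abundance_conservation(self, rt_model):
        """Noiseless TIC area over a species window is proportional to its
        relative abundance."""
        run = make_run("urushi", noise_sd=0.0, seed=0)
        tic = compute_tic(run)
        profile = builtin_profile("urushi")
        areas = {}
        for tg, w in profile.triglycerides:
            rt0 = rt_model.predict(tg.total_carbons)
            areas[tg.label] = (integrate(tic, (rt0 - 0.2, rt0 + 0.2)), w)
        (a1, w1), (a2, w2) = areas.values()
        assert a1 / a2 == pytest.approx(w1 / w2, rel=1e-6)

    def test_fragment_ratios_are_rt_invariant(self, carnauba_noiseless):
        """No chromatographic skew: within-spectrum ratios hold across a peak."""
        scans = [s for s in carnauba_noiseless.scans if abs(s.rt - 25.0) <= 0.1]
        ratios = []
        for scan in scans:
            i341 = scan.intensity[scan.mz == 341]
            i369 = scan.intensity[scan.mz == 369]
            assert i341.size == 1 and i369.size == 1
            ratios.append(i341[0] / i369[0])
        assert np.ptp(ratios) == pytest.approx(0.0, abs=1e-9)

    def test_carnauba_c54_window_has_341_and_369(self, carnauba_run):
        """Both the C22:0 (341) and C24:0 (369) acid ions peak inside the
        C54 ester's elution window (they also occur in neighboring esters,
        so the check is for a strong local peak, not exclusivity)."""
        for mz in (341, 369):
            eic = extract_eic(carnauba_run, mz)
            window = np.abs(eic.rt - 25.0) <= 0.25
            in_window = eic.intensity[window].max()
            assert in_window > 0.1 * eic.intensity.max()
            assert in_window > 5 * np.median(eic.intensity[window])  # peaked, not flat


    def test_out_of_window_species_skipped_with_warning(self, rt_model):
        early = ester_from_parts(
            ChainSpecies(SpeciesClass.FATTY_ALCOHOL, 10),
            ChainSpecies(SpeciesClass.FATTY_ACID, 10),
        )  # C20 -> RT -9 min
        ok = ester_from_parts(
            ChainSpecies(SpeciesClass.FATTY_ALCOHOL, 22),
            ChainSpecies(SpeciesClass.FATTY_ACID, 18),
        )
        profile = ReferenceProfile(
            name="toy", ester_species=[(early, 0.5), (ok, 0.5)]
        )
        with pytest.warns(UserWarning, match="outside the scan window"):
            run = generate_run(profile, SimulationConfig(noise_sd=0.0, seed=0))
        tic = compute_tic(run)
        assert tic.rt.min() > 10  # only the C40 ester made it in

    def test_config_validation(self):
        with pytest.raises(SimulationError):
            SimulationConfig(scan_interval=0.0)
        with pytest.raises(SimulationError):
            SimulationConfig(mz_range=(10, 2000))


class TestRunIO:
    def test_csv_round_trip_is_exact(self, tmp_path, urushi_run):
        path = tmp_path / "run.csv"
        write_run(urushi_run, path, format="csv_scan_table")
        back = read_run(path)
        assert len(back.scans) == len(urushi_run.scans)
        for a, b in zip(urushi_run.scans, back.scans):
            assert a.rt == b.rt
            assert (a.mz == b.mz).all()
            assert (a.intensity == b.intensity).all()

    def test_mzml_round_trip(self, tmp_path, urushi_run):
        path = tmp_path / "run.mzml"
        write_run(urushi_run, path, format="mzml")
        back = read_run(path)
        assert len(back.scans) == len(urushi_run.scans)
        for a, b in zip(urushi_run.scans, back.scans):
            assert a.rt == pytest.approx(b.rt, abs=1e-12)
            assert (a.mz == b.mz).all()
            assert np.allclose(a.intensity, b.intensity)

    def test_empty_run_writes_header_only_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_run(Run(scans=[]), path)
        assert path.read_text().strip() == "rt_min,mz,intensity"
        assert read_run(path).scans == []

    def test_three_scan_toy_run(self, tmp_path):
        # deliberately tiny: three scans, one centroid each
        scans = [
            Scan(rt=float(i), mz=np.array([100 + i]), intensity=np.array([1.0 * i + 1]))
            for i in range(3)
        ]
        run = Run(scans=scans)
        path = tmp_path / "toy.csv"
        write_run(run, path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 4  # header + 3 centroids
        assert len({line.split(",")[0] for line in text[1:]}) == 3
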