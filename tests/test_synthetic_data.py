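import numpy as np
import pytest

from displaceq import (
    PRESETS,
    NoiseModel,
    QuadraticBindingModel,
    competitor_kd_for_ic50,
    count_bulge_regions,
    default_roster,
    eq1_fluorescence,
    fit_ic50,
    generate_ground_truth_library,
    noiseless_ic50,
    simulate_control_plate,
    simulate_displacement_titration,
    simulate_fneo_titration,
    simulate_ph_titration,
    simulate_screen_plates,
    solve_competitive_equilibrium,
    summarize_screen,
    zfactor,
)
from displaceq.errors import ParseError, ValidationError
from displaceq.synthetic_data import AssayCondition


class TestAssayCondition:
    def test_presets_match_study_conditions(self):
        assert PRESETS["mir504"] == AssayCondition(100.0, 50.0, 300.0, 2, 1.5)
        assert PRESETS["premir504"] == AssayCondition(100.0, 16.7, 300.0, 6, 0.5)
        assert PRESETS["mir142"] == AssayCondition(100.0, 100.0, 500.0, 1, 2.0)
        assert PRESETS["mir335"] == AssayCondition(100.0, 100.0, 500.0, 1, 2.2)

    def test_site_total(self):
        assert PRESETS["mir504"].site_total == pytest.approx(100.0)
        assert PRESETS["premir504"].site_total == pytest.approx(100.2)

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValidationError):
            AssayCondition(0.0, 50.0, 300.0, 2, 1.5)


class TestProbeTitration:
    def test_zero_noise_matches_forward_model(self, quench_model):
        concs = np.linspace(0, 300, 10)
        series = simulate_fneo_titration(quench_model, concs, 2, NoiseModel(cv=0.0))
        np.testing.assert_allclose(
            series.y, eq1_fluorescence(quench_model, 2 * concs), rtol=1e-14
        )

    def test_seed_reproducibility(self, quench_model):
        concs = np.linspace(1, 200, 8)
        a = simulate_fneo_titration(quench_model, concs, 1, NoiseModel(0.02, seed=9))
        b = simulate_fneo_titration(quench_model, concs, 1, NoiseModel(0.02, seed=9))
        np.testing.assert_array_equal(a.y, b.y)

    def test_monte_carlo_mean_close_to_truth(self, quench_model):
        concs = np.array([10.0, 50.0, 100.0, 200.0])
        clean = eq1_fluorescence(quench_model, concs)
        reps = np.array(
            [
                simulate_fneo_titration(
                    quench_model, concs, 1, NoiseModel(0.02, seed=s)
                ).y
                for s in range(1000)
            ]
        )
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(reps.mean(axis=0) - clean) < 3 * se)


class TestDisplacementTitration:
    def test_zero_competitor_is_flat(self, mir504_condition):
        series = simulate_displacement_titration(
            mir504_condition, 1.0, np.zeros(6), noise=NoiseModel(cv=0.0)
        )
        assert np.ptp(series.y) == 0.0

    def test_inert_competitor_is_flat(self, mir504_condition):
        series = simulate_displacement_titration(
            mir504_condition, float("inf"), np.geomspace(1, 1e4, 6),
            noise=NoiseModel(cv=0.0),
        )
        np.testing.assert_allclose(series.y, series.y[0], rtol=1e-12)

    def test_fitted_ic50_monotone_in_kd(self, mir504_condition):
        concs = np.geomspace(2, 50000, 14)
        fitted = []
        for kd in (0.1, 1.0, 10.0, 100.0):
            series = simulate_displacement_titration(
                mir504_condition, kd, concs, noise=NoiseModel(cv=0.0)
            )
            fitted.append(fit_ic50(series).ic50)
        assert fitted == sorted(fitted)


class TestPhTitration:
    def test_zero_noise_exact_midpoint(self):
        series = simulate_ph_titration(6.5, 0.2, 1.0, np.array([5.0, 6.5, 8.0]))
        assert series.y[1] == pytest.approx(0.6)

    def test_seed_reproducibility(self):
        grid = np.arange(4.5, 9.0, 0.5)
        a = simulate_ph_titration(6.37, 0.1, 1.0, grid, NoiseModel(0.01, seed=2))
        b = simulate_ph_titration(6.37, 0.1, 1.0, grid, NoiseModel(0.01, seed=2))
        np.testing.assert_array_equal(a.y, b.y)


class TestGroundTruthLibrary:
    def test_default_roster_size(self):
        assert len(default_roster()) == 215
        assert len(set(default_roster())) == 215

    def test_zero_effects_zero_noise(self):
        alpha = dict.fromkeys("ARNDHLFPSTYVCWK", 0.0)
        beta = dict.fromkeys(list("STYVDWHRLFCAN") + ["βA"], 0.0)
        truth = generate_ground_truth_library(
            alpha=alpha, beta=beta, kd_neo=7.5, noise_sd=0.0
        )
        assert all(kd == pytest.approx(7.5, rel=1e-12) for kd in truth.kd.values())

    def test_seed_determinism(self):
        a = generate_ground_truth_library(seed=11)
        b = generate_ground_truth_library(seed=11)
        assert a.kd == b.kd

    def test_missing_effect_named(self):
        with pytest.raises(ValidationError, match="'K'"):
            generate_ground_truth_library(alpha={"R": -0.3}, roster=["NeoK"])


@pytest.fixture(scope="module")
def screen():
    cond = PRESETS["mir504"]
    truth = generate_ground_truth_library(kd_neo=0.343, seed=4)
    plates = simulate_screen_plates(truth, cond, NoiseModel(cv=0.0))
    return truth, summarize_screen(plates), plates


class TestScreenPlates:
    def test_layout_contract(self, screen):
        _, _, plates = screen
        for pid in plates.plate_ids():
            assert len(plates.by_role(pid, "positive")) >= 2
            assert len(plates.by_role(pid, "negative")) >= 2

    def test_matched_kd_gives_100_percent_at_zero_noise(self, mir504_condition):
        truth = generate_ground_truth_library(
            alpha={"R": 0.0, "S": 0.5, "T": -0.5}, roster=["NeoR", "NeoS", "NeoT"],
            kd_neo=0.343, noise_sd=0.0,
        )
        records = {
            r.compound_name: r
            for r in summarize_screen(
                simulate_screen_plates(truth, mir504_condition, NoiseModel(cv=0.0))
            )
        }
        assert records["NeoR"].percent_binding == pytest.approx(100.0, abs=1e-6)

    def test_all_compounds_present_in_duplicate(self, screen):
        truth, records, _ = screen
        by_name = {r.compound_name: r for r in records}
        assert set(truth.kd) <= set(by_name)
        assert all(by_name[name].n_replicates == 2 for name in truth.kd)

    def test_seeded_reproducibility(self, mir504_condition):
        truth = generate_ground_truth_library(seed=0)
        a = simulate_screen_plates(truth, mir504_condition, NoiseModel(0.02, seed=6))
        b = simulate_screen_plates(truth, mir504_condition, NoiseModel(0.02, seed=6))
        assert [w.signal for w in a] == [w.signal for w in b]

    @pytest.mark.parametrize("preset,ic50", [
        ("mir504", 70.3), ("premir504", 56.2), ("mir142", 95.7), ("mir335", 117.4),
    ])
    def test_control_plates_pass_z_threshold(self, preset, ic50):
        cond = PRESETS[preset]
        kd_neo = competitor_kd_for_ic50(cond, ic50)
        plate = simulate_control_plate(cond, kd_neo, NoiseModel(cv=0.02, seed=13))
        pos = [w.signal for w in plate.by_role("controls", "positive")]
        neg = [w.signal for w in plate.by_role("controls", "negative")]
        assert zfactor(pos, neg).z > 0.5


class TestIc50Inversion:
    def test_round_trip(self, mir504_condition):
        kd = competitor_kd_for_ic50(mir504_condition, 70.3)
        assert noiseless_ic50(mir504_condition, kd) == pytest.approx(70.3, rel=1e-6)

    def test_ic50_monotone_in_kd(self, mir504_condition):
        vals = [noiseless_ic50(mir504_condition, kd) for kd in (0.1, 1.0, 10.0)]
        assert vals == sorted(vals)


class TestBulgeCounting:
    def test_hairpin_only(self):
        assert count_bulge_regions("((((....))))") == 0

    def test_symmetric_internal_loop(self):
        assert count_bulge_regions("(((.(((....))).)))") == 1

    def test_single_one_base_bulge(self):
        assert count_bulge_regions("((((((....)).))))") == 1

    def test_two_separate_bulges(self):
        assert count_bulge_regions("(((.((.((...)).)).)))") == 2

    def test_exterior_dangles_excluded(self):
        assert count_bulge_regions("..((((....))))..") == 0

    def test_duplex_strand_break_not_a_loop(self):
        assert count_bulge_regions("((((&))))") == 0

    def test_duplex_with_internal_loop(self):
        assert count_bulge_regions("((.((&)).))") == 1

    def test_duplex_overhangs_excluded(self):
        assert count_bulge_regions("((((..&..))))") == 0

    def test_unbalanced_reports_position(self):
        with pytest.raises(ParseError) as err:
            count_bulge_regions("(((...))")
        assert err.value.position is not None
        with pytest.raises(ParseError):
            count_bulge_regions("((...)))")

    def test_invalid_character(self):
        with pytest.raises(ParseError, match="position 2"):
            count_bulge_regions("((x))")

    def test_multiloop_counts_each_run(self):
        # two helices branching from one loop with unpaired spacers
        assert count_bulge_regions("((..((...))..((...))..))") == 3
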