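import numpy as np
import pytest

from gradientscape.calibration import HXT7_PEAK_MM, make_default_panel
from gradientscape.reconstruction import (
    FluorescenceLandscape,
    LandscapeFeature,
    NoTransitionError,
    ReconstructionError,
    align_landscapes,
    classify_phases,
    find_peak_position,
    find_transition_position,
    reconstruct_gradient,
)
from gradientscape.synth import SyntheticScenario, generate_fluorescence_landscape
from gradientscape.units import percent_to_millimolar


def relative_error(rec, profile):
    m = rec.valid_mask
    truth = profile.interpolate(rec.positions_um[m])
    ok = truth > 0
    return np.abs(rec.concentrations_mM[m][ok] - truth[ok]) / truth[ok]


class TestFindPeak:
    def test_triangle_profile_apex(self):
        y = np.arange(0, 800, 10.0)
        f = np.where(y <= 400, y, 800 - y) / 400.0
        ls = FluorescenceLandscape(y, f)
        feat = find_peak_position(ls, smoothing_window_bins=1)
        assert feat.kind == "peak"
        assert feat.position_um == pytest.approx(400.0, abs=10.0)

    def test_monotone_landscape_flagged_boundary(self):
        y = np.arange(0, 800, 10.0)
        ls = FluorescenceLandscape(y, np.linspace(1.0, 0.1, y.size))
        feat = find_peak_position(ls)
        assert feat.note == "boundary_peak"

    def test_synthetic_hxt7_peak_matches_gradient_crossing(self, scenario_clean):
        """Closed loop: the peak sits where the gradient crosses 0.89 mM."""
        ls = generate_fluorescence_landscape(scenario_clean, "HXT7")
        feat = find_peak_position(ls)
        prof = scenario_clean.glucose_profile
        crossing = prof.positions_um[np.argmax(prof.concentrations_mM
                                               < HXT7_PEAK_MM)]
        bin_width = ls.positions_um[1] - ls.positions_um[0]
        assert abs(feat.position_um - crossing) <= bin_width

    def test_peak_position_non_decreasing_in_c0(self):
        """Higher external glucose pushes the low-glucose peak deeper."""
        positions = []
        for pct in (0.25, 0.5, 1.0, 2.0):
            sc = SyntheticScenario(seed=9, noise_cv=0.0, perdurance_um=0.0,
                                   c0_mM=percent_to_millimolar(pct))
            ls = generate_fluorescence_landscape(sc, "HXT7")
            positions.append(find_peak_position(ls).position_um)
        assert all(a <= b for a, b in zip(positions, positions[1:]))

    def test_needs_five_bins(self):
        with pytest.raises(ValueError):
            find_peak_position(FluorescenceLandscape(
                np.array([0.0, 10, 20]), np.array([1.0, 2, 1])))


class TestFindTransition:
    def test_ideal_step_at_300(self):
        y = np.arange(5.0, 800, 10.0)
        f = np.where(y < 300, 1.0, 0.0)
        ls = FluorescenceLandscape(y, f)
        feat = find_transition_position(ls)
        assert feat.kind == "transition"
        assert feat.position_um == pytest.approx(300.0, abs=5.0)

    def test_noisy_logistic_midpoint_recovered(self):
        rng = np.random.default_rng(11)
        y = np.arange(5.0, 800, 10.0)
        clean = 0.1 + 0.9 / (1 + np.exp(-(y - 420.0) / 30.0))
        ls = FluorescenceLandscape(y, clean * rng.normal(1.0, 0.05, y.size),
                                   spread_au=np.full(y.size, 0.02))
        feat = find_transition_position(ls)
        assert feat.position_um == pytest.approx(420.0, abs=10.0)

    def test_hxt1_shallow_transition_at_low_glucose(self):
        sc = SyntheticScenario(seed=13, c0_mM=percent_to_millimolar(1.0))
        ls = generate_fluorescence_landscape(sc, "HXT1")
        feat = find_transition_position(ls)
        assert feat.position_um < 400.0

    def test_hxt1_no_transition_at_high_glucose(self):
        """At 8% glucose floods the chamber and HXT1 stays high throughout."""
        sc = SyntheticScenario(seed=13, c0_mM=percent_to_millimolar(8.0))
        ls = generate_fluorescence_landscape(sc, "HXT1")
        with pytest.raises(NoTransitionError):
            find_transition_position(ls)

    def test_flat_landscape_below_noise_rejected(self):
        y = np.arange(5.0, 800, 10.0)
        ls = FluorescenceLandscape(y, np.full(y.size, 0.5),
                                   spread_au=np.full(y.size, 0.3))
        with pytest.raises(NoTransitionError):
            find_transition_position(ls)


class TestReconstructGradient:
    def test_noiseless_recovery_within_2_percent(self, scenario_clean):
        """Closed loop: the inferred C(y) matches the generating gradient."""
        ls = generate_fluorescence_landscape(scenario_clean, "HXT7")
        rec = reconstruct_gradient(ls, scenario_clean.panel["HXT7"])
        assert relative_error(rec, scenario_clean.glucose_profile).max() < 0.02

    def test_front_anchor_is_exact(self, scenario_clean):
        ls = generate_fluorescence_landscape(scenario_clean, "HXT7")
        rec = reconstruct_gradient(ls, scenario_clean.panel["HXT7"])
        assert rec.positions_um[0] == 0.0
        assert rec.concentrations_mM[0] == scenario_clean.c0_mM

    def test_concentrations_bounded_and_monotone_on_valid_region(self, scenario_clean):
        ls = generate_fluorescence_landscape(scenario_clean, "HXT7")
        rec = reconstruct_gradient(ls, scenario_clean.panel["HXT7"])
        c = rec.concentrations_mM[rec.valid_mask]
        assert np.all(c <= scenario_clean.c0_mM + 1e-6)
        assert np.all(c >= HXT7_PEAK_MM - 1e-6)
        assert np.all(np.diff(c) <= 1e-6)

    def test_beyond_peak_marked_invalid(self, scenario_clean):
        ls = generate_fluorescence_landscape(scenario_clean, "HXT7")
        rec = reconstruct_gradient(ls, scenario_clean.panel["HXT7"])
        deeper = rec.positions_um > rec.valid_to_um
        assert deeper.any()
        assert np.all(np.isnan(rec.concentrations_mM[deeper]))

    def test_hxt1_and_hxt7_routes_agree(self, scenario_clean):
        """Independent reporters infer the same gradient (within 10%)."""
        rec7 = reconstruct_gradient(
            generate_fluorescence_landscape(scenario_clean, "HXT7"),
            scenario_clean.panel["HXT7"])
        rec1 = reconstruct_gradient(
            generate_fluorescence_landscape(scenario_clean, "HXT1"),
            scenario_clean.panel["HXT1"])
        common = rec7.valid_mask & rec1.valid_mask
        assert common.sum() > 10
        a = rec7.concentrations_mM[common]
        b = rec1.concentrations_mM[common]
        assert np.max(np.abs(a - b) / np.maximum(a, b)) < 0.10

    def test_noisy_scenarios_median_error_within_5_percent(self):
        """20 seeded scenarios across 0.5-4% w/vol at 5% noise."""
        errors = []
        for i, pct in enumerate([0.5, 1.0, 2.0, 4.0] * 5):
            sc = SyntheticScenario(seed=100 + i, noise_cv=0.05,
                                   c0_mM=percent_to_millimolar(pct))
            ls = generate_fluorescence_landscape(sc, "HXT7")
            rec = reconstruct_gradient(ls, sc.panel["HXT7"])
            errors.append(relative_error(rec, sc.glucose_profile))
        assert np.median(np.concatenate(errors)) <= 0.05

    def test_no_interior_peak_is_reconstruction_error(self):
        y = np.arange(5.0, 800, 10.0)
        ls = FluorescenceLandscape(y, np.linspace(1.0, 0.1, y.size),
                                   reporter_name="HXT7", c0_mM=111.0)
        with pytest.raises(ReconstructionError):
            reconstruct_gradient(ls, make_default_panel()["HXT7"])

    def test_csv_roundtrip(self, tmp_path, scenario_clean):
        ls = generate_fluorescence_landscape(scenario_clean, "HXT7")
        path = tmp_path / "landscape.csv"
        ls.to_csv(path)
        back = FluorescenceLandscape.from_csv(path)
        assert back.reporter_name == "HXT7"
        assert back.c0_mM == pytest.approx(scenario_clean.c0_mM)
        assert np.allclose(back.intensities_au, ls.intensities_au)


class TestClassifyPhases:
    def test_single_feature_sets_boundary(self):
        pm = classify_phases([LandscapeFeature("peak", 400.0, 1.0, 1.0)])
        assert pm.boundary_position_um == 400.0
        assert set(pm.labels) == {"phase_I", "phase_II"}

    def test_median_of_features(self):
        feats = [LandscapeFeature("peak", p, 1.0, 1.0)
                 for p in (380.0, 400.0, 500.0)]
        pm = classify_phases(feats)
        assert pm.boundary_position_um == 400.0

    def test_labels_split_at_boundary(self):
        pm = classify_phases([LandscapeFeature("transition", 300.0, 1.0, 1.0)],
                             positions_um=np.arange(0.0, 800, 50))
        assert np.all(pm.labels[pm.positions_um < 300] == "phase_I")
        assert np.all(pm.labels[pm.positions_um >= 300] == "phase_II")

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            classify_phases([])

    def test_default_panel_features_cluster_within_150_um(self, scenario_default):
        """The fermentation/respiration boundary markers line up sharply."""
        feats = []
        for name in ("HXT7", "HXK1", "HXK2"):
            feats.append(find_peak_position(
                generate_fluorescence_landscape(scenario_default, name)))
        for name in ("HXT1", "HXT5", "PDC1", "SDH2"):
            feats.append(find_transition_position(
                generate_fluorescence_landscape(scenario_default, name)))
        positions = [f.position_um for f in feats]
        assert max(positions) - min(positions) <= 150.0


class TestAlignLandscapes:
    def test_single_landscape_normalised(self):
        y = np.arange(5.0, 800, 10.0)
        ls = FluorescenceLandscape(y, np.linspace(0.2, 1.2, y.size),
                                   reporter_name="A", c0_mM=111.0)
        grid = np.linspace(10, 780, 40)
        mat = align_landscapes([ls], grid)
        assert mat.shape == (1, 40)
        vals = mat.loc["A"].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert np.all(np.diff(vals) > 0)  # monotone input stays monotone

    def test_constant_landscape_maps_to_zeros(self):
        y = np.arange(5.0, 800, 10.0)
        ls = FluorescenceLandscape(y, np.full(y.size, 0.7), reporter_name="B")
        mat = align_landscapes([ls], y)
        assert np.allclose(mat.loc["B"], 0.0)

    def test_own_grid_is_identity_after_normalisation(self, scenario_clean):
        ls = generate_fluorescence_landscape(scenario_clean, "HXT7")
        mat = align_landscapes([ls], ls.positions_um)
        f = ls.intensities_au
        expected = (f - f.min()) / (f.max() - f.min())
        assert np.allclose(mat.loc["HXT7"], expected)

    def test_mixed_c0_rejected(self):
        y = np.arange(5.0, 800, 10.0)
        a = FluorescenceLandscape(y, y / 800, reporter_name="A", c0_mM=111.0)
        b = FluorescenceLandscape(y, y / 800, reporter_name="B", c0_mM=55.0)
        with pytest.raises(ValueError):
            align_landscapes([a, b], y)
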