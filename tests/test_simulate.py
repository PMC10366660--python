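"""Synthetic measurement generator: populations, trajectories, contrasts."""

import numpy as np
import pytest
from scipy import stats

from inta.config import ContrastCalibration, InstrumentSpec, OpticalConfig
from inta.mie import scattering_cross_section
from inta.physics import diffusion_from_diameter
from inta.simulate import (
    POPULATION_PRESETS,
    PopulationSpec,
    TrajectorySet,
    sample_population,
    simulate_contrasts,
    simulate_sample,
    simulate_trajectory,
)

OPTICS = OpticalConfig()
CALIB = ContrastCalibration()


class TestPopulationSampling:
    def test_ev_preset_median_and_iqr(self):
        spec = POPULATION_PRESETS["EV"]
        d, _ = sample_population(spec, 100_000, rng=1)
        assert np.median(d) == pytest.approx(97.0, rel=0.02)
        q25, q75 = np.percentile(d, [25, 75])
        assert q25 == pytest.approx(79.0, rel=0.05)
        assert q75 == pytest.approx(120.0, rel=0.05)

    def test_ri_distribution_matches_preset(self):
        spec = POPULATION_PRESETS["VLDL"]
        _, ri = sample_population(spec, 50_000, rng=2)
        assert np.median(ri) == pytest.approx(1.49, abs=0.002)
        q25, q75 = np.percentile(ri, [25, 75])
        assert q25 == pytest.approx(1.45, abs=0.005)
        assert q75 == pytest.approx(1.52, abs=0.005)

    def test_degenerate_iqr_yields_constant_draws(self):
        spec = PopulationSpec("pt", 80.0, (80.0, 80.0), 1.4, (1.4, 1.4), 1.0)
        d, ri = sample_population(spec, 100, rng=3)
        assert np.all(d == 80.0)
        assert np.all(ri == 1.4)

    def test_inverted_iqr_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec("bad", 80.0, (90.0, 70.0), 1.4, (1.39, 1.41), 1.0)

    def test_median_outside_iqr_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec("bad", 200.0, (79.0, 120.0), 1.4, (1.39, 1.41), 1.0)

    def test_fixed_seed_reproduces_draws(self):
        spec = POPULATION_PRESETS["ULDL"]
        a = sample_population(spec, 1000, rng=42)
        b = sample_population(spec, 1000, rng=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_ri_truncated_at_medium_index(self):
        spec = PopulationSpec("low", 80.0, (70.0, 90.0), 1.34, (1.33, 1.35), 1.0)
        _, ri = sample_population(spec, 20_000, rng=4, medium_ri=OPTICS.medium_ri)
        assert ri.min() >= OPTICS.medium_ri


class TestTrajectorySimulation:
    def test_immobile_particle_never_leaves(self):
        # enormous viscosity drives D -> 0: full-duration trajectory
        optics = OpticalConfig(viscosity_Pa_s=1e6)
        instr = InstrumentSpec(duration_s=0.1)
        traj = simulate_trajectory(100.0, optics, instr, rng=5)
        assert len(traj) == int(0.1 * instr.frame_rate_hz)

    def test_step_variance_matches_stokes_einstein(self):
        instr = InstrumentSpec(duration_s=0.2)
        D = float(diffusion_from_diameter(100.0, OPTICS))
        rng = np.random.default_rng(6)
        sq, n = 0.0, 0
        for _ in range(500):
            traj = simulate_trajectory(100.0, OPTICS, instr, rng)
            if len(traj) < 2:
                continue
            dx = np.diff(traj.positions_um[:, 0])
            sq += np.sum(dx**2)
            n += len(dx)
        expected = 2 * D * instr.dt_s
        se = expected * np.sqrt(2.0 / n)  # chi-square relative error
        assert abs(sq / n - expected) < 3 * se

    def test_faster_particles_escape_sooner(self):
        instr = InstrumentSpec(duration_s=0.3)
        rng = np.random.default_rng(7)
        med_len = {}
        for d in (40.0, 200.0):
            lens = [
                len(simulate_trajectory(d, OPTICS, instr, rng)) for _ in range(300)
            ]
            med_len[d] = np.median(lens)
        assert med_len[40.0] < med_len[200.0]

    def test_positions_stay_inside_fov(self):
        instr = InstrumentSpec(duration_s=0.2)
        rng = np.random.default_rng(8)
        for _ in range(50):
            traj = simulate_trajectory(60.0, OPTICS, instr, rng)
            assert np.all(traj.positions_um >= 0)
            assert np.all(traj.positions_um <= instr.fov_side_um)


class TestContrasts:
    def test_noise_free_contrast_is_calibrated_amplitude(self):
        sigma = scattering_cross_section(100.0, 1.40, OPTICS)
        c = simulate_contrasts(100.0, 1.40, CALIB, OPTICS, 20, 0.0, rng=9)
        np.testing.assert_allclose(c, CALIB.amplitude * np.sqrt(sigma))

    def test_index_matched_particle_is_invisible(self):
        c = simulate_contrasts(100.0, OPTICS.medium_ri, CALIB, OPTICS, 10, 0.0, rng=10)
        np.testing.assert_allclose(c, 0.0)

    def test_empirical_noise_sd(self):
        c = simulate_contrasts(100.0, 1.40, CALIB, OPTICS, 10_000, 2e-3, rng=11)
        assert np.std(c) == pytest.approx(2e-3, rel=0.05)


class TestSampleSimulation:
    def test_single_population_labels(self, instr):
        ts = simulate_sample(
            [POPULATION_PRESETS["EV"]], instr, OPTICS, CALIB, seed=12, n_expected=50
        )
        labels = {t.truth["label"] for t in ts.trajectories}
        assert labels == {"EV"}

    def test_mixture_ratio_within_binomial_ci(self, instr):
        ev = POPULATION_PRESETS["EV"]
        three_to_one = [
            PopulationSpec("EV", ev.size_median_nm, ev.size_iqr_nm, ev.ri_median, ev.ri_iqr, 3.0),
            PopulationSpec("VLDL", 46.0, (41.0, 52.0), 1.49, (1.45, 1.52), 1.0),
        ]
        ts = simulate_sample(three_to_one, instr, OPTICS, CALIB, seed=13, n_expected=4000)
        n_ev = sum(t.truth["label"] == "EV" for t in ts.trajectories)
        n = len(ts)
        lo, hi = stats.binom.interval(0.99, n, 0.75)
        assert lo <= n_ev <= hi

    def test_label_proportions_goodness_of_fit(self, instr):
        pops = [
            PopulationSpec("A", 80.0, (70.0, 90.0), 1.4, (1.39, 1.41), 5.0),
            PopulationSpec("B", 80.0, (70.0, 90.0), 1.4, (1.39, 1.41), 3.0),
            PopulationSpec("C", 80.0, (70.0, 90.0), 1.4, (1.39, 1.41), 2.0),
        ]
        ts = simulate_sample(pops, instr, OPTICS, CALIB, seed=14, n_expected=10_000)
        counts = {"A": 0, "B": 0, "C": 0}
        for t in ts.trajectories:
            counts[t.truth["label"]] += 1
        n = len(ts)
        chi2 = stats.chisquare(
            [counts["A"], counts["B"], counts["C"]], [0.5 * n, 0.3 * n, 0.2 * n]
        )
        assert chi2.pvalue > 0.01

    def test_all_zero_concentrations_rejected(self, instr):
        pop = PopulationSpec("none", 80.0, (70.0, 90.0), 1.4, (1.39, 1.41), 0.0)
        with pytest.raises(ValueError):
            simulate_sample([pop], instr, OPTICS, CALIB, seed=15)

    def test_csv_round_trip_is_byte_identical(self, instr, tmp_path):
        args = ([POPULATION_PRESETS["VLDL"]], instr, OPTICS, CALIB)
        out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate_sample(*args, seed=16, n_expected=30).to_csv(out1)
        simulate_sample(*args, seed=16, n_expected=30).to_csv(out2)
        assert out1.read_bytes() == out2.read_bytes()
        sidecar1 = out1.with_suffix(".csv.json")
        sidecar2 = out2.with_suffix(".csv.json")
        assert sidecar1.read_bytes() == sidecar2.read_bytes()

    def test_csv_reload_preserves_trajectories(self, instr, tmp_path):
        ts = simulate_sample(
            [POPULATION_PRESETS["EV"]], instr, OPTICS, CALIB, seed=17, n_expected=20
        )
        path = tmp_path / "traj.csv"
        ts.to_csv(path)
        back = TrajectorySet.from_csv(path)
        assert len(back) == sum(1 for t in ts.trajectories if len(t) > 0)
        orig = {t.particle_id: t for t in ts.trajectories if len(t) > 0}
        for t in back.trajectories:
            np.testing.assert_allclose(
                t.positions_um, orig[t.particle_id].positions_um, atol=1e-8
            )
            assert t.truth["label"] == orig[t.particle_id].truth["label"]
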