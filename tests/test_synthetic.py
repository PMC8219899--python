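"""Generators: planted truth, stationarity, determinism."""

import numpy as np
import pytest
from scipy.stats import chisquare

from phrelay import synthetic as syn
from phrelay.rupture import detect_rupture
from phrelay.thermo import fit_one_site

KT = syn.KB_KJ_MOL_K * 300.0


class TestLangevin:
    def test_harmonic_equipartition(self):
        """Sample variance of a harmonic walker matches kT/stiffness."""
        spec = syn.PotentialSpec("harmonic", {"stiffness": 100.0}, 300.0, 1.0)
        traj, truth = syn.generate_langevin(spec, 1_000_000, 5e-4, seed=11)
        var = traj.values[:, 0].var()
        expected = truth.values["position_variance_nm2"]
        assert var == pytest.approx(expected, rel=0.05)

    def test_zero_temperature_descends_to_minimum(self):
        """T -> 0 reduces the dynamics to gradient descent into the well."""
        spec = syn.PotentialSpec("harmonic", {"stiffness": 50.0, "center": 0.7},
                                 1e-9, 1.0)
        traj, _ = syn.generate_langevin(spec, 2000, 1e-3, seed=0, x0=2.0)
        assert traj.values[-1, 0] == pytest.approx(0.7, abs=1e-6)

    def test_unstable_step_rejected(self):
        spec = syn.PotentialSpec("harmonic", {"stiffness": 1000.0}, 300.0, 1.0)
        with pytest.raises(ValueError, match="unstable"):
            syn.generate_langevin(spec, 100, 1e-3, seed=0)

    def test_double_well_stationary_distribution(self):
        """Position histogram agrees with exp(-U/kT) (chi-square p > 0.01).

        The chain is thinned beyond the slowest relaxation time (the
        interwell exchange, read off the grid oracle) so the counts are
        effectively independent and the chi-square assumptions hold.
        """
        spec = syn.PotentialSpec("double_well_1d",
                                 {"barrier": 1.0 * KT, "half_distance": 1.0})
        dt = 5e-4
        traj, _ = syn.generate_langevin(spec, 1_000_000, dt, seed=21)
        t_slow = syn.grid_relaxation_timescale(spec, dt)
        thin = int(np.ceil(3 * t_slow / dt))
        x = traj.values[::thin, 0]
        edges = np.linspace(-2.0, 2.0, 13)
        observed, _ = np.histogram(x, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        weights = np.exp(-spec.potential(centers) / spec.kT)
        expected = weights / weights.sum() * observed.sum()
        keep = expected > 5
        _, p = chisquare(observed[keep], expected[keep] * observed[keep].sum()
                         / expected[keep].sum())
        assert p > 0.01

    def test_same_seed_bit_identical(self):
        spec = syn.PotentialSpec("double_well_1d",
                                 {"barrier": 3 * KT, "half_distance": 1.0})
        a, _ = syn.generate_langevin(spec, 5000, 5e-4, seed=5)
        b, _ = syn.generate_langevin(spec, 5000, 5e-4, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_triple_well_2d_runs_and_records_truth(self):
        spec = syn.PotentialSpec(
            "triple_well_2d",
            {"confinement": 2.0,
             "wells": [(-1, 0, 4 * KT, 0.4), (1, 0, 4 * KT, 0.4),
                       (0, 1, 3 * KT, 0.4)]})
        traj, truth = syn.generate_langevin(spec, 20_000, 2e-4, seed=3)
        assert traj.feature_names == ["x", "y"]
        assert truth.values["kind"] == "triple_well_2d"
        assert np.isfinite(traj.values).all()


class TestGridOracle:
    def test_timescale_positive_and_barrier_monotone(self):
        """Higher barriers slow the interwell relaxation."""
        t = []
        for barrier in (2 * KT, 4 * KT):
            spec = syn.PotentialSpec("double_well_1d",
                                     {"barrier": barrier, "half_distance": 1.0})
            t.append(syn.grid_relaxation_timescale(spec, 5e-4))
        assert 0 < t[0] < t[1]


class TestRuptureTraces:
    def test_noiseless_trace_max_is_planted_force(self):
        traces, truth = syn.generate_rupture_traces(50.0, 600.0, 0.0, 0.0, 1,
                                                    seed=0)
        assert traces[0].force.max() == pytest.approx(
            truth.values["rupture_forces"][0], rel=1e-3)

    def test_planted_median_matches_ground_truth_list(self):
        traces, truth = syn.generate_rupture_traces(50.0, 600.0, 40.0, 0.0, 40,
                                                    seed=1)
        planted = np.asarray(truth.values["rupture_forces"])
        assert len(traces) == 40
        assert np.median(planted) == pytest.approx(
            np.median(sorted(planted)))

    def test_detector_recovers_planted_forces(self):
        noise = 0.05 * 600.0
        traces, truth = syn.generate_rupture_traces(50.0, 600.0, 40.0, noise,
                                                    40, seed=2)
        planted = truth.values["rupture_forces"]
        for trace, f_true in zip(traces, planted):
            res = detect_rupture(trace)
            assert res.detected
            assert abs(res.rupture_force - f_true) < 2 * noise

    def test_nonpositive_loading_rate_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_rupture_traces(0.0, 600.0, 0.0, 0.0, 1, seed=0)


class TestUnfoldingTimes:
    def test_zero_rate_all_censored(self):
        data, _ = syn.generate_unfolding_times(0.0, 220.0, 30, seed=0)
        assert data.censored.all()
        assert (data.times_ns == 220.0).all()

    def test_half_life_definition(self):
        """With no censoring horizon, half the draws fall below t_half."""
        k = np.log(2) / 100.0
        data, _ = syn.generate_unfolding_times(k, 1e9, 4000, seed=7)
        frac = (data.times_ns <= 100.0).mean()
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_censored_fraction_matches_survival(self):
        k = np.log(2) / 93.0
        expected = np.exp(-220.0 * k)
        n = 60
        data, truth = syn.generate_unfolding_times(k, 220.0, n, seed=9)
        se = np.sqrt(expected * (1 - expected) / n)
        assert truth.values["expected_censored_fraction"] == pytest.approx(expected)
        assert abs(data.censored.mean() - expected) < 3 * se + 1.0 / n


class TestItcThermogram:
    def test_round_trip_recovers_kd(self):
        vols = np.full(20, 2.0)
        table, _ = syn.generate_itc_thermogram(105e-6, -20.0, 1.0, 80e-6,
                                               1.5e-3, vols, 0.0, seed=0)
        fit = fit_one_site(table["heat_ucal"].to_numpy(), 80e-6, 1.5e-3, vols)
        assert fit.kd_molar == pytest.approx(105e-6, rel=0.01)

    def test_zero_enthalpy_gives_zero_heats(self):
        vols = np.full(10, 2.0)
        table, _ = syn.generate_itc_thermogram(1e-4, 0.0, 1.0, 1e-4, 1.5e-3,
                                               vols, 0.0, seed=0)
        assert np.allclose(table["heat_ucal"], 0.0)

    def test_c_value_and_low_c_flag(self):
        vols = np.full(10, 2.0)
        _, truth = syn.generate_itc_thermogram(105e-6, -20.0, 1.0, 80e-6,
                                               1.5e-3, vols, 0.0, seed=0)
        assert truth.values["c_value"] == pytest.approx(80e-6 / 105e-6)
        assert truth.values["low_c"] is True or truth.values["low_c"] == True  # noqa: E712

    def test_zero_cell_volume_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_itc_thermogram(1e-4, -20.0, 1.0, 1e-4, 1.5e-3,
                                        np.full(10, 2.0), 0.0, seed=0,
                                        cell_volume_ul=0.0)


class TestPkaRecords:
    def test_zero_coupling_fraction(self):
        records, _ = syn.generate_pka_records(100, 4.0, 0.5, 0.0, seed=0)
        assert not any(r.coupled for r in records)

    def test_zero_sd_collapses_distribution(self):
        records, _ = syn.generate_pka_records(50, 4.0, 0.0, 0.0, seed=0)
        vals = [r.pka for r in records]
        assert np.std(vals) == 0.0
        assert vals[0] == 4.0

    def test_coupled_records_carry_alternatives(self):
        records, truth = syn.generate_pka_records(200, 4.0, 0.5, 0.74, seed=3,
                                                  coupling_mean=6.4,
                                                  coupling_sd=0.7)
        coupled = [r for r in records if r.coupled]
        assert all(r.partner and r.alternative_a is not None
                   and r.alternative_b is not None for r in coupled)
        frac = truth.values["coupled_frames"] / 200
        assert abs(frac - 0.74) < 3 * np.sqrt(0.74 * 0.26 / 200)


class TestHbondToy:
    def test_scheduled_occupancies_and_labels_recorded(self):
        schedule = {0: {"b": 1.0}, 1: {"b": 0.0}}
        traj, truth = syn.generate_hbond_toy_trajectory(schedule, 500, seed=0)
        labels = truth.values["labels"]
        assert len(labels) == 500
        assert set(np.unique(labels)) <= {0, 1}

    def test_occupancy_bounds_validated(self):
        with pytest.raises(ValueError):
            syn.generate_hbond_toy_trajectory({0: {"b": 1.5}}, 10, seed=0)
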