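"""Synthetic generators: determinism, ground-truth fidelity, invariants."""

import numpy as np
import pytest

from gillwave.conditioning import ECG_FILTER, bandpass, segment_signal, standardize
from gillwave.events import ECG_PEAKS, detect_peaks
from gillwave.kinematics import default_grid
from gillwave.mixedmodel import log_concentration
from gillwave.synth import (
    CohortSimSpec,
    EcgSimSpec,
    VentilatorySimSpec,
    gen_array_recording,
    gen_cohort_indices,
    gen_ecg,
    gen_restraint_cohort,
    gen_trajectory,
    gen_ventilatory,
)


class TestDeterminism:
    def test_ventilatory_bit_identical(self):
        a, _ = gen_ventilatory(VentilatorySimSpec(duration_s=10.0, seed=5))
        b, _ = gen_ventilatory(VentilatorySimSpec(duration_s=10.0, seed=5))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_ecg_bit_identical(self):
        a, ta = gen_ecg(EcgSimSpec(duration_s=10.0, seed=5))
        b, tb = gen_ecg(EcgSimSpec(duration_s=10.0, seed=5))
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(ta["beat_times_s"], tb["beat_times_s"])

    def test_trajectory_and_cohort_bit_identical(self):
        t1 = gen_trajectory(duration_s=10.0, seed=2)
        t2 = gen_trajectory(duration_s=10.0, seed=2)
        np.testing.assert_array_equal(t1.x_mm, t2.x_mm)
        c1, _ = gen_cohort_indices(CohortSimSpec(seed=9))
        c2, _ = gen_cohort_indices(CohortSimSpec(seed=9))
        assert c1.equals(c2)


class TestGenVentilatory:
    def test_periodic_when_cv_zero(self):
        rec, truth = gen_ventilatory(
            VentilatorySimSpec(mean_freq_hz=3.0, interval_cv=0.0, noise_sd=0.0, duration_s=10.0, seed=0)
        )
        iv = np.diff(truth["event_times_s"])
        np.testing.assert_allclose(iv, 1.0 / 3.0, atol=1e-9)

    def test_interval_cv_converges(self):
        # empirical CV of the generated event train approaches the spec value
        spec = VentilatorySimSpec(mean_freq_hz=3.0, interval_cv=0.26, duration_s=600.0, seed=1)
        _, truth = gen_ventilatory(spec)
        iv = np.diff(truth["event_times_s"])
        assert np.std(iv, ddof=1) / iv.mean() == pytest.approx(0.26, rel=0.05)
        assert 1.0 / iv.mean() == pytest.approx(3.0, rel=0.05)

    def test_noise_dominates_limit(self):
        rec, _ = gen_ventilatory(
            VentilatorySimSpec(mean_freq_hz=3.0, noise_sd=1e4, duration_s=5.0, seed=2)
        )
        # signal is swamped: amplitude is essentially the noise level
        assert rec.samples.std() == pytest.approx(1e4, rel=0.05)


class TestGenEcg:
    def test_beats_recovered_exactly_when_clean(self):
        # segment 1 avoids both the filter startup transient and the
        # half-rendered beat at the recording onset
        rec, truth = gen_ecg(EcgSimSpec(beat_cv=0.0, noise_sd=0.0, duration_s=15.0, seed=3))
        x = bandpass(rec.samples[0], rec.rate_hz, ECG_FILTER)
        z = standardize(segment_signal(x, rec.rate_hz)[1])
        ev = detect_peaks(z, ECG_PEAKS)
        tb = truth["beat_times_s"]
        true_seg = tb[(tb >= 5.0) & (tb < 10.0)]
        # every true beat matched to +-1 sample
        assert ev.n_peaks == len(true_seg)
        np.testing.assert_allclose(ev.peak_times_s, true_seg, atol=1.5 / rec.rate_hz)

    def test_width_guard(self):
        with pytest.raises(Exception):
            EcgSimSpec(rate_bps=4.0, r_wave_width_s=0.1)


class TestGenTrajectory:
    def test_positions_inside_tank(self):
        traj = gen_trajectory(duration_s=60.0, seed=4)
        assert not traj.out_of_bounds().any()

    def test_zero_speed_is_stationary(self):
        traj = gen_trajectory(duration_s=10.0, mean_speed_mm_s=0.0, seed=5)
        assert np.ptp(traj.x_mm) == 0.0 and np.ptp(traj.y_mm) == 0.0

    def test_commanded_speed_recovered(self):
        from gillwave.kinematics import average_speed

        speeds = []
        for seed in range(5):
            traj = gen_trajectory(duration_s=100.0, mean_speed_mm_s=27.7, seed=seed)
            speeds.extend(average_speed(traj, duration_s=100.0))
        assert np.nanmean(speeds) == pytest.approx(27.7, rel=0.1)


class TestGenArrayRecording:
    def test_fish_atop_electrode(self):
        grid = default_grid()
        k = 60
        n = 200
        t = np.arange(n) / 29.97
        from gillwave.kinematics import Trajectory

        traj = Trajectory(t, np.full(n, grid.positions_mm[k, 0]), np.full(n, grid.positions_mm[k, 1]))
        src, _ = gen_ventilatory(VentilatorySimSpec(duration_s=5.0, noise_sd=0.0, seed=6))
        rec = gen_array_recording(traj, src, grid, attenuation_scale_mm=30.0, noise_sd=0.0)
        np.testing.assert_allclose(rec.samples[k], src.samples[0], atol=1e-12)
        assert rec.n_channels == 126

    def test_infinite_attenuation_scale_equalizes_channels(self):
        grid = default_grid()
        traj = gen_trajectory(duration_s=5.0, seed=7)
        src, _ = gen_ventilatory(VentilatorySimSpec(duration_s=5.0, noise_sd=0.0, seed=8))
        rec = gen_array_recording(traj, src, grid, attenuation_scale_mm=1e12, noise_sd=0.0)
        np.testing.assert_allclose(rec.samples, np.broadcast_to(src.samples[0], rec.samples.shape), rtol=1e-9)


class TestGenCohortIndices:
    def test_row_bookkeeping(self):
        table, _ = gen_cohort_indices(CohortSimSpec(seed=0))
        assert len(table) == 480
        assert table.groupby("concentration_mg_per_l").size().eq(120).all()
        assert table.groupby("individual_id").size().eq(24).all()

    def test_exact_line_when_noise_free(self):
        spec = CohortSimSpec(sd_by_C=0.0, sd_by_Cj=0.0, residual_sd=0.0, seed=1)
        table, truth = gen_cohort_indices(spec)
        C = log_concentration(table["concentration_mg_per_l"].to_numpy())
        np.testing.assert_allclose(table["value"], truth["beta1"] * C + truth["beta0"], atol=1e-12)

    def test_marginal_variance_decomposition(self):
        # at 10k draws per dose the within-dose variance matches
        # sd_Cj^2 + residual^2 within 5%
        spec = CohortSimSpec(n_individuals_per_dose=400, n_segments=25, seed=2)
        table, truth = gen_cohort_indices(spec)
        within = table.groupby("concentration_mg_per_l")["value"].var(ddof=1)
        expect = truth["sd_by_Cj"] ** 2 + truth["residual_sd"] ** 2
        np.testing.assert_allclose(within, expect, rtol=0.05)

    def test_invalid_sd_for_model(self):
        with pytest.raises(Exception):
            CohortSimSpec(generating_model_id=1, sd_by_Cj=0.5)


class TestCohortBuilders:
    def test_restraint_cohort_shapes(self):
        recs, meta, truth = gen_restraint_cohort(seed=0, duration_s=10.0, n_per_dose=2)
        assert len(recs) == 8 and len(meta) == 8
        assert sum(not m.survived_72h for m in meta) == 1
        excluded = [m for m in meta if not m.survived_72h][0]
        assert excluded.concentration_mg_per_l == 50.0
        one = next(iter(recs.values()))
        assert one["ventilatory"].rate_hz == 100.0
        assert one["ecg"].rate_hz == 1000.0
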