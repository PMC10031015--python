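import numpy as np
import pytest

from gaitgrf import gait_stats as gs
from gaitgrf.dynamics import Wrench


class TestButterworthFilter:
    def test_constant_signal_invariant(self):
        out = gs.butterworth_filter(np.full(300, 100.0), rate=150.0)
        assert np.abs(out - 100.0).max() < 1e-9

    def test_attenuation_at_least_analytic(self):
        rate, f = 1500.0, 60.0
        t = np.arange(6000) / rate
        x = np.sin(2 * np.pi * f * t)
        y = gs.butterworth_filter(x, rate, cutoff=12.0, order=2)
        # forward-backward application squares the magnitude response
        analytic = 1.0 / (1.0 + (f / 12.0) ** 4)
        amp = y[2000:4000].std() * np.sqrt(2)
        assert amp <= analytic * 1.05

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            gs.butterworth_filter(np.zeros(100), rate=1500.0, cutoff=800.0)


class TestDetectEvents:
    def test_clean_step_crossing(self):
        rate = 1000.0
        f = np.where(np.arange(2000) / rate >= 0.5, 400.0, 0.0)
        ev = gs.detect_events(f, rate)
        assert len(ev.ic_times) == 1
        assert ev.ic_times[0] == pytest.approx(0.5, abs=1.5 / rate)

    def test_subthreshold_series_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="never exceeds"):
            ev = gs.detect_events(np.full(100, 10.0), 150.0)
        assert len(ev.ic_times) == 0 and len(ev.to_times) == 0

    def test_noisy_plateau_yields_single_contact(self):
        rate = 1000.0
        t = np.arange(1500) / rate
        f = np.where(t < 0.5, 0.0, 300.0)
        # chattering plateau oscillating about the threshold right after IC
        band = (t >= 0.5) & (t < 0.53)
        f[band] = 20.0 + 2.0 * np.sin(2 * np.pi * 300 * t[band])
        ev = gs.detect_events(f, rate)
        assert len(ev.ic_times) == 1

    def test_alternating_steps(self):
        rate = 1000.0
        t = np.arange(3000) / rate
        f = 200.0 * ((t % 1.0) < 0.6)
        ev = gs.detect_events(f, rate)
        # the series starts loaded, so the first stance has no IC crossing
        assert len(ev.ic_times) == 2 and len(ev.to_times) == 3
        assert len(ev.cycles()) == 1
        assert len(ev.stance_windows()) == 2


class TestTimeNormalize:
    def test_exactly_101_samples_and_linear_exactness(self):
        t = np.arange(200) / 100.0
        y = 3.0 * t + 1.0
        out = gs.time_normalize(y, t, 0.3, 1.7)
        assert out.shape == (101,)
        grid = np.linspace(0.3, 1.7, 101)
        assert np.abs(out - (3.0 * grid + 1.0)).max() < 1e-12

    def test_idempotent_on_own_grid(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=101)
        t = np.linspace(0.0, 1.0, 101)
        out = gs.time_normalize(y, t, 0.0, 1.0)
        assert np.abs(out - y).max() < 1e-12

    def test_window_outside_series_rejected(self):
        t = np.arange(100) / 100.0
        with pytest.raises(ValueError, match="outside"):
            gs.time_normalize(np.zeros(100), t, 0.5, 2.0)


class TestMetricOracles:
    def test_rmsd_identity_and_offset(self):
        a = np.sin(np.linspace(0, 2 * np.pi, 101))
        assert gs.rmsd(a, a) == (0.0, 0.0)
        abs_val, pct = gs.rmsd(a, a + 0.5)
        assert abs_val == pytest.approx(0.5, abs=1e-12)
        assert pct == pytest.approx(50.0, rel=1e-9)

    def test_zero_reference_flags_pct(self):
        with pytest.warns(UserWarning, match="zero"):
            _, pct = gs.rmsd(np.zeros(101), np.ones(101))
        assert np.isnan(pct)

    def test_brute_force_equivalence_100_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = rng.normal(size=(2, 101))
            abs_val, pct = gs.rmsd(a, b)
            brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 101)
            assert abs(abs_val - brute) < 1e-12
            assert abs(pct - 100 * brute / max(abs(x) for x in a)) < 1e-9
            r, _ = gs.pcc_and_category(a, b)
            am, bm = a - a.mean(), b - b.mean()
            brute_r = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
            assert abs(r - brute_r) < 1e-12

    @pytest.mark.parametrize("r,expected", [
        (0.2, "weak"), (0.35, "weak"), (0.36, "moderate"), (0.67, "moderate"),
        (0.68, "strong"), (0.71, "strong"), (0.90, "strong"), (0.91, "excellent"),
        (-1.0, "weak"), (1.0, "excellent"),
    ])
    def test_pcc_categories_at_boundaries(self, r, expected):
        assert gs.pcc_category(r) == expected

    def test_engineered_correlation_recovered(self):
        n = 101
        rng = np.random.default_rng(1)
        a = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        noise = rng.normal(size=n)
        noise -= noise.mean() + a * (a @ noise) / (a @ a)
        noise /= noise.std()
        for r in (0.25, 0.5, 0.8, 0.95):
            b = r * a + np.sqrt(1 - r * r) * noise
            got_r, got_cat = gs.pcc_and_category(a, b)
            assert got_r == pytest.approx(r, abs=1e-9)
            assert got_cat == gs.pcc_category(got_r)

    def test_anticorrelated_is_weak(self):
        a = np.sin(np.linspace(0, 2 * np.pi, 101))
        r, cat = gs.pcc_and_category(a, -a)
        assert r == pytest.approx(-1.0)
        assert cat == "weak"

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r, cat = gs.pcc_and_category(np.ones(101), np.arange(101.0))
        assert np.isnan(r) and cat == "undefined"


class TestXcorr:
    def test_identical_curves(self):
        a = np.sin(np.linspace(0, 2 * np.pi, 101))
        val, lag = gs.xcorr_lag(a, a)
        assert val == pytest.approx(1.0, abs=1e-9)
        assert lag == 0.0

    def test_circular_shift_recovered(self):
        a = np.sin(np.linspace(0, 4 * np.pi, 101))
        b = np.roll(a, 5)
        val, lag = gs.xcorr_lag(a, b)
        assert lag == pytest.approx(5.0, abs=1e-9)

    def test_uncorrelated_noise_low_value(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(20):
            a, b = rng.normal(size=(2, 101))
            val, _ = gs.xcorr_lag(a, b)
            vals.append(val)
        assert max(vals) < 0.5

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b = rng.normal(size=(2, 101))
            val, lag = gs.xcorr_lag(a, b)
            az = (a - a.mean()) / a.std()
            bz = (b - b.mean()) / b.std()
            best_val, best_lag = -np.inf, None
            for L in range(-25, 26):
                v = float(np.mean(np.roll(az, L) * bz))
                if v > best_val + 1e-15 or (abs(v - best_val) <= 1e-15
                                            and abs(L) < abs(best_lag)):
                    best_val, best_lag = v, L
            assert val == pytest.approx(best_val, abs=1e-12)
            assert lag == pytest.approx(best_lag, abs=1e-9)


class TestSPM:
    def test_identical_groups_no_clusters(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 101))
        res = gs.spm_paired_ttest(A, A.copy() + 0.0)
        assert res.clusters == []

    def test_constructed_effect_detected_in_window(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 101))
        B = A + rng.normal(size=(10, 101)) * 0.5
        B[:, 30:51] += 3.0 * 0.5
        res = gs.spm_paired_ttest(A, B, alpha=0.05)
        assert res.clusters, "expected a supra-threshold cluster"
        assert any(s <= 50 and e >= 30 for s, e, _ in res.clusters)
        assert all(0 < p <= 1 for *_, p in res.clusters)

    def test_null_type_one_error_calibrated(self):
        # light calibration run; the full 1000-replicate check is part of
        # the acceptance suite
        rng = np.random.default_rng(2)
        hits = 0
        reps = 200
        for _ in range(reps):
            D = rng.normal(size=(10, 101))
            res = gs.spm_paired_ttest(D, np.zeros_like(D), alpha=0.05)
            hits += bool(res.clusters)
        assert 2 <= hits <= 22  # ~95% band around 10/200

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            gs.spm_paired_ttest(np.zeros((8, 101)), np.zeros((7, 101)))
        with pytest.raises(ValueError, match="at least 5"):
            gs.spm_paired_ttest(np.zeros((3, 101)), np.zeros((3, 101)))

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(20, 101))
        B = A + rng.normal(size=(20, 101))
        r1 = gs.spm_paired_ttest(A, B, n_perm=2000, seed=7)
        r2 = gs.spm_paired_ttest(A, B, n_perm=2000, seed=7)
        assert r1.critical_threshold == r2.critical_threshold


class TestRepresentativeTrial:
    def test_trial_equal_to_mean_wins(self):
        # if the last trial equals the mean of the others, it also equals
        # the mean of all trials (zero RMSD) and must be selected
        rng = np.random.default_rng(4)
        others = [rng.normal(size=101) for _ in range(3)]
        x = np.mean(others, axis=0)
        trials = [{"sagittal": o} for o in others] + [{"sagittal": x}]
        assert gs.representative_trial(trials) == 3

    def test_tie_resolves_to_lowest_index(self):
        t = {"a": np.arange(101.0)}
        assert gs.representative_trial([dict(t), dict(t)]) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        trials = [{"a": rng.normal(size=101), "b": rng.normal(size=101)}
                  for _ in range(5)]
        means = {k: np.mean([t[k] for t in trials], axis=0) for k in ("a", "b")}
        scores = [np.mean([np.sqrt(np.mean((t[k] - means[k]) ** 2))
                           for k in ("a", "b")]) for t in trials]
        assert gs.representative_trial(trials) == int(np.argmin(scores))

    def test_inconsistent_curve_sets_rejected(self):
        with pytest.raises(ValueError, match="identical curve sets"):
            gs.representative_trial([{"a": np.zeros(101)}, {"b": np.zeros(101)}])


class TestGaitFrameAlignment:
    def _wrench(self, rng):
        return Wrench(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)),
                      np.zeros(3))

    def test_walking_along_x_is_identity(self):
        rng = np.random.default_rng(1)
        w = self._wrench(rng)
        out = gs.align_to_gait_frame(w, (3.0, 0.0))
        assert np.abs(out.force - w.force).max() < 1e-9

    def test_walking_along_y_swaps_components(self):
        rng = np.random.default_rng(2)
        w = self._wrench(rng)
        out = gs.align_to_gait_frame(w, (0.0, 2.0))
        assert np.allclose(out.force[:, 0], w.force[:, 1], atol=1e-12)
        assert np.allclose(out.force[:, 1], -w.force[:, 0], atol=1e-12)
        assert np.allclose(out.force[:, 2], w.force[:, 2], atol=1e-12)

    def test_norm_preserved(self):
        rng = np.random.default_rng(3)
        w = self._wrench(rng)
        out = gs.align_to_gait_frame(w, (1.0, -2.0))
        assert np.allclose(np.linalg.norm(out.force, axis=1),
                           np.linalg.norm(w.force, axis=1), atol=1e-12)

    def test_zero_displacement_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="direction"):
            gs.align_to_gait_frame(self._wrench(rng), (0.0, 0.0))
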