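"""Dynamics features: time/geometric/spectral/Poincare/SampEn/DFA."""

import numpy as np
import pytest

import ppgbp as pb
from ppgbp.dynamics import DYNAMICS_NAMES, DynamicsConfig
from ppgbp.errors import InsufficientDataError
from ppgbp.fiducials import IBISeries


def _series(values) -> IBISeries:
    values = np.asarray(values, dtype=float)
    return IBISeries(values, "peaks", np.cumsum(values))


class TestTimeDomain:
    def test_hand_computed_example(self):
        ibi = _series([0.8, 0.85, 0.86, 1.0])
        mean, sdnn, rmssd, nnx, pnnx = pb.time_domain(ibi, min_n=4)
        assert mean == pytest.approx(0.8775)
        # diffs 50, 10, 140 ms; strict > 50 ms excludes the 50 ms one
        assert rmssd == pytest.approx(0.0860, abs=5e-5)
        assert nnx == 1
        assert pnnx == pytest.approx(100 / 3, abs=0.05)

    def test_constant_series(self):
        _, sdnn, rmssd, nnx, _ = pb.time_domain(_series([0.8] * 20))
        assert sdnn == pytest.approx(0.0, abs=1e-12)
        assert rmssd == pytest.approx(0.0, abs=1e-12)
        assert nnx == 0

    def test_alternating_rmssd(self):
        _, _, rmssd, _, _ = pb.time_domain(_series([0.8, 1.0] * 10))
        assert rmssd == pytest.approx(0.2)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            pb.time_domain(_series([0.8] * 5))


class TestGeometric:
    def test_identical_intervals_degenerate_triangle(self):
        prvti, tinn = pb.geometric(_series([0.8] * 100))
        assert prvti == pytest.approx(1.0)
        assert tinn == 0.0

    def test_two_distant_bins(self):
        vals = np.concatenate([np.full(50, 0.6), np.full(50, 1.2)])
        prvti, _ = pb.geometric(_series(vals))
        assert prvti == pytest.approx(2.0)

    def test_uniform_over_k_bins(self):
        bw = 1.0 / 128.0
        k = 5
        vals = np.repeat([(80 + i) * bw + bw / 2 for i in range(k)], 20)
        prvti, _ = pb.geometric(_series(vals))
        assert prvti == pytest.approx(k)

    def test_spread_increases_tinn(self):
        rng = np.random.default_rng(2)
        narrow = _series(0.9 + rng.normal(0, 0.01, 300))
        wide = _series(0.9 + rng.normal(0, 0.05, 300))
        assert pb.geometric(wide)[1] > pb.geometric(narrow)[1]


class TestSpectral:
    def _tone(self, freq, duration=300.0, mean=0.9, amp=0.05):
        times, t = [], 0.0
        while t < duration:
            t += mean
            times.append(t)
        times = np.asarray(times)
        vals = mean + amp * np.sin(2 * np.pi * freq * times)
        return IBISeries(vals, "peaks", times)

    def test_hf_tone_dominates(self):
        lf, hf, ratio = pb.spectral(self._tone(0.25))
        assert hf > 10 * lf
        assert ratio < 0.1

    def test_lf_tone_dominates(self):
        lf, hf, _ = pb.spectral(self._tone(0.10))
        assert lf > 10 * hf

    def test_constant_tachogram_near_zero_power(self):
        lf, hf, ratio = pb.spectral(self._tone(0.25, amp=0.0))
        assert lf < 1e-10 and hf < 1e-10
        assert np.isnan(ratio) or ratio >= 0

    def test_short_span_rejected(self):
        with pytest.raises(InsufficientDataError):
            pb.spectral(self._tone(0.25, duration=30.0))

    def test_two_tone_power_ratio_recovered(self):
        times = np.cumsum(np.full(400, 0.8))
        vals = (0.8 + 0.04 * np.sin(2 * np.pi * 0.10 * times)
                + 0.02 * np.sin(2 * np.pi * 0.25 * times))
        lf, hf, _ = pb.spectral(IBISeries(vals, "peaks", times))
        assert lf / hf == pytest.approx(4.0, rel=0.10)


class TestPoincare:
    def test_constant(self):
        sd1, sd2 = pb.poincare(_series([0.8] * 20))
        assert sd1 == pytest.approx(0.0, abs=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)

    def test_alternating(self):
        sd1, sd2 = pb.poincare(_series([0.8, 1.0] * 5 + [0.8]))
        assert sd1 == pytest.approx(0.2 / np.sqrt(2), abs=1e-9)
        assert sd2 == pytest.approx(0.0, abs=1e-12)

    def test_sd1_identity_with_successive_differences(self):
        rng = np.random.default_rng(3)
        x = 0.9 + rng.normal(0, 0.05, 500)
        sd1, _ = pb.poincare(_series(np.clip(x, 0.4, 1.6)))
        d = np.diff(np.clip(x, 0.4, 1.6))
        assert sd1 ** 2 == pytest.approx(0.5 * np.var(d), abs=1e-12)

    def test_sd1_rmssd_relation(self):
        rng = np.random.default_rng(4)
        x = np.clip(0.9 + rng.normal(0, 0.05, 300), 0.4, 1.6)
        ibi = _series(x)
        sd1, _ = pb.poincare(ibi)
        _, _, rmssd, _, _ = pb.time_domain(ibi)
        d = np.diff(x)
        assert sd1 ** 2 == pytest.approx(
            0.5 * (rmssd ** 2 - np.mean(d) ** 2), abs=1e-12)


def brute_force_sampen(x, m, r):
    """O(n^2) reference counter, straight from the definition."""
    n = len(x)
    A = B = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -np.log(A / B)


class TestSampleEntropy:
    def test_periodic_series_is_zero(self):
        x = np.tile([1.0, 2.0], 10)
        cfg = DynamicsConfig(sampen_r_factor=0.5 / np.std(x))
        assert pb.sample_entropy(x, cfg, min_n=10) == pytest.approx(0.0)

    def test_constant_series_undefined(self):
        assert np.isnan(pb.sample_entropy(np.full(60, 0.8)))

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(7)
        cfg = DynamicsConfig()
        for _ in range(20):
            x = 0.9 + rng.normal(0, 0.05, 60)
            r = cfg.sampen_r_factor * np.std(x)
            expected = brute_force_sampen(x, cfg.sampen_m, r)
            got = pb.sample_entropy(x, cfg)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestDFA:
    def test_white_noise_exponent(self):
        rng = np.random.default_rng(42)
        x = 0.9 + rng.normal(0, 0.05, 1000)
        alpha1, _ = pb.dfa(x)
        assert alpha1 == pytest.approx(0.5, abs=0.1)

    def test_random_walk_exponent(self):
        rng = np.random.default_rng(42)
        x = 5.0 + np.cumsum(rng.normal(0, 0.01, 1000))
        alpha1, _ = pb.dfa(x)
        assert alpha1 == pytest.approx(1.5, abs=0.15)

    def test_vanishing_profile_undefined(self):
        # a constant series has an identically-zero integrated profile, so
        # the detrended fluctuation vanishes and the exponent is undefined
        alpha1, alpha2 = pb.dfa(np.full(1000, 0.9))
        assert np.isnan(alpha1) and np.isnan(alpha2)

    def test_length_rules(self):
        rng = np.random.default_rng(1)
        x = 0.9 + rng.normal(0, 0.05, 150)
        alpha1, alpha2 = pb.dfa(x)
        assert np.isfinite(alpha1) and np.isnan(alpha2)


class TestExtractDynamics:
    def test_clean_subject_all_defined(self, cohort_table_40):
        table, _ = cohort_table_40
        dyn_cols = [c for c in table.columns if c.startswith("dyn_peaks_")]
        assert len(dyn_cols) == 15
        assert not table[dyn_cols].isna().any().any()

    def test_150_interval_record_misses_alpha2_only(self):
        rng = np.random.default_rng(9)
        vec = pb.extract_dynamics(_series(np.clip(
            0.9 + rng.normal(0, 0.05, 150), 0.4, 1.6)))
        assert np.isnan(vec.values["alpha2"])
        assert "alpha2" in vec.missing
        defined = [n for n in DYNAMICS_NAMES if n != "alpha2"]
        assert all(np.isfinite(vec.values[n]) for n in defined)

    def test_schema(self):
        rng = np.random.default_rng(10)
        vec = pb.extract_dynamics(_series(np.clip(
            0.9 + rng.normal(0, 0.05, 400), 0.4, 1.6)))
        assert list(vec.values.keys()) == DYNAMICS_NAMES

    def test_constant_shift_moves_only_mean(self):
        rng = np.random.default_rng(11)
        base = np.clip(0.8 + rng.normal(0, 0.04, 400), 0.4, 1.4)
        times = np.cumsum(base)
        v0 = pb.extract_dynamics(IBISeries(base, "peaks", times)).values
        v1 = pb.extract_dynamics(IBISeries(base + 0.2, "peaks", times)).values
        assert v1["mean_ibi"] == pytest.approx(v0["mean_ibi"] + 0.2, abs=1e-9)
        for name in ("sdnn", "rmssd", "sd1", "sd2", "sampen",
                     "alpha1", "alpha2", "lf", "hf"):
            assert v1[name] == pytest.approx(v0[name], abs=1e-9)

    def test_source_label_does_not_change_features(self):
        rng = np.random.default_rng(12)
        vals = np.clip(0.9 + rng.normal(0, 0.05, 400), 0.4, 1.6)
        vp = pb.extract_dynamics(IBISeries(vals, "peaks", np.cumsum(vals)))
        vt = pb.extract_dynamics(IBISeries(vals, "troughs", np.cumsum(vals)))
        assert vp.values == vt.values
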