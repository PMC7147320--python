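"""Bilateral envelope comparison: averaging, normalization, regression."""

import numpy as np
import pandas as pd
import pytest

from rowemg.cycles import CycleSet
from rowemg.pipeline import analyze_recording
from rowemg.signal_model import SessionError
from rowemg.symmetry import (
    bilateral_stats,
    bilateral_symmetry,
    mean_active_envelope,
    normalize_per_leg,
    union_windows,
)
from rowemg.synth import BurstSpec, SessionSpec, gen_session


def _rows(windows):
    return pd.DataFrame(
        [
            dict(cycle=k, onset_pct=a, silencing_pct=b, duration_pct=b - a,
                 segments=[(a, b)], flag="ok")
            for k, (a, b) in windows.items()
        ]
    )


def _cycles(n, per=1000):
    return CycleSet(
        cycles=tuple((k * per, k * per + 400, (k + 1) * per) for k in range(n)),
        fs=1000.0,
    )


class TestMeanActiveEnvelope:
    def test_identical_cycles_average_to_any_single_cycle(self):
        cs = _cycles(3)
        base = np.sin(np.linspace(0, np.pi, 1000)) ** 2
        env = np.tile(base, 3)
        rows = _rows({k: (10.0, 90.0) for k in range(3)})
        mean, mat = mean_active_envelope(env, cs, rows, N=100)
        assert mean.shape == (100,)
        assert mat.shape == (3, 100)
        np.testing.assert_allclose(mean, mat[0], atol=1e-9)

    def test_output_length_is_always_100(self):
        cs = _cycles(2)
        env = np.abs(np.sin(np.arange(2000) / 55.0))
        rows = _rows({0: (5.0, 60.0), 1: (12.0, 70.0)})
        mean, _ = mean_active_envelope(env, cs, rows, N=100)
        assert mean.shape == (100,)

    def test_time_shifted_copies_average_to_same_shape(self):
        # two cycles holding the same waveform at shifted positions:
        # extracting each cycle's own active window recovers the shape
        cs = _cycles(2)
        wave = np.sin(np.linspace(0, np.pi, 400)) ** 2
        env = np.zeros(2000)
        env[100:500] = wave          # cycle 0: 10-50%
        env[1300:1700] = wave        # cycle 1: 30-70%
        rows = _rows({0: (10.0, 50.0), 1: (30.0, 70.0)})
        mean, mat = mean_active_envelope(env, cs, rows, N=100)
        np.testing.assert_allclose(mat[0], mat[1], atol=0.01)
        np.testing.assert_allclose(
            mean, np.interp(np.linspace(0, 399, 100), np.arange(400), wave), atol=0.01
        )

    def test_no_valid_cycles_is_an_error(self):
        cs = _cycles(2)
        rows = _rows({})
        with pytest.raises(SessionError):
            mean_active_envelope(np.ones(2000), cs, rows)


class TestNormalizePerLeg:
    def test_scaling_one_leg_leaves_normalized_curve_unchanged(self):
        curve = np.array([0.2, 0.5, 1.0, 0.7])
        mat = np.vstack([curve, 0.9 * curve])
        a = normalize_per_leg(curve, mat)
        b = normalize_per_leg(2.0 * curve, 2.0 * mat)
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert a.max() == pytest.approx(1.0)

    def test_cycle_max_mode_keeps_normalized_mean_at_most_one(self):
        mat = np.array([[0.1, 0.9, 0.3], [0.2, 1.4, 0.2]])
        mean = mat.mean(axis=0)
        out = normalize_per_leg(mean, mat, mode="cycle_max")
        assert out.max() <= 1.0
        assert out.max() == pytest.approx(mean.max() / mat.max())

    def test_zero_maximum_is_an_error(self):
        with pytest.raises(SessionError):
            normalize_per_leg(np.zeros(5))


class TestBilateralStats:
    def test_identity_gives_unit_slope_and_correlation(self):
        x = np.linspace(0.1, 1.0, 50)
        res = bilateral_stats(x, x)
        assert res.R == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.degenerate
        assert res.slope_p_vs_unity == 1.0

    def test_half_slope_with_small_noise_detected(self, rng):
        # closed-form OLS on left = 0.5*right + noise; the unity test
        # must reject decisively
        right = np.linspace(0.0, 1.0, 100)
        left = 0.5 * right + rng.normal(0, 0.01, 100)
        res = bilateral_stats(left, right)
        assert res.slope == pytest.approx(0.5, abs=0.02)
        assert res.slope_p_vs_unity < 0.01

    def test_r_invariant_under_positive_affine_rescaling(self, rng):
        l = rng.random(60)
        r = l + rng.normal(0, 0.1, 60)
        base = bilateral_stats(l, r)
        scaled = bilateral_stats(3.0 * l + 2.0, 0.5 * r + 1.0)
        assert scaled.R == pytest.approx(base.R, rel=1e-9)

    def test_slope_product_bounded_by_r_squared_identity(self, rng):
        # slope(l|r) * slope(r|l) = R^2 <= 1, with equality iff |R| = 1
        l = rng.random(80)
        r = 0.7 * l + rng.normal(0, 0.05, 80)
        a = bilateral_stats(l, r).slope
        b = bilateral_stats(r, l).slope
        R = bilateral_stats(l, r).R
        assert a * b == pytest.approx(R**2, rel=1e-9)
        assert a * b <= 1.0

    def test_zero_variance_is_an_error(self):
        with pytest.raises(SessionError):
            bilateral_stats(np.ones(10), np.linspace(0, 1, 10))


class TestEndToEnd:
    def test_side_gain_two_gives_unit_slope_and_high_R(self):
        spec = SessionSpec(
            spm=24, n_cycles=30, side_gain={"left": 1.0, "right": 2.0},
            bursts={("soleus", s): BurstSpec(5.0, 45.0, peak_uv=100.0) for s in ("left", "right")},
            seed=33,
        )
        rec, rest, _ = gen_session(spec)
        res = analyze_recording(rec, rest)
        sym = res.symmetry[0]
        assert sym.R > 0.99
        assert sym.slope == pytest.approx(1.0, abs=0.05)
        assert sym.slope_p_vs_unity > 0.05

    def test_normalized_curves_agree_pointwise_despite_gain(self):
        spec = SessionSpec(
            spm=24, n_cycles=30, side_gain={"left": 1.0, "right": 2.0},
            bursts={("soleus", s): BurstSpec(5.0, 45.0, peak_uv=100.0) for s in ("left", "right")},
            seed=34,
        )
        rec, rest, _ = gen_session(spec)
        res = analyze_recording(rec, rest)
        l, r = res.sym_curves["soleus"]
        # pointwise agreement at the few-percent level: RMS within 5%,
        # isolated excursions (peak-region averaging noise) within 12%
        assert np.sqrt(np.mean((l - r) ** 2)) < 0.05
        assert np.abs(l - r).max() < 0.12

    def test_union_window_covers_both_sides(self):
        rows_l = _rows({0: (10.0, 40.0), 1: (12.0, 42.0)})
        rows_r = _rows({0: (8.0, 38.0), 2: (5.0, 30.0)})
        win = union_windows(rows_l, rows_r)
        assert set(win) == {0}
        assert win[0] == (8.0, 40.0)

    def test_slope_converges_to_unity_as_noise_vanishes(self):
        # same timing, any side gain, rest noise shrinking: the slope
        # estimate must approach 1
        dev = []
        for rest_uv in (6.0, 1.0):
            spec = SessionSpec(
                spm=24, n_cycles=10, jitter_pct=0, timing_jitter_pct=0,
                rest_noise_uv=rest_uv, side_gain={"left": 1.0, "right": 1.7},
                bursts={("soleus", s): BurstSpec(5.0, 45.0, peak_uv=400.0) for s in ("left", "right")},
                seed=35,
            )
            rec, rest, _ = gen_session(spec)
            res = analyze_recording(rec, rest)
            dev.append(abs(res.symmetry[0].slope - 1.0))
        assert dev[1] < dev[0]
        assert dev[1] < 0.02
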