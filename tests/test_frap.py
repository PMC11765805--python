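"""FRAP normalization steps (a)-(d), decomposition, exchange rates."""

import numpy as np
import pytest

from forkdyn.frap import (
    FRAPRecord,
    analyze_frap,
    bound_recovery,
    exchange_rate,
    fit_two_component,
    normalize_frap,
)

LN2 = np.log(2)


def synthetic_record(a_f=0.5, k_f=0.1, a_s=0.35, k_s=LN2 / 149.0, depth=0.3,
                     diffuse=20.0, focus=60.0, bg=5.0, n_pre=6, span_s=300,
                     acq_bleach=0.0):
    """Analytic ROI traces for a bleach + two-component recovery."""
    times = np.arange(-n_pre, span_s + 1, dtype=float)
    t_post = np.clip(times, 0, None)
    r = a_f * (1 - np.exp(-k_f * t_post)) + a_s * (1 - np.exp(-k_s * t_post))
    factor = np.where(times >= 0, depth + (1 - depth) * r, 1.0)
    bleached = bg + diffuse + focus * factor
    unbleached = np.full_like(times, bg + diffuse + 0.8 * focus)
    if acq_bleach > 0:
        decay = np.exp(-acq_bleach * np.arange(len(times)))
        bleached = bg + (bleached - bg) * decay
        unbleached = bg + (unbleached - bg) * decay
    return times, bleached, unbleached, np.full_like(times, bg), n_pre


class TestNormalization:
    def test_prebleach_mean_one_and_first_postbleach_zero(self):
        rec = normalize_frap(*synthetic_record())
        pre = rec.normalized[rec.bleach_frame - 6 : rec.bleach_frame]
        assert pre.mean() == pytest.approx(1.0, abs=1e-9)
        assert rec.normalized[rec.bleach_frame] == 0.0

    def test_normalized_curve_equals_true_recovery(self):
        """The diffuse pedestal and bleach depth cancel exactly."""
        a_f, k_f, a_s, k_s = 0.5, 0.1, 0.35, LN2 / 149.0
        rec = normalize_frap(*synthetic_record(a_f, k_f, a_s, k_s))
        t, y = rec.post_bleach()
        expected = a_f * (1 - np.exp(-k_f * t)) + a_s * (1 - np.exp(-k_s * t))
        assert np.allclose(y, expected, atol=1e-9)

    def test_idempotent_on_an_already_normalized_record(self):
        rec = normalize_frap(*synthetic_record())
        again = normalize_frap(
            rec.times, rec.normalized, np.ones_like(rec.normalized),
            np.zeros_like(rec.normalized), rec.bleach_frame,
        )
        assert np.allclose(again.normalized, rec.normalized, atol=1e-9)

    def test_acquisition_photobleaching_cancels_in_the_ratio(self):
        plain = normalize_frap(*synthetic_record())
        faded = normalize_frap(*synthetic_record(acq_bleach=0.002))
        assert np.allclose(plain.normalized, faded.normalized, atol=1e-9)

    def test_unbleached_record_is_flagged_degenerate(self):
        times = np.arange(-6.0, 50.0)
        flat = np.full_like(times, 40.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_frap(times, flat, flat, np.zeros_like(times), 6)

    def test_five_prebleach_frames_rejected(self):
        times, b, u, bg, _ = synthetic_record(n_pre=5)
        with pytest.raises(ValueError, match="pre-bleach"):
            normalize_frap(times, b, u, bg, 5)

    def test_gap_in_reference_trace_rejected(self):
        times, b, u, bg, n_pre = synthetic_record()
        u[40] = np.nan
        with pytest.raises(ValueError, match="gaps"):
            normalize_frap(times, b, u, bg, n_pre)


class TestTwoComponentFit:
    def test_noise_free_parameters_recovered(self):
        a_f, k_f, a_s, k_s = 0.5, 0.1, 0.35, 0.0047
        rec = normalize_frap(*synthetic_record(a_f, k_f, a_s, k_s))
        fit_two_component(rec)
        assert rec.two_component
        assert rec.a_fast == pytest.approx(a_f, rel=1e-4)
        assert rec.k_fast == pytest.approx(k_f, rel=1e-4)
        assert rec.a_slow == pytest.approx(a_s, rel=1e-4)
        assert rec.k_slow == pytest.approx(k_s, rel=1e-4)
        assert rec.immobile == pytest.approx(0.15, abs=1e-4)

    def test_single_exponential_input_selects_fallback(self):
        rec = normalize_frap(*synthetic_record(a_f=1.0, k_f=LN2 / 5.0, a_s=0.0,
                                               k_s=1e-6))
        fit_two_component(rec)
        assert rec.two_component is False
        assert rec.a_slow == 0.0
        assert rec.a_fast == pytest.approx(1.0, rel=1e-3)

    def test_plateau_plus_immobile_is_one(self):
        rec = normalize_frap(*synthetic_record())
        fit_two_component(rec)
        plateau = rec.a_fast + rec.a_slow
        assert plateau + rec.immobile == pytest.approx(1.0, abs=1e-9)


class TestBoundRecovery:
    def test_bound_curve_matches_the_algebra(self):
        a_f, k_f, a_s, k_s = 0.5, 0.1, 0.35, 0.0047
        rec = normalize_frap(*synthetic_record(a_f, k_f, a_s, k_s))
        bound_recovery(fit_two_component(rec))
        t, _ = rec.post_bleach()
        expected = a_s / (1 - a_f) * (1 - np.exp(-k_s * t))
        assert np.allclose(rec.bound_curve, expected, atol=1e-6)

    def test_stalled_two_step_half_time_from_the_slow_rate(self):
        # treated: fast diffusing component + bound exchange at t1/2 = 149 s
        rec = normalize_frap(*synthetic_record(a_s=0.35, k_s=LN2 / 149.0))
        bound_recovery(fit_two_component(rec))
        assert rec.t_half_bound == pytest.approx(149.0, rel=1e-3)

    def test_untreated_single_step_half_time(self):
        # unperturbed replication: one-step full recovery at t1/2 = 55 s
        rec = normalize_frap(*synthetic_record(a_f=1.0, k_f=LN2 / 55.0,
                                               a_s=0.0, k_s=1e-6))
        bound_recovery(fit_two_component(rec))
        assert rec.two_component is False
        assert rec.t_half_bound == pytest.approx(55.0, rel=1e-3)

    def test_requires_a_fit_first(self):
        rec = normalize_frap(*synthetic_record())
        with pytest.raises(ValueError, match="fit_two_component"):
            bound_recovery(rec)


class TestExchangeRate:
    def make_record(self, gain_at, window, span=120):
        """A record whose bound curve rises linearly to ``gain_at`` at
        ``window`` seconds."""
        times = np.arange(-6.0, span + 1.0)
        rec = FRAPRecord(times=times - 0.0, normalized=np.zeros_like(times),
                         bleach_frame=6)
        rec.times = times - times[6]
        t, _ = rec.post_bleach()
        rec.bound_curve = np.clip(t / window, 0, 1) * gain_at
        rec.a_fast, rec.a_slow = 0.0, 1.0
        return rec

    def test_rpa_like_exchange_in_nine_seconds(self):
        # 61.125 complexes in 9 s -> 407.5 per minute
        rec = self.make_record(gain_at=61.125 / 81.0, window=9.0)
        out = exchange_rate(rec, n_bound=81.0, window_s=9.0)
        assert out["complexes"] == pytest.approx(61.125, rel=1e-6)
        assert out["per_min"] == pytest.approx(407.5, rel=1e-6)

    def test_pcna_like_exchange_in_one_minute(self):
        rec = self.make_record(gain_at=2.4 / 10.4, window=60.0)
        out = exchange_rate(rec, n_bound=10.4, window_s=60.0)
        assert out["complexes"] == pytest.approx(2.4, rel=1e-6)
        assert out["per_min"] == pytest.approx(2.4, rel=1e-6)

    def test_zero_recovery_exchanges_nothing(self):
        rec = self.make_record(gain_at=0.0, window=9.0)
        assert exchange_rate(rec, 81.0, 9.0)["complexes"] == 0.0

    def test_window_beyond_data_raises(self):
        rec = self.make_record(gain_at=0.5, window=9.0, span=30)
        with pytest.raises(ValueError, match="beyond"):
            exchange_rate(rec, 81.0, 300.0)
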