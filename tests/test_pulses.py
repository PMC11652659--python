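"""RAFF2 waveform synthesis, preparation-train arithmetic, field geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.integrate import quad

from raffmap.pulses import (
    ConfigurationError,
    PulseConfig,
    assemble_prep_train,
    default_duration,
    field_trajectory,
    make_raff2_composite,
    make_raff2_pulse,
    rf_power_fraction,
    waveform_from_csv,
    waveform_to_csv,
)

TWO_PI = 2.0 * math.pi


class TestPulseSynthesis:
    def test_default_duration_convention(self):
        # two revolutions about the sqrt(2)*f1max doubly-rotating-frame field
        assert default_duration(625.0) == pytest.approx(math.sqrt(2) / 625.0)
        wf = make_raff2_pulse(PulseConfig(f1max=625.0))
        assert round(wf.duration * 1e3, 2) == 2.26

    def test_waveform_endpoints_phi0_zero(self):
        wf = make_raff2_pulse(PulseConfig(f1max=625.0))
        assert wf.omega1[0] == 0.0
        assert wf.delta_omega[0] == pytest.approx(TWO_PI * 625.0)
        assert wf.phase[0] == 0.0

    def test_phase_matches_closed_form_and_quadrature(self):
        # phi(t) = sin(w1max t) for phi0 = 0; max |phi| is 1 rad
        cfg = PulseConfig(f1max=625.0, n_samples=2048)
        wf = make_raff2_pulse(cfg)
        closed = np.sin(cfg.omega1max * wf.t)
        assert np.max(np.abs(wf.phase - closed)) < 1e-6
        assert np.max(np.abs(wf.phase)) == pytest.approx(1.0, abs=1e-6)
        # independent oracle: adaptive quadrature of the FM function
        for t_probe in (wf.duration / 3, wf.duration):
            k = int(np.argmin(np.abs(wf.t - t_probe)))
            ref, _ = quad(lambda u: cfg.omega1max * math.cos(cfg.omega1max * u),
                          0.0, float(wf.t[k]))
            assert wf.phase[k] == pytest.approx(ref, abs=1e-6)

    @given(phi0=hst.floats(-3.0, 3.0), f1max=hst.floats(100.0, 2000.0))
    @settings(max_examples=25, deadline=None)
    def test_phase_closed_form_any_phi0(self, phi0, f1max):
        cfg = PulseConfig(f1max=f1max, phi0=phi0, n_samples=1024)
        wf = make_raff2_pulse(cfg)
        closed = np.sin(cfg.omega1max * wf.t + phi0) - math.sin(phi0)
        assert np.max(np.abs(wf.phase - closed)) < 1e-6

    def test_b1_scale_applies_to_am_only(self):
        ref = make_raff2_pulse(PulseConfig(f1max=625.0))
        lo = make_raff2_pulse(PulseConfig(f1max=625.0, b1_scale=0.4))
        assert np.allclose(lo.omega1, 0.4 * ref.omega1)
        assert np.array_equal(lo.delta_omega, ref.delta_omega)
        assert np.array_equal(lo.phase, ref.phase)

    @pytest.mark.parametrize("kw", [
        dict(f1max=-1.0), dict(f1max=0.0), dict(f1max=625.0, duration=-1.0),
        dict(f1max=625.0, n_samples=8), dict(f1max=625.0, b1_scale=0.0),
        dict(f1max=625.0, b1_scale=2.5),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            PulseConfig(**kw)


class TestPrepTrain:
    @pytest.mark.parametrize("n_pulses,total_ms", [(8, 22.98), (16, 46.66), (24, 70.34)])
    def test_printed_totals(self, n_pulses, total_ms):
        # spoilers sit strictly between pulses: n*2.26 + (n-1)*0.7
        pulse = make_raff2_pulse(PulseConfig(f1max=625.0, duration=2.26e-3))
        train = assemble_prep_train(pulse, n_pulses, 0.7e-3)
        assert train.total_duration * 1e3 == pytest.approx(total_ms, abs=1e-9)

    def test_single_pulse_has_no_spoiler(self):
        pulse = make_raff2_pulse(PulseConfig(f1max=625.0))
        train = assemble_prep_train(pulse, 1, 0.7e-3)
        assert train.total_duration == pulse.duration

    def test_rejects_empty_train(self):
        pulse = make_raff2_pulse(PulseConfig(f1max=625.0))
        with pytest.raises(ConfigurationError):
            assemble_prep_train(pulse, 0, 0.7e-3)


class TestFieldTrajectory:
    def test_on_resonance_field_constancy(self):
        wf = make_raff2_pulse(PulseConfig(f1max=625.0, n_samples=10_000))
        tr = field_trajectory(wf)
        assert np.ptp(tr.b_eff_mag) / 625.0 < 1e-12
        e_ref = math.sqrt(2) * 625.0
        assert np.max(np.abs(tr.e_field_mag - e_ref)) / e_ref < 1e-6

    @given(f1max=hst.floats(200.0, 1500.0), phi0=hst.floats(-2.0, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_on_resonance_constancy_any_config(self, f1max, phi0):
        wf = make_raff2_pulse(PulseConfig(f1max=f1max, phi0=phi0, n_samples=512))
        tr = field_trajectory(wf)
        assert np.ptp(tr.b_eff_mag) / f1max < 1e-12

    def test_sweep_rate_constant_on_resonance(self):
        wf = make_raff2_pulse(PulseConfig(f1max=625.0, n_samples=10_000))
        tr = field_trajectory(wf)
        # alpha(t) = w1max * t analytically (finite-difference oracle)
        assert np.allclose(tr.sweep_rate, TWO_PI * 625.0, rtol=1e-9)

    def test_off_resonance_maximum(self):
        # at +50 Hz offset the field peaks where delta_omega = +625 Hz, omega1 = 0
        wf = make_raff2_pulse(PulseConfig(f1max=625.0, n_samples=50_000))
        tr = field_trajectory(wf, delta_omega0=50.0)
        assert np.ptp(tr.b_eff_mag) > 1.0  # no longer constant
        assert np.max(tr.b_eff_mag) == pytest.approx(675.0, abs=1e-3)

    def test_two_revolution_duration_consistency(self):
        # e_field * duration = 2 cycles -> 4 pi rad of precession
        wf = make_raff2_pulse(PulseConfig(f1max=625.0, n_samples=4096))
        tr = field_trajectory(wf)
        rad = float(np.mean(tr.e_field_mag)) * wf.duration * TWO_PI
        assert rad == pytest.approx(4 * math.pi, abs=1e-9)


class TestPower:
    def test_raff2_am_over_integer_half_periods(self):
        w1 = TWO_PI * 625.0
        cfg = PulseConfig(f1max=625.0, duration=4 * math.pi / w1, n_samples=4097)
        assert rf_power_fraction(make_raff2_pulse(cfg)) == pytest.approx(0.5, abs=1e-6)

    def test_default_duration_value_from_quadrature(self):
        # non-integer half-periods: frozen from the sin^2 quadrature oracle
        # mean = 1/2 - sin(2X)/(4X) at X = 2*sqrt(2)*pi
        x = 2 * math.sqrt(2) * math.pi
        expected = 0.5 - math.sin(2 * x) / (4 * x)
        wf = make_raff2_pulse(PulseConfig(f1max=625.0, n_samples=8192))
        assert rf_power_fraction(wf) == pytest.approx(expected, abs=1e-6)

    def test_constant_amplitude_is_unity(self):
        from raffmap.pulses import Waveform

        t = np.linspace(0.0, 1e-3, 128)
        w1 = TWO_PI * 625.0
        wf = Waveform(t=t, omega1=np.full_like(t, w1),
                      delta_omega=np.zeros_like(t), phase=np.zeros_like(t))
        assert rf_power_fraction(wf) == pytest.approx(1.0)

    def test_b1_scaled_pulse_referenced_to_nominal(self):
        w1 = TWO_PI * 625.0
        cfg = PulseConfig(f1max=625.0, duration=4 * math.pi / w1, n_samples=4097,
                          b1_scale=0.4)
        assert rf_power_fraction(make_raff2_pulse(cfg)) == pytest.approx(0.08, abs=1e-6)

    def test_zero_amplitude_returns_zero(self):
        from raffmap.pulses import Waveform

        t = np.linspace(0.0, 1e-3, 64)
        wf = Waveform(t=t, omega1=np.zeros_like(t),
                      delta_omega=np.zeros_like(t), phase=np.zeros_like(t))
        assert rf_power_fraction(wf) == 0.0


class TestComposite:
    def test_same_duration_comparable_power(self):
        cfg = PulseConfig(f1max=625.0, n_samples=2048)
        plain, comp = make_raff2_pulse(cfg), make_raff2_composite(cfg)
        assert comp.duration == pytest.approx(plain.duration)
        assert 0.4 < rf_power_fraction(comp) < 0.6

    def test_time_reversal_structure(self):
        # amplitude is palindromic; the second half's sweep is the negated
        # time-reverse of the first (with a fresh sign at the junction)
        comp = make_raff2_composite(PulseConfig(f1max=625.0, n_samples=2048))
        am, fm = comp.omega1, comp.delta_omega
        m = (am.size + 1) // 2
        assert np.allclose(am, am[::-1], atol=1e-12)
        assert np.allclose(fm[m:], -fm[:m][::-1][1:], atol=1e-9)


def test_waveform_csv_round_trip(tmp_path):
    wf = make_raff2_pulse(PulseConfig(f1max=625.0, n_samples=512))
    path = tmp_path / "wf.csv"
    waveform_to_csv(wf, path)
    back = waveform_from_csv(path)
    assert np.array_equal(back.t, wf.t)
    # omega1 is stored in Hz; the rad/s <-> Hz conversion costs one rounding
    assert np.allclose(back.omega1, wf.omega1, rtol=1e-14, atol=1e-12)
    assert np.array_equal(back.phase, wf.phase)
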