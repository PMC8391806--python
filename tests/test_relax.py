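"""Spin-relaxation processing: decay fits, offset correction, rigid-rotor
predictions and correlation-time scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldbind.relax import (R1RHO_DELAYS_S, OffsetGeometry, RateEstimate,
                            RelaxationSeries, TumblingModel, fit_decay,
                            offset_correct, popavg_r2, predict_rigid_r2,
                            scale_tauc, viscosity_water_glycerol)


def _series(rate=12.0, i0=100.0, delays=R1RHO_DELAYS_S, noise=0.0,
            rng=None, errors=None, rate_type="R1rho"):
    t = np.asarray(delays)
    y = i0 * np.exp(-rate * t)
    if noise:
        y = y + rng.normal(0, noise, t.size)
    return RelaxationSeries(7, t, y, errors, rate_type)


class TestFitDecay:
    def test_noiseless_exact_recovery_on_schedule_with_repeat(self):
        """The 10-point schedule plus its repeat is accepted and fitted
        exactly on noiseless data."""
        est = fit_decay(_series(rate=12.0), n_mc=10, seed=0)
        assert est.converged
        assert est.rate == pytest.approx(12.0, abs=1e-6)
        assert est.i0 == pytest.approx(100.0, abs=1e-4)
        assert len(R1RHO_DELAYS_S) == 11  # duplicate 70 ms enters twice

    def test_mc_error_scales_with_intensity_error(self, rng):
        """Doubling the intensity errors roughly doubles the Monte-Carlo
        rate error (same seed, n_mc = 1000)."""
        e1 = np.full(len(R1RHO_DELAYS_S), 1.0)
        s1 = _series(noise=1.0, rng=rng, errors=e1)
        s2 = RelaxationSeries(7, s1.delays, s1.intensities, 2 * e1, "R1rho")
        r1 = fit_decay(s1, n_mc=1000, seed=42)
        r2 = fit_decay(s2, n_mc=1000, seed=42)
        assert r2.rate_error / r1.rate_error == pytest.approx(2.0, rel=0.15)

    def test_recovery_within_three_sigma_on_most_replicates(self):
        """Monte-Carlo error bars are calibrated: the true rate lies within
        3 sigma on >= 95% of noisy replicates."""
        master = np.random.default_rng(7)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            s = _series(rate=12.0, noise=1.0, rng=master,
                        errors=np.full(len(R1RHO_DELAYS_S), 1.0))
            est = fit_decay(s, n_mc=500, seed=int(master.integers(2**31)))
            hits += abs(est.rate - 12.0) <= 3 * est.rate_error
        assert hits / n_rep >= 0.95

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            RelaxationSeries(1, [0.1, 0.1, 0.1], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            RelaxationSeries(1, [-0.1, 0.2, 0.3], [3.0, 2.0, 1.0])
        flat = RelaxationSeries(1, [0.1, 0.2, 0.3], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            fit_decay(flat, n_mc=10, seed=0)


class TestOffsetCorrect:
    def _est(self, rate, err=0.1, kind="R1rho"):
        return RateEstimate(3, rate, err, kind)

    def test_on_resonance_returns_r1rho(self):
        geom = OffsetGeometry(1500.0, 0.0)
        assert geom.theta == pytest.approx(math.pi / 2)
        out = offset_correct(self._est(18.0), self._est(1.4, kind="R1"), geom)
        assert out.rate == pytest.approx(18.0)

    def test_r1rho_equal_r1_gives_r1_any_tilt(self):
        for dnu in (100.0, 750.0, 1500.0, 4000.0, -2000.0):
            geom = OffsetGeometry(1500.0, dnu)
            out = offset_correct(self._est(1.4), self._est(1.4, kind="R1"),
                                 geom)
            assert out.rate == pytest.approx(1.4)

    def test_45_degree_tilt(self):
        geom = OffsetGeometry(1500.0, 1500.0)
        assert geom.theta == pytest.approx(math.pi / 4)
        out = offset_correct(self._est(10.0), self._est(2.0, kind="R1"), geom)
        assert out.rate == pytest.approx(2 * 10.0 - 2.0)

    @settings(derandomize=True, max_examples=50)
    @given(r2=st.floats(1.0, 80.0), r1=st.floats(0.2, 3.0),
           dnu=st.floats(-5000.0, 5000.0))
    def test_inverts_composition_exactly(self, r2, r1, dnu):
        """offset_correct is the exact inverse of
        R1rho = R2 sin^2(theta) + R1 cos^2(theta)."""
        geom = OffsetGeometry(1500.0, dnu)
        r1rho = r2 * math.sin(geom.theta) ** 2 + r1 * math.cos(geom.theta) ** 2
        out = offset_correct(self._est(r1rho), self._est(r1, kind="R1"), geom)
        assert out.rate == pytest.approx(r2, rel=1e-9)

    def test_residue_and_type_mismatch_rejected(self):
        geom = OffsetGeometry(1500.0, 0.0)
        with pytest.raises(ValueError):
            offset_correct(self._est(10.0), self._est(1.0, kind="R1rho"), geom)
        with pytest.raises(ValueError):
            offset_correct(RateEstimate(1, 10.0, 0.1, "R1rho"),
                           RateEstimate(2, 1.0, 0.1, "R1"), geom)


class TestRigidRotor:
    def test_bound_complex_estimate(self):
        """~69 s^-1 at the scaled correlation time and 600 MHz with
        conventional amide constants (within the +-10% band)."""
        r2 = predict_rigid_r2(TumblingModel(tau_c=47.1, field_1H=600.0))
        assert r2 == pytest.approx(69.0, rel=0.10)

    def test_vanishes_with_tau_c(self):
        assert predict_rigid_r2(TumblingModel(tau_c=1e-6, field_1H=600.0)) \
            == pytest.approx(0.0, abs=1e-4)

    def test_linear_in_tau_c_in_slow_tumbling_limit(self):
        """J(0) dominance: R2 doubles with tau_c to within 1% for
        omega_N * tau_c >> 1."""
        a = predict_rigid_r2(TumblingModel(tau_c=47.1, field_1H=600.0))
        b = predict_rigid_r2(TumblingModel(tau_c=94.2, field_1H=600.0))
        assert b / a == pytest.approx(2.0, rel=0.01)

    @settings(derandomize=True, max_examples=30)
    @given(tau=st.floats(0.5, 100.0), csa=st.floats(-175.0, -160.0))
    def test_monotone_in_tau_c_and_csa(self, tau, csa):
        m = TumblingModel(tau_c=tau, field_1H=600.0, csa=csa)
        up_tau = TumblingModel(tau_c=tau * 1.1, field_1H=600.0, csa=csa)
        up_csa = TumblingModel(tau_c=tau, field_1H=600.0, csa=csa * 1.05)
        assert predict_rigid_r2(up_tau) > predict_rigid_r2(m)
        assert predict_rigid_r2(up_csa) > predict_rigid_r2(m)


class TestViscosityAndTauc:
    def test_pure_water_25C(self):
        assert viscosity_water_glycerol(298.15, 0.0) \
            == pytest.approx(0.89, abs=0.01)

    def test_cold_water_more_viscous(self):
        assert viscosity_water_glycerol(278.15, 0.0) \
            > viscosity_water_glycerol(298.15, 0.0)

    def test_glycerol_raises_viscosity(self):
        assert viscosity_water_glycerol(278.15, 0.05) \
            > viscosity_water_glycerol(278.15, 0.0)

    def test_reference_scaling_to_cold_glycerol_buffer(self):
        """21.8 ns at 25 C (water) -> ~47.1 ns at 5 C in 5% v/v glycerol."""
        eta_ref = viscosity_water_glycerol(298.15, 0.0)
        eta = viscosity_water_glycerol(278.15, 0.05)
        tau = scale_tauc(21.8, 298.15, eta_ref, 278.15, eta)
        assert tau == pytest.approx(47.1, rel=0.05)

    def test_identity_and_doubling(self):
        assert scale_tauc(21.8, 298.15, 0.89, 298.15, 0.89) == 21.8
        assert scale_tauc(10.0, 300.0, 1.0, 300.0, 2.0) == pytest.approx(20.0)

    @settings(derandomize=True, max_examples=30)
    @given(tau=st.floats(1.0, 100.0), t2=st.floats(274.0, 370.0),
           eta2=st.floats(0.3, 10.0))
    def test_forward_backward_roundtrip(self, tau, t2, eta2):
        fwd = scale_tauc(tau, 298.15, 0.89, t2, eta2)
        back = scale_tauc(fwd, t2, eta2, 298.15, 0.89)
        assert back == pytest.approx(tau, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            viscosity_water_glycerol(250.0, 0.0)
        with pytest.raises(ValueError):
            viscosity_water_glycerol(298.15, 0.6)


class TestPopavgR2:
    @pytest.mark.parametrize("p,expected", [(0.0, 5.0), (0.5, 37.0), (1.0, 69.0)])
    def test_weighted_average(self, p, expected):
        assert popavg_r2(p, 5.0, 69.0) == pytest.approx(expected)

    def test_rejects_bad_population(self):
        with pytest.raises(ValueError):
            popavg_r2(1.2, 5.0, 69.0)
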