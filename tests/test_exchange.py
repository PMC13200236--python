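"""Two-state exchange-modulated tumbling and gel rate enhancements."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from gnasr import (
    MotionModel,
    TumblingExchangeModel,
    compose_with_tumbling,
    composite_spectral_density,
    delta_r1,
    delta_r2,
    delta_rates,
    effective_nasr_prefactor,
    free_rates,
    gel_rates,
    internal_correlation_modes,
    numerical_correlation_oracle,
    overall_tumbling_modes,
    sweep_timescale_map,
)
from gnasr.errors import InfeasibleModelError


class TestOverallTumblingModes:
    def test_no_binding_single_mode(self):
        model = TumblingExchangeModel(p_b=0.0)
        modes = overall_tumbling_modes(model)
        assert modes.n_modes == 1
        assert modes.amplitudes == pytest.approx([1.0])
        assert modes.rates == pytest.approx([1.0 / 16e-9])

    def test_bound_without_exchange_infeasible(self):
        with pytest.raises(InfeasibleModelError):
            TumblingExchangeModel(p_b=0.0025, k_ex=0.0)

    def test_two_modes_normalized(self, gel_model):
        modes = overall_tumbling_modes(gel_model)
        assert modes.n_modes == 2
        assert modes.amplitudes.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(modes.rates > 0)
        # slow mode carries roughly the bound population
        assert modes.amplitudes[-1] == pytest.approx(gel_model.p_b, rel=0.05)

    def test_matches_matrix_exponential(self, gel_model):
        """Mode-sum C(t) vs direct expm(G t) on a time grid, < 1e-10."""
        modes = overall_tumbling_modes(gel_model)
        G = gel_model.generator()
        ts = np.logspace(-10, -5, 40)
        for t in ts:
            direct = float(scipy.linalg.expm(G * t).sum(axis=0) @ gel_model.p_eq)
            assert abs(modes.correlation(t) - direct) < 1e-10


class TestCompositeSpectralDensity:
    def test_rigid_motion_identity(self, gel_model):
        overall = overall_tumbling_modes(gel_model)
        comp = composite_spectral_density(overall, MotionModel())
        assert comp.amplitudes == pytest.approx(overall.amplitudes)
        assert comp.rates == pytest.approx(overall.rates)

    def test_single_mode_reduces_to_lipari_szabo(self, constants):
        m = MotionModel(S2_fast=0.85, tau_fast=50e-12)
        model = TumblingExchangeModel(p_b=0.0, tau_ref=10e-9, tau_free_gel=10e-9)
        comp = composite_spectral_density(overall_tumbling_modes(model), m)
        ls = compose_with_tumbling(internal_correlation_modes(m), 10e-9)
        for w in [0.0, constants.omega_N, constants.omega_H]:
            assert comp.j(w) == pytest.approx(ls.j(w), rel=1e-14)

    def test_mode_count_and_normalization(self, gel_model):
        m = MotionModel(S2_fast=0.8, tau_fast=40e-12, S2_slow=0.6, tau_slow=300e-9)
        comp = composite_spectral_density(overall_tumbling_modes(gel_model), m)
        assert comp.n_modes == 2 * 3  # 2 overall x (plateau + 2 internal)
        assert comp.amplitudes.sum() == pytest.approx(1.0, abs=1e-12)


class TestGelRates:
    def test_null_gel_equals_free(self, constants):
        model = TumblingExchangeModel(p_b=0.0, tau_ref=10e-9, tau_free_gel=10e-9)
        m = MotionModel(S2_fast=0.85, tau_fast=50e-12)
        f = free_rates(m, model, constants)
        g = gel_rates(m, model, constants)
        assert g.R1 == pytest.approx(f.R1, rel=1e-14)
        assert g.R2 == pytest.approx(f.R2, rel=1e-14)
        assert delta_r2(m, model, constants) == pytest.approx(0.0, abs=1e-12)

    def test_viscosity_sign_pattern(self, constants):
        """Slower tumbling alone: R2 up, R1 down at 19.97 T."""
        model = TumblingExchangeModel(p_b=0.0)
        d = delta_rates(MotionModel(), model, constants)
        assert d.R2 > 0
        assert d.R1 < 0

    def test_binding_adds_transverse_weight(self, constants, gel_model):
        visc_only = TumblingExchangeModel(p_b=0.0)
        rigid = MotionModel()
        assert (
            gel_rates(rigid, gel_model, constants).R2
            > gel_rates(rigid, visc_only, constants).R2
        )

    def test_rex_cancellation_bitwise(self, constants, gel_model):
        m0 = MotionModel(S2_fast=0.85, tau_fast=50e-12, Rex=0.0)
        m8 = MotionModel(S2_fast=0.85, tau_fast=50e-12, Rex=8.0)
        assert delta_r2(m0, gel_model, constants) == delta_r2(m8, gel_model, constants)
        assert delta_rates(m0, gel_model, constants) == delta_rates(m8, gel_model, constants)

    def test_delta_r2_regression_value(self, constants, gel_model):
        """Representative core residue under the reference gel parameters.

        Frozen after verification against the quadrature oracle.
        """
        m = MotionModel(S2_fast=0.85, tau_fast=50e-12)
        assert delta_r2(m, gel_model, constants) == pytest.approx(16.70851271717, rel=1e-9)

    def test_monotone_in_binding_and_viscosity(self, constants):
        rigid = MotionModel()
        d_pb = [
            delta_r2(rigid, TumblingExchangeModel(p_b=pb), constants)
            for pb in [0.0, 0.001, 0.0025, 0.005, 0.01]
        ]
        assert np.all(np.diff(d_pb) > 0)
        d_tau = [
            delta_r2(rigid, TumblingExchangeModel(tau_free_gel=tg), constants)
            for tg in [10e-9, 12e-9, 16e-9, 20e-9]
        ]
        assert np.all(np.diff(d_tau) > 0)
        kexs = [1e8, 1e9, 1e10]  # all above 1/tau_free_gel = 6.25e7
        d_kex = [
            delta_r2(rigid, TumblingExchangeModel(k_ex=kx), constants) for kx in kexs
        ]
        assert np.all(np.diff(d_kex) < 0)

    def test_fast_exchange_limit_is_pure_viscosity(self, constants):
        """k_ex -> inf: the bound mode broadens away, leaving viscosity only."""
        rigid = MotionModel()
        visc = delta_r2(rigid, TumblingExchangeModel(p_b=0.0), constants)
        fast = delta_r2(rigid, TumblingExchangeModel(k_ex=1e10), constants)
        assert fast == pytest.approx(visc, rel=0.01)

    def test_vanishing_binding_continuous(self, constants):
        rigid = MotionModel()
        at_zero = delta_r2(rigid, TumblingExchangeModel(p_b=0.0), constants)
        near_zero = delta_r2(rigid, TumblingExchangeModel(p_b=1e-8), constants)
        assert near_zero == pytest.approx(at_zero, rel=1e-4)


class TestSweep:
    def test_rigid_row_constant(self, constants, gel_model):
        taus = np.logspace(-11, -6, 10)
        sw = sweep_timescale_map([1.0], taus, gel_model, constants)
        assert np.ptp(sw.delta_R2[0]) == pytest.approx(0.0, abs=1e-10)

    def test_fast_motion_ordering_follows_s2(self, constants, gel_model):
        sw = sweep_timescale_map([0.2, 0.5, 0.8], [10e-12], gel_model, constants)
        col = sw.delta_R2[:, 0]
        assert col[0] < col[1] < col[2]

    def test_slow_end_converges_and_orders_after_free_curves(self, constants, gel_model):
        """Free-R2 curves converge near tau_P; Delta R2 only near 1/k_ex."""
        s2s = [0.2, 0.5, 0.8]
        taus = np.logspace(-11, -5, 40)
        sw = sweep_timescale_map(s2s, taus, gel_model, constants)
        spread_d = np.ptp(sw.delta_R2, axis=0) / sw.delta_R2_rigid
        spread_f = np.ptp(sw.normalized_R2_free, axis=0)
        # both families converge toward their slow ends
        assert spread_d[-1] < 0.05
        assert spread_f[-1] < 0.01
        conv_d = taus[np.argmax(spread_d < 0.1)]
        conv_f = taus[np.argmax(spread_f < 0.1)]
        assert conv_f < conv_d / 10  # much slower convergence of Delta R2
        assert conv_d > 1.0 / gel_model.k_ex  # only once tau_int passes 1/k_ex


class TestNasrPrefactor:
    def test_pure_viscosity_linear(self, constants):
        res = effective_nasr_prefactor(TumblingExchangeModel(p_b=0.0), constants)
        assert res.r_squared > 0.999
        assert res.slope > 0

    def test_null_model_zero_slope(self, constants):
        model = TumblingExchangeModel(p_b=0.0, tau_ref=10e-9, tau_free_gel=10e-9)
        res = effective_nasr_prefactor(model, constants)
        assert res.slope == pytest.approx(0.0, abs=1e-10)

    def test_binding_contribution_linear_in_pb(self, constants):
        visc = effective_nasr_prefactor(TumblingExchangeModel(p_b=0.0), constants).slope
        # fast-exchange regime so the binding term is linear in p_b
        s1 = effective_nasr_prefactor(
            TumblingExchangeModel(p_b=0.0025, k_ex=1e8), constants
        ).slope
        s2 = effective_nasr_prefactor(
            TumblingExchangeModel(p_b=0.005, k_ex=1e8), constants
        ).slope
        assert (s2 - visc) == pytest.approx(2.0 * (s1 - visc), rel=0.01)


class TestQuadratureOracle:
    def test_single_lorentzian_j0(self):
        modes = compose_with_tumbling(internal_correlation_modes(MotionModel()), 10e-9)
        assert numerical_correlation_oracle(modes, 0.0) == pytest.approx(4.0e-9, rel=1e-6)

    def test_high_frequency_rolloff(self):
        modes = compose_with_tumbling(internal_correlation_modes(MotionModel()), 10e-9)
        assert numerical_correlation_oracle(modes, 1e12) < 1e-15

    def test_reference_composite_matches_analytic(self, constants, gel_model):
        m = MotionModel(S2_fast=0.85, tau_fast=50e-12, S2_slow=0.6, tau_slow=200e-9)
        J = composite_spectral_density(overall_tumbling_modes(gel_model), m)
        w = constants.omega_N
        assert numerical_correlation_oracle(m, w, gel_model) == pytest.approx(
            J.j(w), rel=1e-6
        )

    @given(
        s2f=st.floats(0.3, 1.0),
        tauf=st.floats(10e-12, 200e-12),
        s2s=st.floats(0.4, 1.0),
        taus=st.floats(10e-9, 1e-6),
        slow_factor=st.floats(1.0, 2.0),
        pb=st.floats(0.0, 0.01),
        log_kex=st.floats(4.0, 7.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_random_models(
        self, constants, s2f, tauf, s2s, taus, slow_factor, pb, log_kex
    ):
        """Analytic mode-sum J vs matrix-exponential quadrature, < 1e-6 rel."""
        motion = MotionModel(S2_fast=s2f, tau_fast=tauf, S2_slow=s2s, tau_slow=taus)
        model = TumblingExchangeModel(
            tau_ref=10e-9, tau_free_gel=10e-9 * slow_factor, p_b=pb, k_ex=10**log_kex
        )
        J = composite_spectral_density(overall_tumbling_modes(model), motion)
        for w in (0.0, constants.omega_N):
            assert numerical_correlation_oracle(motion, w, model) == pytest.approx(
                J.j(w), rel=1e-6
            )
        # physical positivity on a frequency grid
        assert np.all(J.j(np.logspace(5, 10, 25)) > 0)
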