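"""Generators must reproduce their closed-form laws and be seed-deterministic."""

import dataclasses

import numpy as np
import pytest

from salibench.exceptions import ParameterError
from salibench.synthetic_data import (
    FlowCurveParams,
    QcmdParams,
    StribeckParams,
    ThinningParams,
    generate_flow_curve,
    generate_friction_curve,
    generate_qcmd_trace,
    generate_thinning_trace,
    preset,
)

from conftest import noiseless


class TestFlowCurve:
    def test_newtonian_degenerate_plateau(self):
        p = FlowCurveParams(0.5, 0.5, 1.0, 1.0, noise_cv=0.0, n_replicates=1)
        curve = generate_flow_curve(p, 0)[0]
        assert np.allclose(curve.viscosity, 0.5, rtol=1e-13)

    def test_noiseless_matches_generating_law_at_50(self, presets):
        p = noiseless(dataclasses.replace(presets["gel"].flow, n_replicates=1))
        curve = generate_flow_curve(p, 0)[0]
        expected = p.viscosity(curve.shear_rate)
        assert np.allclose(curve.viscosity, expected, rtol=1e-12)
        # closed-form model value at exactly 50 1/s
        assert p.viscosity(50.0) == pytest.approx(
            p.infinite_shear_viscosity
            + (p.zero_shear_viscosity - p.infinite_shear_viscosity) / (1 + (p.relaxation_time * 50.0) ** p.thinning_exponent)
        )

    def test_determinism_and_noise_structure(self, presets):
        p = presets["liquid"].flow
        a = generate_flow_curve(p, 7)
        b = generate_flow_curve(p, 7)
        c = generate_flow_curve(p, 8)
        for x, y in zip(a, b):
            assert np.array_equal(x.viscosity, y.viscosity)
        law = p.viscosity(a[0].shear_rate)
        # different seeds differ, but only within noise of the same law
        assert not np.array_equal(a[0].viscosity, c[0].viscosity)
        for curve in (a[0], c[0]):
            assert np.all(np.abs(np.log(curve.viscosity / law)) < 6 * p.noise_cv)

    def test_invalid_params_name_the_invariant(self):
        with pytest.raises(ParameterError, match="zero_shear"):
            FlowCurveParams(0.1, 0.5, 1.0, 1.0)
        with pytest.raises(ParameterError, match="rate_range"):
            FlowCurveParams(1.0, 0.5, 1.0, 1.0, rate_range=(10.0, 1.0))


class TestThinningTrace:
    def test_elastic_noiseless_log_linear(self):
        p = ThinningParams(model="elastic", sigma=0.06, lambda_c=0.05,
                           initial_plateau=0.02, sampling_rate=2000.0, noise_cv=0.0)
        tr = generate_thinning_trace(p, 0)
        sel = (tr.time > p.initial_plateau) & (tr.diameter > tr.resolution * 1.001)
        slope = np.polyfit(tr.time[sel], np.log(tr.diameter[sel]), 1)[0]
        assert slope == pytest.approx(-1.0 / (3 * 0.05), rel=1e-9)

    def test_power_law_linear_decay_reaches_resolution(self):
        # n = 1: D decays linearly, crossing the floor at t_b - res*K/(2*phi0*sigma)
        p = ThinningParams(model="power_law", sigma=0.06, K=0.5, n=1.0, t_b=0.31,
                           initial_plateau=0.15, sampling_rate=5000.0, noise_cv=0.0)
        tr = generate_thinning_trace(p, 0)
        t_cross = 0.31 - 20e-6 * 0.5 / (2 * 0.142 * 0.06)
        assert t_cross == pytest.approx(0.3094131455399061)
        first_floor = tr.time[tr.at_floor()][0]
        assert abs(first_floor - t_cross) <= 1.0 / p.sampling_rate

    def test_breakup_censored_at_resolution_floor(self):
        p = ThinningParams(model="power_law", sigma=0.06, K=0.5, n=1.0, t_b=0.31,
                           initial_plateau=0.15, sampling_rate=5000.0, noise_cv=0.0)
        tr = generate_thinning_trace(p, 0)
        assert np.all(tr.diameter[tr.time >= p.t_b] == tr.resolution)

    def test_power_law_exceeding_plate_diameter_rejected(self):
        p = ThinningParams(model="power_law", sigma=0.06, K=0.5, n=1.0, t_b=0.31,
                           initial_plateau=0.0, sampling_rate=5000.0)
        with pytest.raises(ParameterError, match="plate diameter"):
            generate_thinning_trace(p, 0)

    def test_model_field_exclusivity(self):
        with pytest.raises(ParameterError):
            ThinningParams(model="elastic", sigma=0.06, lambda_c=0.05, K=1.0)
        with pytest.raises(ParameterError):
            ThinningParams(model="power_law", sigma=0.06, K=1.0, n=1.0, t_b=-1.0)


class TestStribeck:
    def test_plateau_and_hydrodynamic_limits(self):
        p = StribeckParams(boundary_mu=0.3, transition_speed=0.03, transition_sharpness=6.0,
                           hydrodynamic_coeff=0.1, hydrodynamic_exponent=0.6,
                           viscosity_at_contact=0.5, speed_range=(1e-4, 10.0), noise_cv=0.0)
        low, high = 1e-4, 10.0
        assert p.mu(low) == pytest.approx(0.3, rel=0.01)
        hyd = 0.1 * (0.5 * high) ** 0.6
        assert p.mu(high) == pytest.approx(hyd, rel=0.01)

    def test_viscosity_scaling_of_hydrodynamic_branch(self):
        base = StribeckParams(boundary_mu=0.3, transition_speed=0.01, transition_sharpness=8.0,
                              hydrodynamic_coeff=0.1, hydrodynamic_exponent=0.6,
                              viscosity_at_contact=0.5, noise_cv=0.0)
        doubled = dataclasses.replace(base, viscosity_at_contact=1.0)
        u = 50.0 * base.transition_speed
        assert doubled.mu(u) / base.mu(u) == pytest.approx(2 ** 0.6, rel=1e-3)

    def test_determinism(self, presets):
        p = presets["gel"].stribeck
        assert np.array_equal(generate_friction_curve(p, 3).mu, generate_friction_curve(p, 3).mu)
        assert not np.array_equal(generate_friction_curve(p, 3).mu, generate_friction_curve(p, 4).mu)


class TestQcmd:
    def test_removal_extremes(self):
        base = dict(plateau_shift=30.0, adsorption_tau=50.0, injection_time=100.0,
                    rinse_time=1500.0, desorption_tau=20.0, baseline_noise_sd=0.0,
                    sampling_interval=1.0, duration=2500.0)
        keep = generate_qcmd_trace(QcmdParams(removal_fraction=0.0, **base), 0)
        gone = generate_qcmd_trace(QcmdParams(removal_fraction=1.0, **base), 0)
        assert keep.delta_f[-1] == pytest.approx(-30.0, rel=1e-6)
        assert abs(gone.delta_f[-1]) < 1e-6 * 30
        assert keep.delta_f[-1] == pytest.approx(keep.delta_f[np.searchsorted(keep.time, 1499)], rel=1e-6)

    def test_value_one_tau_after_injection(self):
        p = QcmdParams(plateau_shift=40.0, adsorption_tau=80.0, injection_time=100.0,
                       rinse_time=1200.0, removal_fraction=0.3, desorption_tau=30.0,
                       baseline_noise_sd=0.0, sampling_interval=1.0, duration=1500.0)
        tr = generate_qcmd_trace(p, 0)
        i = np.searchsorted(tr.time, 180.0)
        assert tr.delta_f[i] == pytest.approx(-40.0 * (1 - np.exp(-1)), rel=1e-9)

    def test_duration_must_cover_rinse(self):
        with pytest.raises(ParameterError, match="duration"):
            QcmdParams(plateau_shift=40.0, adsorption_tau=80.0, injection_time=100.0,
                       rinse_time=1200.0, removal_fraction=0.3, desorption_tau=30.0,
                       duration=1000.0)


class TestPresets:
    def test_unknown_name(self):
        with pytest.raises(KeyError):
            preset("cream")

    def test_saliva_removal_fraction(self, presets):
        assert presets["saliva"].qcmd.removal_fraction == pytest.approx(0.04)

    def test_liquid_breakup_time_scale(self, presets):
        # elastic filament hits the 20 um floor at ~0.03 s
        p = noiseless(presets["liquid"].thinning)
        tr = generate_thinning_trace(p, 0)
        t_floor = tr.time[tr.at_floor()]
        assert t_floor.size > 0
        assert t_floor[0] == pytest.approx(0.03, rel=0.1)
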