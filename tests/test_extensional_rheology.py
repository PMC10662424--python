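"""CaBER thinning fits and the strain/strain-rate/Trouton pipeline."""

import dataclasses

import numpy as np
import pytest

from salibench.exceptions import FitError
from salibench.extensional_rheology import (
    PHI0,
    ThinningTrace,
    detect_breakup,
    extensional_profile,
    fit_elastic,
    fit_power_law,
    select_model,
)
from salibench.shear_rheology import ShearModelFit
from salibench.synthetic_data import ThinningParams, generate_flow_curve, generate_thinning_trace

from conftest import noiseless

CONSTANT_SHEAR = ShearModelFit(eta_zero=0.5, eta_inf=0.5, cross_time=1.0,
                               cross_exponent=1.0, rms_log_residual=0.0)

ELASTIC = ThinningParams(model="elastic", sigma=0.06, lambda_c=0.05,
                         initial_plateau=0.02, sampling_rate=2000.0)
POWER = ThinningParams(model="power_law", sigma=0.06, K=0.5, n=1.0, t_b=0.31,
                       initial_plateau=0.15, sampling_rate=5000.0)


class TestDetectBreakup:
    def test_power_law_breakup_within_one_interval(self):
        tr = generate_thinning_trace(noiseless(POWER), 0)
        t_cross = POWER.t_b - POWER.resolution * POWER.K / (2 * PHI0 * POWER.sigma)
        assert detect_breakup(tr) == pytest.approx(t_cross, abs=1.0 / POWER.sampling_rate)

    def test_no_breakup_returns_none(self):
        t = np.linspace(0, 1, 100)
        tr = ThinningTrace(time=t, diameter=6e-3 * np.exp(-t))
        assert detect_breakup(tr) is None

    def test_noise_spike_below_floor_ignored(self):
        t = np.linspace(0, 1, 200)
        d = 6e-3 * np.exp(-8 * t)
        d[50] = 15e-6  # isolated dip below the 20 um floor
        d = np.clip(d, 20e-6, None)
        tr = ThinningTrace(time=t, diameter=d)
        sustained = t[np.nonzero(6e-3 * np.exp(-8 * t) <= 20e-6)[0][0]]
        assert detect_breakup(tr) == pytest.approx(sustained, abs=t[1] - t[0])


class TestFitElastic:
    def test_noiseless_recovery(self):
        fit = fit_elastic(generate_thinning_trace(noiseless(ELASTIC), 0))
        assert fit.lambda_c == pytest.approx(0.05, rel=1e-3)
        assert fit.rms_log_residual < 1e-9

    def test_noisy_recovery_across_seeds(self):
        p = dataclasses.replace(ELASTIC, noise_cv=0.02, sampling_rate=500.0 / 0.9)
        errors = [
            abs(fit_elastic(generate_thinning_trace(p, seed)).lambda_c - 0.05) / 0.05
            for seed in range(100)
        ]
        assert np.median(errors) < 0.05

    def test_constant_trace_is_an_error(self):
        t = np.linspace(0, 1, 100)
        tr = ThinningTrace(time=t, diameter=np.full(100, 3e-3))
        with pytest.raises(FitError):
            fit_elastic(tr)


class TestFitPowerLaw:
    def test_noiseless_recovery(self):
        fit = fit_power_law(generate_thinning_trace(noiseless(POWER), 0), POWER.sigma)
        assert fit.K == pytest.approx(0.5, rel=0.005)
        assert fit.n == pytest.approx(1.0, rel=0.005)
        assert fit.t_b == pytest.approx(0.31, rel=0.005)

    def test_model_vanishes_at_t_b(self):
        fit = fit_power_law(generate_thinning_trace(noiseless(POWER), 0), POWER.sigma)
        assert fit(np.array([fit.t_b]))[0] == 0.0

    def test_sigma_over_k_degeneracy(self):
        """Doubling sigma with K doubled leaves the model diameter unchanged."""
        tr = generate_thinning_trace(noiseless(POWER), 0)
        fit1 = fit_power_law(tr, POWER.sigma)
        fit2 = fit_power_law(tr, 2 * POWER.sigma)
        t = np.linspace(0.16, 0.30, 20)
        assert np.allclose(fit1(t), fit2(t), rtol=1e-6)
        assert fit2.K == pytest.approx(2 * fit1.K, rel=1e-6)

    def test_noisy_recovery_across_seeds(self):
        p = dataclasses.replace(POWER, noise_cv=0.02)
        errs = {"K": [], "n": [], "t_b": []}
        for seed in range(50):
            fit = fit_power_law(generate_thinning_trace(p, seed), p.sigma)
            errs["K"].append(abs(fit.K - 0.5) / 0.5)
            errs["n"].append(abs(fit.n - 1.0))
            errs["t_b"].append(abs(fit.t_b - 0.31) / 0.31)
        for key, e in errs.items():
            assert np.median(e) < 0.05, key


class TestSelectModel:
    def test_exponential_trace_prefers_elastic(self):
        choice, efit, pfit = select_model(generate_thinning_trace(noiseless(ELASTIC), 0), 0.06)
        assert choice == "elastic"
        assert efit is not None and efit.lambda_c == pytest.approx(0.05, rel=1e-3)

    def test_power_law_trace_prefers_power_law(self):
        choice, efit, pfit = select_model(generate_thinning_trace(noiseless(POWER), 0), 0.06)
        assert choice == "power_law"
        assert pfit is not None and pfit.t_b == pytest.approx(0.31, rel=0.005)


class TestExtensionalProfile:
    def test_strain_is_zero_at_plate_diameter(self):
        t = np.linspace(0, 1, 200)
        tr = ThinningTrace(time=t, diameter=6e-3 * np.exp(-3 * t))
        prof = extensional_profile(tr, 0.06, CONSTANT_SHEAR)
        strain_full = -2 * np.log(tr.diameter / tr.plate_diameter)
        assert strain_full[0] == 0.0
        assert np.allclose(prof.strain, strain_full[prof.indices])

    def test_strain_at_resolution_floor(self):
        # D_o = 6 mm, D_min = 20 um: eps = -2 ln(0.02/6)
        assert -2 * np.log(20e-6 / 6e-3) == pytest.approx(11.407564949312402)

    def test_elastic_closed_form_interior(self):
        """Strain rate 2/(3 lambda_c) and eta_E = 3 sigma lambda_c / D, interior < 0.5%."""
        p = noiseless(ELASTIC)
        tr = generate_thinning_trace(p, 0)
        prof = extensional_profile(tr, p.sigma, CONSTANT_SHEAR)
        w = max(5, round(0.05 * tr.time.size))
        dt = tr.time[1] - tr.time[0]
        inner = (prof.time > prof.time[0] + w * dt) & (prof.time < prof.time[-1] - w * dt)
        rate_true = 2.0 / (3.0 * p.lambda_c)
        assert np.max(np.abs(prof.strain_rate[inner] - rate_true)) / rate_true < 0.005
        d = tr.diameter[prof.indices]
        eta_true = 3.0 * p.sigma * p.lambda_c / d
        rel = np.abs(prof.eta_extensional - eta_true) / eta_true
        assert np.max(rel[inner]) < 0.005
        # Trouton against the constant shear viscosity
        assert np.allclose(prof.trouton, prof.eta_extensional / 0.5, rtol=1e-9)

    def test_power_law_constant_extensional_viscosity(self):
        """For n = 1 the pipeline gives eta_E = K / (2 phi0) at interior points.

        Interior excludes one smoothing window after the thinning onset and
        four windows before breakup, where local-quadratic differentiation of
        the log-singular diameter is biased.
        """
        p = noiseless(POWER)
        tr = generate_thinning_trace(p, 0)
        prof = extensional_profile(tr, p.sigma, CONSTANT_SHEAR)
        w = max(5, round(0.05 * tr.time.size))
        dt = tr.time[1] - tr.time[0]
        inner = (prof.time > prof.time[0] + w * dt) & (p.t_b - prof.time > 4 * w * dt)
        const = p.K / (2 * PHI0)
        rel = np.abs(prof.eta_extensional[inner] - const) / const
        assert np.max(rel) < 0.005

    def test_sigma_scale_covariance(self):
        p = noiseless(ELASTIC)
        tr = generate_thinning_trace(p, 0)
        prof1 = extensional_profile(tr, 0.06, CONSTANT_SHEAR)
        prof2 = extensional_profile(tr, 0.12, CONSTANT_SHEAR)
        assert np.allclose(prof2.eta_extensional, 2 * prof1.eta_extensional, rtol=1e-12)
        assert prof2.max_eta_extensional == pytest.approx(2 * prof1.max_eta_extensional, rel=1e-12)

    def test_strain_invariant_to_diameter_units(self):
        # the ratio inside the log makes strain unit-free
        t = np.linspace(0, 1, 100)
        d = 6e-3 * np.exp(-2 * t)
        a = ThinningTrace(time=t, diameter=d)
        b = ThinningTrace(time=t, diameter=d * 1e3, plate_diameter=6.0, resolution=20e-3)
        pa = extensional_profile(a, 0.06, CONSTANT_SHEAR)
        pb = extensional_profile(b, 0.06, CONSTANT_SHEAR)
        assert np.allclose(pa.strain, pb.strain, rtol=1e-12)
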