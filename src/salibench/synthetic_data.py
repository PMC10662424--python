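"""Synthetic instrument traces with known ground truth.

The benchmarking pipeline is exercised against generated stand-ins for the
four instruments: rotational rheometer flow curves, CaBER filament-thinning
traces, tribometer Stribeck sweeps and QCM-D frequency traces.  Every
generator takes an explicit seed (no global random state) and, run noiseless,
reproduces its closed-form generating law to machine precision, so the
analysis stages can be validated against exact oracles.

Presets bundle parameters for the three saliva-substitute format classes
(liquid / viscous liquid / gel) and for human saliva, placing the noiseless
summary statistics in the measured ranges for each class: viscosity at
50 1/s, filament breakup-time order of magnitude, |delta_f| plateau, and
removal percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Optional

import numpy as np

from .exceptions import ParameterError
from .extensional_rheology import PHI0, ThinningTrace
from .qcmd_adsorption import QcmdTrace
from .shear_rheology import FlowCurve
from .tribology import FrictionCurve

__all__ = [
    "FlowCurveParams",
    "ThinningParams",
    "StribeckParams",
    "QcmdParams",
    "PresetBundle",
    "generate_flow_curve",
    "generate_thinning_trace",
    "generate_friction_curve",
    "generate_qcmd_trace",
    "preset",
    "PRESET_NAMES",
]

#: default instrument coefficient of variation for multiplicative noise
DEFAULT_NOISE_CV = 0.02


@dataclass(frozen=True)
class FlowCurveParams:
    """Cross-model flow-curve generator parameters.

    eta(rate) = infinite_shear_viscosity + (zero_shear - infinite_shear) /
                (1 + (relaxation_time * rate)**thinning_exponent)
    """

    zero_shear_viscosity: float  # Pa.s
    infinite_shear_viscosity: float  # Pa.s
    relaxation_time: float  # s
    thinning_exponent: float
    noise_cv: float = DEFAULT_NOISE_CV
    n_points: int = 30
    rate_range: tuple[float, float] = (0.1, 1000.0)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not self.zero_shear_viscosity >= self.infinite_shear_viscosity > 0:
            raise ParameterError("requires zero_shear_viscosity >= infinite_shear_viscosity > 0")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be non-negative")
        if not (0 < self.rate_range[0] < self.rate_range[1]):
            raise ParameterError("rate_range must be strictly positive and increasing")
        if self.n_points < 3 or self.n_replicates < 1:
            raise ParameterError("need n_points >= 3 and n_replicates >= 1")

    def viscosity(self, rate: np.ndarray | float) -> np.ndarray | float:
        """Noiseless generating law evaluated at the given shear rate(s)."""
        return self.infinite_shear_viscosity + (
            self.zero_shear_viscosity - self.infinite_shear_viscosity
        ) / (1.0 + (self.relaxation_time * np.asarray(rate, float)) ** self.thinning_exponent)


@dataclass(frozen=True)
class ThinningParams:
    """CaBER trace generator parameters for the elastic or power-law model."""

    model: Literal["elastic", "power_law"]
    sigma: float  # N/m, surface tension
    lambda_c: Optional[float] = None  # s, elastic only
    K: Optional[float] = None  # Pa.s^n, power-law only
    n: Optional[float] = None  # power-law only
    t_b: Optional[float] = None  # s, power-law only
    D0: float = 6e-3  # m, plate diameter
    initial_plateau: float = 0.0  # s
    resolution: float = 20e-6  # m, laser micrometer floor
    sampling_rate: float = 1000.0  # Hz
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self) -> None:
        if self.model == "elastic":
            if self.lambda_c is None or self.lambda_c <= 0:
                raise ParameterError("elastic model requires lambda_c > 0")
            if any(v is not None for v in (self.K, self.n, self.t_b)):
                raise ParameterError("elastic model must not set K, n or t_b")
        elif self.model == "power_law":
            if self.K is None or self.n is None or self.t_b is None:
                raise ParameterError("power_law model requires K, n and t_b")
            if self.K <= 0:
                raise ParameterError("K must be positive")
            if not 0 < self.n <= 1.5:
                raise ParameterError("n must lie in (0, 1.5]")
            if self.t_b <= self.initial_plateau:
                raise ParameterError("t_b must exceed initial_plateau")
            if self.lambda_c is not None:
                raise ParameterError("power_law model must not set lambda_c")
        else:
            raise ParameterError(f"unknown thinning model {self.model!r}")
        if self.sigma <= 0 or self.resolution <= 0 or self.sampling_rate <= 0:
            raise ParameterError("sigma, resolution and sampling_rate must be positive")
        if self.noise_cv < 0 or self.initial_plateau < 0:
            raise ParameterError("noise_cv and initial_plateau must be non-negative")


@dataclass(frozen=True)
class StribeckParams:
    """Three-regime Stribeck curve generator.

    mu(U) = w(U) * boundary_mu + (1 - w(U)) * hydrodynamic_coeff *
            (viscosity_at_contact * U)**hydrodynamic_exponent,
    with logistic weight w(U) = 1 / (1 + (U / transition_speed)**transition_sharpness).
    """

    boundary_mu: float
    transition_speed: float  # m/s
    transition_sharpness: float
    hydrodynamic_coeff: float
    hydrodynamic_exponent: float
    viscosity_at_contact: float  # Pa.s
    speed_range: tuple[float, float] = (0.0035, 1.0)
    n_points: int = 25
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self) -> None:
        if self.boundary_mu <= 0:
            raise ParameterError("boundary_mu must be positive")
        if not (0 < self.speed_range[0] < self.speed_range[1]):
            raise ParameterError("speed_range must be positive and increasing")
        if not 0 < self.hydrodynamic_exponent <= 1:
            raise ParameterError("hydrodynamic_exponent must lie in (0, 1]")
        if self.transition_speed <= 0 or self.transition_sharpness <= 0:
            raise ParameterError("transition speed and sharpness must be positive")
        if self.hydrodynamic_coeff <= 0 or self.viscosity_at_contact <= 0:
            raise ParameterError("hydrodynamic_coeff and viscosity_at_contact must be positive")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be non-negative")
        if self.n_points < 3:
            raise ParameterError("need n_points >= 3")

    def mu(self, speed: np.ndarray | float) -> np.ndarray | float:
        """Noiseless generating law evaluated at the given speed(s)."""
        u = np.asarray(speed, float)
        w = 1.0 / (1.0 + (u / self.transition_speed) ** self.transition_sharpness)
        hyd = self.hydrodynamic_coeff * (self.viscosity_at_contact * u) ** self.hydrodynamic_exponent
        return w * self.boundary_mu + (1.0 - w) * hyd


@dataclass(frozen=True)
class QcmdParams:
    """Exponential adsorption-then-partial-desorption QCM-D trace generator."""

    plateau_shift: float  # Hz, magnitude of the adsorption-induced |delta_f|
    adsorption_tau: float  # s
    injection_time: float  # s
    rinse_time: float  # s
    removal_fraction: float  # in [0, 1]
    desorption_tau: float  # s
    baseline_noise_sd: float = 0.2  # Hz
    sampling_interval: float = 2.0  # s
    duration: float = 3600.0  # s

    def __post_init__(self) -> None:
        if self.plateau_shift <= 0:
            raise ParameterError("plateau_shift must be positive")
        if self.rinse_time <= self.injection_time:
            raise ParameterError("rinse_time must exceed injection_time")
        if not 0 <= self.removal_fraction <= 1:
            raise ParameterError("removal_fraction must lie in [0, 1]")
        if self.duration <= self.rinse_time:
            raise ParameterError("duration must exceed rinse_time")
        if self.adsorption_tau <= 0 or self.desorption_tau <= 0:
            raise ParameterError("time constants must be positive")
        if self.baseline_noise_sd < 0 or self.sampling_interval <= 0:
            raise ParameterError("noise sd must be non-negative, sampling_interval positive")

    def delta_f(self, t: np.ndarray) -> np.ndarray:
        """Noiseless generating law."""
        t = np.asarray(t, float)
        out = np.zeros_like(t)
        ads = (t >= self.injection_time) & (t < self.rinse_time)
        out[ads] = -self.plateau_shift * (
            1.0 - np.exp(-(t[ads] - self.injection_time) / self.adsorption_tau)
        )
        f_rinse = -self.plateau_shift * (
            1.0 - math.exp(-(self.rinse_time - self.injection_time) / self.adsorption_tau)
        )
        target = -self.plateau_shift * (1.0 - self.removal_fraction)
        post = t >= self.rinse_time
        out[post] = target + (f_rinse - target) * np.exp(
            -(t[post] - self.rinse_time) / self.desorption_tau
        )
        return out


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=size)


def generate_flow_curve(params: FlowCurveParams, seed: int) -> list[FlowCurve]:
    """Replicate flow curves on a log-spaced rate grid; replicates differ only by noise."""
    rng = np.random.default_rng(seed)
    rates = np.geomspace(params.rate_range[0], params.rate_range[1], params.n_points)
    law = np.asarray(params.viscosity(rates))
    return [
        FlowCurve(
            shear_rate=rates.copy(),
            viscosity=law * _lognormal_noise(rng, params.noise_cv, rates.size),
            replicate_id=f"r{i + 1}",
        )
        for i in range(params.n_replicates)
    ]


def _thinning_duration(params: ThinningParams) -> float:
    if params.model == "elastic":
        t_floor = params.initial_plateau + 3.0 * params.lambda_c * math.log(
            params.D0 / params.resolution
        )
        return 1.15 * t_floor
    return 1.1 * params.t_b


def generate_thinning_trace(params: ThinningParams, seed: int) -> ThinningTrace:
    """CaBER trace: plateau at D0, then the declared thinning law, censored at the floor."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.sampling_rate
    t = np.arange(0.0, _thinning_duration(params), dt)
    d = np.full(t.size, params.D0)
    after = t > params.initial_plateau
    if params.model == "elastic":
        d[after] = params.D0 * np.exp(-(t[after] - params.initial_plateau) / (3.0 * params.lambda_c))
    else:
        coeff = 2.0 * PHI0 * params.sigma / params.K
        d_at_start = coeff * (params.t_b - params.initial_plateau) ** params.n
        if d_at_start > params.D0 * (1 + 1e-9):
            raise ParameterError(
                "power-law parameters imply a diameter above the plate diameter at the "
                f"plateau end ({d_at_start:.3e} m > D0 = {params.D0:.3e} m)"
            )
        remaining = np.clip(params.t_b - t[after], 0.0, None)
        d[after] = coeff * remaining**params.n
    d = d * _lognormal_noise(rng, params.noise_cv, d.size)
    d = np.clip(d, params.resolution, params.D0)
    return ThinningTrace(time=t, diameter=d, plate_diameter=params.D0, resolution=params.resolution)


def generate_friction_curve(params: StribeckParams, seed: int) -> FrictionCurve:
    """Three-regime Stribeck curve on a log-spaced speed grid with multiplicative noise."""
    rng = np.random.default_rng(seed)
    u = np.geomspace(params.speed_range[0], params.speed_range[1], params.n_points)
    mu = np.asarray(params.mu(u)) * _lognormal_noise(rng, params.noise_cv, u.size)
    return FrictionCurve(speed=u, mu=mu)


def generate_qcmd_trace(params: QcmdParams, seed: int) -> QcmdTrace:
    """QCM-D trace: baseline, exponential adsorption, rinse-induced partial desorption."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.duration, params.sampling_interval)
    f = params.delta_f(t)
    if params.baseline_noise_sd > 0:
        f = f + rng.normal(0.0, params.baseline_noise_sd, t.size)
    return QcmdTrace(
        time=t, delta_f=f, injection_time=params.injection_time, rinse_time=params.rinse_time
    )


class PresetBundle(NamedTuple):
    """Ground-truth parameter bundle for one sample archetype."""

    name: str
    expected_class: str
    flow: FlowCurveParams
    thinning: ThinningParams
    stribeck: StribeckParams
    qcmd: QcmdParams


def _presets() -> dict[str, PresetBundle]:
    return {
        # spray-type liquid (Boots-like): eta(50/s) ~ 0.026 Pa.s, elastic filament
        # breaking at ~0.03 s, boundary mu ~ 0.4, |delta_f| ~ 20.6 Hz, 28% removal
        "liquid": PresetBundle(
            name="liquid",
            expected_class="liquid",
            flow=FlowCurveParams(1.2, 0.024, 10.0, 1.0),
            thinning=ThinningParams(
                model="elastic", sigma=0.060, lambda_c=1.5e-3,
                initial_plateau=0.005, sampling_rate=20000.0,
            ),
            stribeck=StribeckParams(
                boundary_mu=0.40, transition_speed=0.08, transition_sharpness=3.0,
                hydrodynamic_coeff=0.12, hydrodynamic_exponent=0.6,
                viscosity_at_contact=0.026,
            ),
            qcmd=QcmdParams(
                plateau_shift=20.6, adsorption_tau=184.0, injection_time=300.0,
                rinse_time=2700.0, removal_fraction=0.28, desorption_tau=100.0,
                duration=3600.0,
            ),
        ),
        # BioXtra-like viscous liquid: eta(50/s) ~ 0.52 Pa.s, power-law filament
        # with t_b ~ 0.31 s, boundary mu ~ 0.07, |delta_f| ~ 21.6 Hz, 23% removal,
        # slow adsorption (t_saturation ~ 54 min)
        "viscous_liquid": PresetBundle(
            name="viscous_liquid",
            expected_class="viscous_liquid",
            flow=FlowCurveParams(1.6, 0.05, 0.04, 1.2),
            thinning=ThinningParams(
                model="power_law", sigma=0.060, K=0.5, n=1.0, t_b=0.31,
                initial_plateau=0.15, sampling_rate=5000.0,
            ),
            stribeck=StribeckParams(
                boundary_mu=0.07, transition_speed=0.03, transition_sharpness=3.0,
                hydrodynamic_coeff=0.05, hydrodynamic_exponent=0.6,
                viscosity_at_contact=0.52,
            ),
            qcmd=QcmdParams(
                plateau_shift=21.6, adsorption_tau=828.0, injection_time=300.0,
                rinse_time=5100.0, removal_fraction=0.23, desorption_tau=150.0,
                sampling_interval=3.0, duration=6600.0,
            ),
        ),
        # Oralieve-like gel: eta(50/s) ~ 5.4 Pa.s with a steep shear-thinning decay,
        # long-lived power-law filament (t_b ~ 24 s), boundary mu ~ 0.012,
        # |delta_f| ~ 50 Hz, 47% removal
        "gel": PresetBundle(
            name="gel",
            expected_class="gel",
            flow=FlowCurveParams(300.0, 0.05, 3.0, 0.8),
            thinning=ThinningParams(
                model="power_law", sigma=0.060, K=20.0, n=0.6, t_b=24.0,
                initial_plateau=1.0, sampling_rate=100.0,
            ),
            stribeck=StribeckParams(
                boundary_mu=0.012, transition_speed=0.02, transition_sharpness=3.0,
                hydrodynamic_coeff=0.02, hydrodynamic_exponent=0.6,
                viscosity_at_contact=5.4,
            ),
            qcmd=QcmdParams(
                plateau_shift=50.0, adsorption_tau=184.0, injection_time=300.0,
                rinse_time=2700.0, removal_fraction=0.47, desorption_tau=120.0,
                duration=3900.0,
            ),
        ),
        # human saliva: very low shear viscosity (~2.5 mPa.s at 50/s, classifies as
        # liquid), elastic filament with t_b ~ 2 s, boundary mu ~ 0.02 on PDMS,
        # |delta_f| ~ 63.6 Hz, 4% removal, t_saturation ~ 30 min
        "saliva": PresetBundle(
            name="saliva",
            expected_class="liquid",
            flow=FlowCurveParams(0.02, 0.0023, 1.0, 1.0),
            thinning=ThinningParams(
                model="elastic", sigma=0.053, lambda_c=0.111,
                initial_plateau=0.1, sampling_rate=1000.0,
            ),
            stribeck=StribeckParams(
                boundary_mu=0.02, transition_speed=0.05, transition_sharpness=3.0,
                hydrodynamic_coeff=0.03, hydrodynamic_exponent=0.6,
                viscosity_at_contact=0.0025,
            ),
            qcmd=QcmdParams(
                plateau_shift=63.6, adsorption_tau=460.0, injection_time=300.0,
                rinse_time=3000.0, removal_fraction=0.04, desorption_tau=100.0,
                duration=4200.0,
            ),
        ),
    }


PRESET_NAMES = tuple(_presets().keys())


def preset(name: str) -> PresetBundle:
    """Ground-truth parameters for one of {liquid, viscous_liquid, gel, saliva}."""
    table = _presets()
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(table)}") from None
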