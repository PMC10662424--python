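"""Soft-contact tribology: Hertz pressures, friction conversion and Stribeck analysis.

Two tribometer configurations are supported:

* ball-on-disc (mini-traction machine) with a 19 mm PDMS ball on a PDMS disc,
  2.0 N normal load, sliding/rolling ratio 50% — friction coefficient is
  reported directly against entrainment speed;
* plate-on-plate with a biomimetic tongue-like lower surface — the instrument
  measures torque M at angular speed Omega, converted via mu = M / (R * F_N)
  and U = Omega * R (plate radius R = 0.025 m, F_N = 1.0 N).

A Stribeck curve (mu vs entrainment speed U) is segmented into the boundary
plateau (flat, adsorption-controlled), the mixed regime, and the hydrodynamic
rise (viscosity-controlled), using slopes of the smoothed log-log curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import ParameterError, ExtrapolationError, SegmentationError

__all__ = [
    "SphereContact",
    "PlateOnPlate",
    "FrictionCurve",
    "RegimeSegmentation",
    "hertz_sphere_contact",
    "friction_from_torque",
    "entrainment_from_angular",
    "segment_regimes",
    "friction_at",
    "percent_reduction",
]

#: default reference speeds (m/s) at which boundary friction is benchmarked
REFERENCE_SPEEDS = {"smooth_pdms": 0.01, "biomimetic_tongue": 0.0007}
#: reference speed (m/s) for hydrodynamic-regime comparison on smooth PDMS
HYDRODYNAMIC_REFERENCE_SPEED = 0.25


@dataclass(frozen=True)
class SphereContact:
    """Hertzian sphere-on-flat contact between two identical soft elastomers."""

    ball_radius: float
    load: float
    youngs_modulus: float
    poisson_ratio: float
    contact_radius: float
    mean_pressure: float
    peak_pressure: float


@dataclass
class PlateOnPlate:
    """Plate-on-plate tribometer sweep: torque vs angular speed."""

    angular_speed: np.ndarray
    torque: np.ndarray
    plate_radius: float = 0.025
    normal_force: float = 1.0

    def __post_init__(self) -> None:
        self.angular_speed = np.asarray(self.angular_speed, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if self.plate_radius <= 0 or self.normal_force <= 0:
            raise ParameterError("plate radius and normal force must be positive")
        if self.angular_speed.size != self.torque.size:
            raise ParameterError("angular_speed and torque must have equal length")

    def to_friction_curve(self, surface: str = "biomimetic_tongue") -> "FrictionCurve":
        """Convert the sweep to a Stribeck curve via mu = M/(R F_N) and U = Omega R."""
        return FrictionCurve(
            speed=entrainment_from_angular(self.angular_speed, self.plate_radius),
            mu=friction_from_torque(self.torque, self.plate_radius, self.normal_force),
            surface=surface,
        )


@dataclass
class FrictionCurve:
    """Friction coefficient versus entrainment speed (a Stribeck curve)."""

    speed: np.ndarray
    mu: np.ndarray
    surface: Literal["smooth_pdms", "biomimetic_tongue"] = "smooth_pdms"
    sliding_rolling_ratio: float = 50.0

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.speed.ndim != 1 or self.speed.size != self.mu.size:
            raise ParameterError("speed and mu must be 1-D arrays of equal length")
        if not np.all(self.speed > 0) or not np.all(np.diff(self.speed) > 0):
            raise ParameterError("speeds must be positive and strictly increasing")
        if np.any(self.mu < 0):
            raise ParameterError("friction coefficients must be non-negative")


@dataclass(frozen=True)
class RegimeSegmentation:
    """Boundary / mixed / hydrodynamic segmentation of a Stribeck curve."""

    boundary_end: float
    hydrodynamic_start: float
    boundary_mu: float
    minimum_mu: float
    minimum_speed: float


def hertz_sphere_contact(
    ball_radius: float, load: float, youngs_modulus: float, poisson_ratio: float
) -> SphereContact:
    """Classical Hertz sphere-on-flat contact, both bodies of the same material.

    Effective modulus E* = E / (2 (1 - nu^2)); contact radius
    a = (3 F R / (4 E*))^(1/3); mean pressure F / (pi a^2); peak = 1.5 * mean.
    """
    if ball_radius <= 0 or load < 0 or youngs_modulus <= 0:
        raise ParameterError("radius and modulus must be positive, load non-negative")
    if not 0 <= poisson_ratio <= 0.5:
        raise ParameterError("Poisson ratio must lie in [0, 0.5]")
    e_star = youngs_modulus / (2.0 * (1.0 - poisson_ratio**2))
    a = (3.0 * load * ball_radius / (4.0 * e_star)) ** (1.0 / 3.0)
    mean = load / (np.pi * a**2) if a > 0 else 0.0
    return SphereContact(
        ball_radius=ball_radius,
        load=load,
        youngs_modulus=youngs_modulus,
        poisson_ratio=poisson_ratio,
        contact_radius=float(a),
        mean_pressure=float(mean),
        peak_pressure=float(1.5 * mean),
    )


def friction_from_torque(torque, plate_radius: float, normal_force: float):
    """Friction coefficient mu = M / (R * F_N); vectorises over torque."""
    if plate_radius <= 0 or normal_force <= 0:
        raise ParameterError("plate radius and normal force must be positive")
    mu = np.asarray(torque, dtype=float) / (plate_radius * normal_force)
    return float(mu) if mu.ndim == 0 else mu


def entrainment_from_angular(angular_speed, plate_radius: float):
    """Entrainment speed U = Omega * R for a plate-on-plate geometry."""
    if plate_radius <= 0:
        raise ParameterError("plate radius must be positive")
    omega = np.asarray(angular_speed, dtype=float)
    if np.any(omega < 0):
        raise ParameterError("angular speed must be non-negative")
    u = omega * plate_radius
    return float(u) if u.ndim == 0 else u


def _moving_polyfit(x: np.ndarray, y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Local linear smoothing: returns (smoothed y, local slope dy/dx)."""
    half = window // 2
    n = x.size
    ys = np.empty(n)
    slope = np.empty(n)
    for i in range(n):
        # near the edges the window is shifted inward, not shrunk, so the
        # slope estimate keeps its full averaging length everywhere
        lo = min(max(0, i - half), max(0, n - window))
        hi = min(n, lo + window)
        b, a = np.polyfit(x[lo:hi], y[lo:hi], 1)
        ys[i] = a + b * x[i]
        slope[i] = b
    return ys, slope


def segment_regimes(
    curve: FrictionCurve,
    flatness_threshold: float = 0.1,
    smoothing_window: int = 5,
) -> RegimeSegmentation:
    """Segment a Stribeck curve into boundary / mixed / hydrodynamic regimes.

    On the smoothed log U - log mu curve, the boundary plateau is the initial
    low-speed run where |d log mu / d log U| stays below ``flatness_threshold``
    (its last point is ``boundary_end``); ``boundary_mu`` is the median raw mu
    over that run.  The global minimum of the smoothed curve marks the
    mixed-to-hydrodynamic transition; ``hydrodynamic_start`` is the first
    speed after it where the slope exceeds +``flatness_threshold`` (the last
    speed when the rise never steepens that far within the sweep).
    """
    log_u = np.log(curve.speed)
    if curve.speed.size < 8 or (log_u[-1] - log_u[0]) < 1.5 * np.log(10):
        raise SegmentationError("need >= 8 points spanning >= 1.5 decades of speed")
    if np.any(curve.mu <= 0):
        raise SegmentationError("segmentation requires strictly positive friction values")
    log_mu = np.log(curve.mu)
    smooth_mu, slope = _moving_polyfit(log_u, log_mu, smoothing_window)

    flat = np.abs(slope) < flatness_threshold
    if not flat[0]:
        raise SegmentationError("no boundary plateau: curve is not flat at the lowest speeds")
    plateau_len = int(np.argmin(flat)) if not flat.all() else flat.size
    boundary_end_idx = plateau_len - 1
    boundary_mu = float(np.median(curve.mu[:plateau_len]))

    # the minimum is sought from the plateau end onward so the regime ordering
    # boundary_end <= minimum_speed <= hydrodynamic_start holds by construction
    min_idx = boundary_end_idx + int(np.argmin(smooth_mu[boundary_end_idx:]))
    rising = np.nonzero(slope[min_idx:] > flatness_threshold)[0]
    hydro_idx = min_idx + int(rising[0]) if rising.size else curve.speed.size - 1
    hydro_idx = max(hydro_idx, boundary_end_idx)
    return RegimeSegmentation(
        boundary_end=float(curve.speed[boundary_end_idx]),
        hydrodynamic_start=float(curve.speed[hydro_idx]),
        boundary_mu=boundary_mu,
        minimum_mu=float(np.exp(smooth_mu[min_idx])),
        minimum_speed=float(curve.speed[min_idx]),
    )


def friction_at(curve: FrictionCurve, speed: float) -> float:
    """Friction coefficient at ``speed`` by log-log interpolation of the curve."""
    if speed < curve.speed[0] or speed > curve.speed[-1]:
        raise ExtrapolationError(
            f"speed {speed} m/s outside measured range [{curve.speed[0]}, {curve.speed[-1]}] m/s"
        )
    if np.any(curve.mu <= 0):
        # fall back to linear interpolation in mu where zeros are present
        return float(np.interp(np.log(speed), np.log(curve.speed), curve.mu))
    return float(np.exp(np.interp(np.log(speed), np.log(curve.speed), np.log(curve.mu))))


def percent_reduction(mu_sample: float, mu_reference: float) -> float:
    """Percent friction reduction of a sample against a reference, 100*(1 - mu_s/mu_r)."""
    if mu_reference <= 0:
        raise ParameterError("reference friction coefficient must be positive")
    if mu_sample < 0:
        raise ParameterError("sample friction coefficient must be non-negative")
    return 100.0 * (1.0 - mu_sample / mu_reference)
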