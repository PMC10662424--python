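"""Shear (rotational) rheology: flow curves, Cross-model fits and format classification.

A flow curve records the apparent shear viscosity ``eta_shear`` against shear
rate over several decades.  Saliva substitutes are compared at an orally
relevant shear rate of 50 1/s and binned into three format categories:

* ``liquid``          eta_shear(50/s) < 0.10 Pa.s
* ``viscous_liquid``  0.10 <= eta_shear(50/s) <= 1.0 Pa.s
* ``gel``             eta_shear(50/s) > 1.0 Pa.s

The boundary convention is closed on the viscous-liquid side: the outer
classes use strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np

from .exceptions import AlignmentError, ExtrapolationError, FitError, ParameterError

__all__ = [
    "FlowCurve",
    "ShearModelFit",
    "ViscosityClass",
    "REFERENCE_SHEAR_RATE",
    "LIQUID_THRESHOLD",
    "GEL_THRESHOLD",
    "viscosity_at",
    "fit_shear_model",
    "classify",
    "aggregate_replicates",
]

#: orally relevant shear rate used for classification, 1/s
REFERENCE_SHEAR_RATE = 50.0
#: below this apparent viscosity at the reference rate a sample is a "liquid", Pa.s
LIQUID_THRESHOLD = 0.10
#: above this apparent viscosity at the reference rate a sample is a "gel", Pa.s
GEL_THRESHOLD = 1.0


@dataclass
class FlowCurve:
    """Apparent shear viscosity versus shear rate for one replicate.

    Parameters
    ----------
    shear_rate : array of float
        Shear rates in 1/s, strictly increasing and positive.
    viscosity : array of float
        Apparent shear viscosities in Pa.s, positive.
    replicate_id : str
        Label of the replicate this curve belongs to.
    temperature : float
        Measurement temperature in deg C (metadata only).
    """

    shear_rate: np.ndarray
    viscosity: np.ndarray
    replicate_id: str = "r1"
    temperature: float = 37.0

    def __post_init__(self) -> None:
        self.shear_rate = np.asarray(self.shear_rate, dtype=float)
        self.viscosity = np.asarray(self.viscosity, dtype=float)
        if self.shear_rate.ndim != 1 or self.viscosity.ndim != 1:
            raise ParameterError("shear_rate and viscosity must be 1-D arrays")
        if self.shear_rate.size != self.viscosity.size:
            raise ParameterError("shear_rate and viscosity must have equal length")
        if self.shear_rate.size < 3:
            raise ParameterError("a flow curve needs at least 3 points")
        if not np.all(self.shear_rate > 0):
            raise ParameterError("shear rates must be positive")
        if not np.all(np.diff(self.shear_rate) > 0):
            raise ParameterError("shear rates must be strictly increasing")
        if not np.all(self.viscosity > 0):
            raise ParameterError("viscosities must be positive")


@dataclass(frozen=True)
class ShearModelFit:
    """Fitted Cross-type shear-thinning model.

    eta(rate) = eta_inf + (eta_zero - eta_inf) / (1 + (cross_time * rate)**cross_exponent)
    """

    eta_zero: float
    eta_inf: float
    cross_time: float
    cross_exponent: float
    rms_log_residual: float

    def __call__(self, rate: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the fitted apparent viscosity at the given shear rate(s), Pa.s."""
        rate = np.asarray(rate, dtype=float)
        out = self.eta_inf + (self.eta_zero - self.eta_inf) / (
            1.0 + (self.cross_time * rate) ** self.cross_exponent
        )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ViscosityClass:
    """Format category of a sample at the reference shear rate."""

    label: Literal["liquid", "viscous_liquid", "gel"]
    eta_at_reference: float
    reference_rate: float = REFERENCE_SHEAR_RATE


def viscosity_at(curve: FlowCurve, rate: float) -> float:
    """Apparent viscosity at ``rate`` by log-log linear interpolation.

    Flow curves span decades and are locally near power-law, so interpolation
    is performed on (log rate, log viscosity).  Exact node values are returned
    at the nodes.  Querying outside the measured range raises
    :class:`ExtrapolationError`; the instrument was never there.
    """
    if rate < curve.shear_rate[0] or rate > curve.shear_rate[-1]:
        raise ExtrapolationError(
            f"rate {rate} 1/s outside measured range "
            f"[{curve.shear_rate[0]}, {curve.shear_rate[-1]}] 1/s"
        )
    log_eta = np.interp(np.log(rate), np.log(curve.shear_rate), np.log(curve.viscosity))
    return float(np.exp(log_eta))


def _cross_residual(params: lmfit.Parameters, rate: np.ndarray, log_eta: np.ndarray) -> np.ndarray:
    v = params.valuesdict()
    model = v["eta_inf"] + (v["eta_zero"] - v["eta_inf"]) / (
        1.0 + (v["cross_time"] * rate) ** v["cross_exponent"]
    )
    return np.log(np.clip(model, 1e-300, None)) - log_eta


def fit_shear_model(curve: FlowCurve) -> ShearModelFit:
    """Least-squares fit of the Cross model in log-viscosity space.

    Initialisation is deterministic: ``eta_zero`` at the largest measured
    viscosity, ``eta_inf`` at the smallest, ``cross_time`` at the reciprocal
    of the rate where the curve passes its geometric-mean viscosity.
    """
    if curve.shear_rate.size < 5:
        raise ParameterError("fit_shear_model needs at least 5 points")
    rate = curve.shear_rate
    eta = curve.viscosity
    log_eta = np.log(eta)

    eta_max, eta_min = float(eta.max()), float(eta.min())
    gm = float(np.exp(0.5 * (np.log(eta_max) + np.log(eta_min))))
    idx = int(np.argmin(np.abs(np.log(eta) - np.log(gm))))
    t0 = 1.0 / float(rate[idx])

    params = lmfit.Parameters()
    params.add("eta_zero", value=eta_max, min=1e-9)
    # keep eta_inf strictly positive and below eta_zero
    params.add("eta_inf", value=max(eta_min, 1e-9), min=1e-12)
    params.add("cross_time", value=t0, min=1e-9)
    params.add("cross_exponent", value=1.0, min=0.05, max=3.0)

    result = lmfit.minimize(_cross_residual, params, args=(rate, log_eta), method="leastsq")
    if not result.success:
        raise FitError(f"Cross-model fit did not converge: {result.message}")
    v = result.params.valuesdict()
    eta_zero, eta_inf = v["eta_zero"], v["eta_inf"]
    if eta_inf > eta_zero:  # nearly Newtonian data can swap the plateaus
        eta_zero, eta_inf = eta_inf, eta_zero
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return ShearModelFit(
        eta_zero=float(eta_zero),
        eta_inf=float(eta_inf),
        cross_time=float(v["cross_time"]),
        cross_exponent=float(v["cross_exponent"]),
        rms_log_residual=rms,
    )


def classify(eta_at_50: float, reference_rate: float = REFERENCE_SHEAR_RATE) -> ViscosityClass:
    """Bin an apparent viscosity at the reference rate into the three categories."""
    if not np.isfinite(eta_at_50) or eta_at_50 <= 0:
        raise ParameterError(f"viscosity must be positive and finite, got {eta_at_50}")
    if eta_at_50 < LIQUID_THRESHOLD:
        label = "liquid"
    elif eta_at_50 <= GEL_THRESHOLD:
        label = "viscous_liquid"
    else:
        label = "gel"
    return ViscosityClass(label=label, eta_at_reference=float(eta_at_50), reference_rate=reference_rate)


def classify_curve(curve: FlowCurve, rate: float = REFERENCE_SHEAR_RATE) -> ViscosityClass:
    """Classify a flow curve by its interpolated viscosity at ``rate``."""
    return classify(viscosity_at(curve, rate), reference_rate=rate)


def aggregate_replicates(curves: Sequence[FlowCurve]) -> tuple[FlowCurve, np.ndarray]:
    """Pointwise mean flow curve and per-point sample standard deviation.

    All replicates must share an identical shear-rate grid; anything else is
    an :class:`AlignmentError` (no silent regridding).
    """
    if len(curves) < 2:
        raise AlignmentError("aggregation needs at least 2 replicate curves")
    grid = curves[0].shear_rate
    for c in curves[1:]:
        if c.shear_rate.size != grid.size or not np.allclose(c.shear_rate, grid, rtol=1e-12, atol=0.0):
            raise AlignmentError("replicate curves are not on identical shear-rate grids")
    stack = np.vstack([c.viscosity for c in curves])
    mean = FlowCurve(
        shear_rate=grid.copy(),
        viscosity=stack.mean(axis=0),
        replicate_id="mean",
        temperature=curves[0].temperature,
    )
    sd = stack.std(axis=0, ddof=1)
    return mean, sd
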