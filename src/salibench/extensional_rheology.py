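"""Capillary-breakup extensional rheometry (CaBER) analysis.

A CaBER run tracks the minimum diameter ``D_min(t)`` of the liquid filament
formed when two plates (diameter ``D_o`` = 6 mm, initial separation
``h_o`` = 3 mm, final separation ``h_f`` = 10 mm) are pulled apart.  The laser
micrometer has a 20 um resolution; diameters at or below it are censored to
that floor, which operationally defines filament breakup.

Two thinning models are fitted:

* elastic (upper-convected Maxwell) — elastocapillary balance gives an
  exponential decay, ``D_min(t) ~ exp(-t / (3 * lambda_c))``;
* power-law — ``D_min(t) = 2 * phi0 * (sigma / K) * (t_b - t)**n`` with the
  prefactor ``phi0 = 0.142``, consistency ``K`` (Pa.s^n), exponent ``n`` and
  breakup time ``t_b``.

From the diameter trace the Hencky strain ``eps = -2 ln(D_min / D_o)``, the
instantaneous strain rate ``eps_dot = -(2 / D_min) dD_min/dt``, the apparent
extensional viscosity ``eta_E = (2 sigma / D_min) / eps_dot`` and the
strain-rate-matched Trouton ratio ``Tr(eps_dot) = eta_E(eps_dot) /
eta_shear(eps_dot)`` are derived.  The Trouton denominator is the fitted shear
model evaluated at a shear rate numerically equal to the strain rate; the
conventional sqrt(3) kinematic conversion is deliberately not applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import lmfit
import numpy as np
from scipy.signal import savgol_filter

from .exceptions import AnalysisError, FitError, ParameterError
from .shear_rheology import ShearModelFit

__all__ = [
    "PHI0",
    "ThinningTrace",
    "ElasticFit",
    "PowerLawFit",
    "ExtensionalProfile",
    "detect_breakup",
    "fit_elastic",
    "fit_power_law",
    "select_model",
    "extensional_profile",
]

#: visco-capillary prefactor of the power-law thinning law (dimensionless)
PHI0 = 0.142

_PLATEAU_FRACTION = 0.95  # plateau = initial run with D > 95% of the start value
_BEADS_JUMP = 1.05  # >5% neighbour-to-neighbour diameter increase flags an instability
_FLOOR_FACTOR = 2.0  # fits ignore points below this multiple of the resolution floor,
# where censoring truncates the noise distribution and biases log-space regressions


@dataclass
class ThinningTrace:
    """Minimum filament diameter versus time from one CaBER run.

    Geometry defaults match the instrument configuration: 6 mm plates,
    3 mm initial / 10 mm final separation, 20 um laser resolution.
    """

    time: np.ndarray
    diameter: np.ndarray
    plate_diameter: float = 6e-3
    initial_separation: float = 3e-3
    final_separation: float = 10e-3
    resolution: float = 20e-6

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.diameter.size:
            raise ParameterError("time and diameter must be 1-D arrays of equal length")
        if self.time.size < 4:
            raise ParameterError("a thinning trace needs at least 4 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ParameterError("time must be strictly increasing")
        if self.resolution <= 0:
            raise ParameterError("resolution must be positive")
        if not np.all(self.diameter > 0):
            raise ParameterError("diameters must be positive")
        if np.any(self.diameter > self.plate_diameter * (1 + 1e-9)):
            raise ParameterError("diameter exceeds the plate diameter")

    @property
    def aspect_ratio(self) -> float:
        """Initial aspect ratio h_o / D_o of the liquid bridge."""
        return self.initial_separation / self.plate_diameter

    def at_floor(self) -> np.ndarray:
        """Boolean mask of samples censored at (or below) the resolution floor."""
        return self.diameter <= self.resolution * (1 + 1e-9)


@dataclass(frozen=True)
class ElasticFit:
    """Exponential (elastocapillary) thinning fit."""

    lambda_c: float
    window: tuple[float, float]
    rms_log_residual: float

    def __call__(self, t: np.ndarray, d_ref: float, t_ref: float) -> np.ndarray:
        """Model diameter anchored at ``(t_ref, d_ref)``."""
        return d_ref * np.exp(-(np.asarray(t, float) - t_ref) / (3.0 * self.lambda_c))


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law (visco-capillary) thinning fit, D = 2*phi0*(sigma/K)*(t_b - t)**n."""

    K: float
    n: float
    t_b: float
    sigma: float
    rms_log_residual: float
    phi0: float = PHI0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        dt = np.clip(self.t_b - np.asarray(t, float), 0.0, None)
        return 2.0 * self.phi0 * (self.sigma / self.K) * dt**self.n


@dataclass
class ExtensionalProfile:
    """Strain, strain rate, extensional viscosity and Trouton ratio over the valid window."""

    time: np.ndarray
    strain: np.ndarray
    strain_rate: np.ndarray
    eta_extensional: np.ndarray
    trouton: np.ndarray
    max_eta_extensional: float
    max_trouton: float
    #: indices into the original trace corresponding to the arrays above
    indices: np.ndarray


def detect_breakup(trace: ThinningTrace) -> Optional[float]:
    """Earliest time of a sustained crossing of the resolution floor.

    Returns the first time at which the diameter reaches the floor and never
    rises above it afterwards — a single noise spike below the floor is
    ignored.  ``None`` if the filament never breaks within the trace.
    """
    floor = trace.at_floor()
    if not floor[-1]:
        return None
    # last index where the trace is above the floor; breakup starts just after
    above = np.nonzero(~floor)[0]
    idx = 0 if above.size == 0 else int(above[-1]) + 1
    return float(trace.time[idx])


def _plateau_end(diameter: np.ndarray) -> int:
    """Index of the first sample past the initial plateau.

    The plateau ends where the diameter falls below 95% of the start value
    (median of the first 5 samples) for good: a single noise dip does not end
    it, so the criterion is the last excursion above the 95% level.
    """
    d_ref = float(np.median(diameter[:5]))
    above = np.nonzero(diameter > _PLATEAU_FRACTION * d_ref)[0]
    return int(above[-1]) + 1 if above.size else 0


def _fit_masks(trace: ThinningTrace) -> tuple[np.ndarray, np.ndarray]:
    """(window, keep) masks for thinning fits.

    ``window`` marks the fit region: past the initial plateau and above
    ``_FLOOR_FACTOR`` times the resolution floor.  ``keep`` additionally drops
    beads-on-a-string spikes (local >5% diameter increases) from the
    regression without breaking the window's contiguity.
    """
    d = trace.diameter
    window = np.zeros(d.size, dtype=bool)
    window[_plateau_end(d):] = True
    window &= d > _FLOOR_FACTOR * trace.resolution
    jumps = np.zeros(d.size, dtype=bool)
    jumps[1:] = d[1:] > _BEADS_JUMP * d[:-1]
    return window, window & ~jumps


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, mask.size))
    return runs


def _linfit_rms(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    rms = float(np.sqrt(np.mean((intercept + slope * t - y) ** 2)))
    return float(slope), float(intercept), rms


def fit_elastic(
    trace: ThinningTrace,
    residual_threshold: float = 0.05,
    min_points: int = 8,
) -> ElasticFit:
    """Fit ln(D) = a - t / (3 * lambda_c) over an automatically chosen window.

    The window is the longest contiguous stretch of usable points whose
    log-linear fit has an rms residual below ``residual_threshold``; if no
    stretch passes, the candidate with the smallest residual is used.  The
    search scans a deterministic grid of window lengths and offsets.
    """
    window, keep = _fit_masks(trace)
    if int(keep.sum()) < min_points:
        raise FitError("not enough usable points above the resolution floor")
    runs = _contiguous_runs(window)
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    t_all = trace.time[start:stop]
    logd_all = np.log(trace.diameter[start:stop])
    kmask = keep[start:stop]
    n = t_all.size
    if int(kmask.sum()) < min_points:
        raise FitError("not enough contiguous usable points for the elastic fit")

    best = None
    fallback = None  # smallest-rms candidate, used if no window passes the threshold
    lengths = np.unique(np.clip(np.round(n * np.linspace(1.0, 0.3, 12)).astype(int), min_points, n))
    for length in lengths[::-1]:
        starts = np.unique(np.linspace(0, n - length, min(16, n - length + 1)).astype(int))
        for s in starts:
            sel = np.zeros(n, dtype=bool)
            sel[s : s + length] = True
            sel &= kmask
            if int(sel.sum()) < min_points:
                continue
            slope, _, rms = _linfit_rms(t_all[sel], logd_all[sel])
            cand = (length, s, slope, rms)
            if fallback is None or rms < fallback[3]:
                fallback = cand
            if rms < residual_threshold:
                best = cand
                break
        if best is not None:
            break
    if best is None and fallback is None:
        raise FitError("no candidate window with enough points for the elastic fit")
    length, s, slope, rms = best if best is not None else fallback
    if slope >= 0:
        raise FitError("no exponential decay detected (non-negative slope)")
    return ElasticFit(
        lambda_c=-1.0 / (3.0 * slope),
        window=(float(t_all[s]), float(t_all[min(s + length, n) - 1])),
        rms_log_residual=rms,
    )


def fit_power_law(trace: ThinningTrace, sigma: float, min_points: int = 8) -> PowerLawFit:
    """Nonlinear least squares of the power-law thinning law in log-diameter space.

    Free parameters are (K, n, t_b); ``phi0`` is fixed at 0.142 and ``sigma``
    is the measured surface tension.  ``t_b`` is initialised from
    :func:`detect_breakup` (or the last sample plus one interval when no
    breakup is observed) and constrained to exceed the last usable sample.
    """
    if sigma <= 0:
        raise ParameterError("surface tension must be positive")
    _, keep = _fit_masks(trace)
    if int(keep.sum()) < min_points:
        raise FitError("not enough usable points for the power-law fit")
    t = trace.time[keep]
    logd = np.log(trace.diameter[keep])
    t_last = float(t[-1])
    dt = float(np.median(np.diff(trace.time)))

    tb_detected = detect_breakup(trace)
    tb0 = max(tb_detected if tb_detected is not None else t_last + dt, t_last + 0.5 * dt)

    params = lmfit.Parameters()
    params.add("t_b", value=tb0, min=t_last + 1e-6 * dt)
    params.add("n", value=1.0, min=0.05, max=1.5)
    k0 = 2.0 * PHI0 * sigma * (tb0 - t[0]) ** 1.0 / np.exp(logd[0])
    params.add("logK", value=float(np.log(k0)))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        v = p.valuesdict()
        model = np.log(2.0 * PHI0 * sigma) - v["logK"] + v["n"] * np.log(v["t_b"] - t)
        return model - logd

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitError(f"power-law fit did not converge: {result.message}")
    v = result.params.valuesdict()
    if v["t_b"] <= t_last:
        raise FitError("inconsistent breakup time: fitted t_b precedes the last usable sample")
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return PowerLawFit(K=float(np.exp(v["logK"])), n=float(v["n"]), t_b=float(v["t_b"]),
                       sigma=float(sigma), rms_log_residual=rms)


def select_model(
    trace: ThinningTrace, sigma: float
) -> tuple[Literal["elastic", "power_law"], Optional[ElasticFit], Optional[PowerLawFit]]:
    """Fit both thinning models and pick the one with the lower rms log residual.

    Ties break toward the power-law model.  Where only one model converges it
    is chosen; if both fail an :class:`AnalysisError` is raised.
    """
    elastic: Optional[ElasticFit] = None
    power: Optional[PowerLawFit] = None
    try:
        elastic = fit_elastic(trace)
    except FitError:
        pass
    try:
        power = fit_power_law(trace, sigma)
    except FitError:
        pass
    if elastic is None and power is None:
        raise AnalysisError("neither thinning model could be fitted to the trace")
    if power is None:
        return "elastic", elastic, None
    if elastic is None or power.rms_log_residual <= elastic.rms_log_residual:
        return "power_law", elastic, power
    return "elastic", elastic, power


def _smoothed_log_derivative(time: np.ndarray, logd: np.ndarray, window: int) -> np.ndarray:
    """d(ln D)/dt by local second-order polynomial smoothing."""
    dt = np.diff(time)
    if np.allclose(dt, dt[0], rtol=1e-6):
        return savgol_filter(logd, window_length=window, polyorder=2, deriv=1, delta=float(dt[0]))
    # non-uniform sampling: per-point local quadratic fit
    half = window // 2
    out = np.empty_like(logd)
    n = logd.size
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        coeffs = np.polyfit(time[lo:hi] - time[i], logd[lo:hi], 2)
        out[i] = coeffs[1]
    return out


def extensional_profile(
    trace: ThinningTrace,
    sigma: float,
    shear_fit: ShearModelFit,
    rate_floor: float = 1e-3,
    smooth_fraction: float = 0.05,
    min_smooth_points: int = 5,
) -> ExtensionalProfile:
    """Hencky strain, strain rate, extensional viscosity and Trouton ratio.

    The strain rate comes from a local second-order polynomial derivative of
    ln(D) (window ``smooth_fraction`` of the trace length, at least
    ``min_smooth_points`` samples).  The valid window keeps points whose
    diameter lies strictly between the resolution floor and 95% of the
    post-plateau start value and whose strain rate exceeds ``rate_floor``
    (the extensional viscosity is singular as the strain rate vanishes).
    Maxima of the extensional viscosity and the Trouton ratio are taken
    independently over that window.
    """
    if sigma <= 0:
        raise ParameterError("surface tension must be positive")
    d = trace.diameter
    t = trace.time
    n = d.size
    window = max(min_smooth_points, int(round(smooth_fraction * n)))
    if window % 2 == 0:
        window += 1
    window = min(window, n if n % 2 == 1 else n - 1)

    logd = np.log(d)
    dlogd = _smoothed_log_derivative(t, logd, window)
    strain_rate = -2.0 * dlogd
    strain = -2.0 * np.log(d / trace.plate_diameter)

    with np.errstate(divide="ignore", invalid="ignore"):
        eta_ext = np.where(strain_rate > 0, (2.0 * sigma / d) / strain_rate, np.nan)
        trouton = eta_ext / np.asarray(shear_fit(np.clip(strain_rate, 1e-300, None)))

    p = _plateau_end(d)
    if p >= n:
        raise AnalysisError("no valid thinning region: trace never leaves the plateau")
    d_start = d[p]
    valid = (
        (d < _PLATEAU_FRACTION * d_start)
        & ~trace.at_floor()
        & (strain_rate > rate_floor)
        & np.isfinite(eta_ext)
    )
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        raise AnalysisError("no valid thinning region")
    return ExtensionalProfile(
        time=t[idx],
        strain=strain[idx],
        strain_rate=strain_rate[idx],
        eta_extensional=eta_ext[idx],
        trouton=trouton[idx],
        max_eta_extensional=float(np.nanmax(eta_ext[idx])),
        max_trouton=float(np.nanmax(trouton[idx])),
        indices=idx,
    )
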