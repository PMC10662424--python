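"""QCM-D adsorption/desorption analysis of lubricant coating behaviour.

A quartz-crystal-microbalance trace records the resonance-frequency shift
``delta_f`` over time while a lubricant is injected over a PDMS-coated sensor
(adsorption drives ``delta_f`` negative, proportionally to the adsorbed mass)
and later rinsed with buffer (desorption drives it back toward baseline).

Three quantities summarise a trace:

* ``t_saturation`` — time from injection until |delta_f| reaches its
  adsorption plateau (criterion: sustained crossing of 98% of the pre-rinse
  plateau), characteristic of the adsorption kinetics;
* the plateau magnitudes |delta_f| before and after rinsing;
* the desorption extent, ``100 * (before - after) / before`` — the fraction of
  the hydration layer removed by rinsing.  A low desorption extent indicates a
  durable coating (the "in vitro coating index" reads this removal percentage:
  higher removal, poorer coating).

Summaries report magnitudes |delta_f| throughout; the sign convention
(negative on adsorption) lives only in the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AnalysisError, ParameterError

__all__ = [
    "QcmdTrace",
    "AdsorptionSummary",
    "plateau_frequencies",
    "saturation_time",
    "desorption_extent",
    "summarize",
]

_PLATEAU_WINDOW_FRACTION = 0.10  # trailing fraction of each phase used for the plateau median
_MIN_WINDOW_SAMPLES = 20


@dataclass
class QcmdTrace:
    """Resonance-frequency shift versus time with injection and rinse markers."""

    time: np.ndarray
    delta_f: np.ndarray
    injection_time: float
    rinse_time: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.delta_f.size:
            raise ParameterError("time and delta_f must be 1-D arrays of equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ParameterError("time must be strictly increasing")
        if self.rinse_time <= self.injection_time:
            raise ParameterError("rinse_time must exceed injection_time")
        if not (self.time[0] <= self.injection_time and self.rinse_time <= self.time[-1]):
            raise ParameterError("injection and rinse markers must lie within the trace")


@dataclass(frozen=True)
class AdsorptionSummary:
    """Headline adsorption/desorption quantities of one QCM-D run."""

    t_saturation: float  # s, from injection
    delta_f_before: float  # Hz, |delta_f| plateau before rinsing
    delta_f_after: float  # Hz, |delta_f| plateau after rinsing
    removal_percent: float
    coating_index_note: str = (
        "removal_percent is the desorption extent; higher removal means a poorer in vitro coating"
    )

    @property
    def t_saturation_min(self) -> float:
        """Saturation time in minutes, as rendered in reports."""
        return self.t_saturation / 60.0


def _trailing_median(values: np.ndarray) -> float:
    n = max(_MIN_WINDOW_SAMPLES, int(round(_PLATEAU_WINDOW_FRACTION * values.size)))
    if values.size < _MIN_WINDOW_SAMPLES:
        raise AnalysisError(
            f"plateau window too short: {values.size} samples (< {_MIN_WINDOW_SAMPLES})"
        )
    return float(np.median(values[-min(n, values.size):]))


def plateau_frequencies(trace: QcmdTrace) -> tuple[float, float]:
    """|delta_f| plateaus before and after rinsing.

    Each plateau is the median of the trailing 10% of its phase (adsorption:
    injection to rinse; post-rinse: rinse to end of trace); medians over
    trailing windows resist drift and spikes.
    """
    adsorption = trace.delta_f[(trace.time >= trace.injection_time) & (trace.time < trace.rinse_time)]
    post_rinse = trace.delta_f[trace.time >= trace.rinse_time]
    before = abs(_trailing_median(adsorption))
    after = abs(_trailing_median(post_rinse))
    return before, after


def saturation_time(
    trace: QcmdTrace, fraction: float = 0.98, smooth_window: int = 41
) -> float:
    """Time from injection to the sustained crossing of ``fraction`` x the plateau.

    The trace is median-smoothed (window ``smooth_window`` samples) before the
    criterion is applied, so single noise excursions neither trigger nor defer
    saturation; the crossing must then hold until the rinse.
    """
    if not 0 < fraction < 1:
        raise ParameterError("fraction must lie in (0, 1)")
    before, _ = plateau_frequencies(trace)
    if before <= 0:
        raise AnalysisError("no adsorption signal: pre-rinse plateau is zero")
    sel = (trace.time >= trace.injection_time) & (trace.time < trace.rinse_time)
    t = trace.time[sel]
    mag = np.abs(_rolling_median(trace.delta_f[sel], smooth_window))
    above = mag >= fraction * before
    if not above[-1]:
        raise AnalysisError("no saturation before rinse")
    below = np.nonzero(~above)[0]
    idx = 0 if below.size == 0 else int(below[-1]) + 1
    return float(t[idx] - trace.injection_time)


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or values.size < window:
        return values
    half = window // 2
    # windows are shifted inward at the edges (never shrunk), so the first and
    # last samples are smoothed as strongly as the interior
    medians = np.median(np.lib.stride_tricks.sliding_window_view(values, window), axis=1)
    idx = np.clip(np.arange(values.size) - half, 0, values.size - window)
    return medians[idx]


def desorption_extent(delta_f_before: float, delta_f_after: float) -> float:
    """Percentage of the adsorbed layer removed by rinsing.

    May be negative when adsorption continued after the rinse; the value is
    reported as computed, not clamped.
    """
    if delta_f_before <= 0:
        raise ParameterError("pre-rinse plateau must be positive")
    return 100.0 * (delta_f_before - delta_f_after) / delta_f_before


def summarize(trace: QcmdTrace, fraction: float = 0.98) -> AdsorptionSummary:
    """Full adsorption/desorption summary of one trace."""
    before, after = plateau_frequencies(trace)
    t_sat = saturation_time(trace, fraction=fraction)
    return AdsorptionSummary(
        t_saturation=t_sat,
        delta_f_before=before,
        delta_f_after=after,
        removal_percent=desorption_extent(before, after),
    )
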