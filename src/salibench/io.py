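"""Delimited-text I/O for the four instrument dialects.

One series per file, header row mandatory:

* flow curves:      ``shear_rate_per_s,viscosity_pa_s,replicate``
* thinning traces:  ``time_s,diameter_m``
* friction sweeps:  ``speed_m_per_s,mu`` or ``omega_per_s,torque_n_m``
* QCM-D traces:     ``time_s,delta_f_hz``

A YAML manifest can record ground-truth parameters and seeds alongside
generated files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .exceptions import ParameterError
from .extensional_rheology import ThinningTrace
from .qcmd_adsorption import QcmdTrace
from .shear_rheology import FlowCurve
from .tribology import FrictionCurve, PlateOnPlate

__all__ = [
    "read_flow_curves", "write_flow_curves",
    "read_thinning_trace", "write_thinning_trace",
    "read_friction_curve", "write_friction_curve",
    "read_qcmd_trace", "write_qcmd_trace",
    "write_manifest", "read_manifest",
]

_FLOAT_FMT = "%.10g"


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing required column(s) {missing}")


def write_flow_curves(path: str | Path, curves: Sequence[FlowCurve]) -> None:
    frames = [
        pd.DataFrame(
            {
                "shear_rate_per_s": c.shear_rate,
                "viscosity_pa_s": c.viscosity,
                "replicate": c.replicate_id,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_flow_curves(path: str | Path) -> list[FlowCurve]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["shear_rate_per_s", "viscosity_pa_s", "replicate"], path)
    return [
        FlowCurve(
            shear_rate=g["shear_rate_per_s"].to_numpy(),
            viscosity=g["viscosity_pa_s"].to_numpy(),
            replicate_id=str(rep),
        )
        for rep, g in df.groupby("replicate", sort=True)
    ]


def write_thinning_trace(path: str | Path, trace: ThinningTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "diameter_m": trace.diameter}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_thinning_trace(path: str | Path, **geometry) -> ThinningTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "diameter_m"], path)
    return ThinningTrace(time=df["time_s"].to_numpy(), diameter=df["diameter_m"].to_numpy(), **geometry)


def write_friction_curve(path: str | Path, curve: FrictionCurve) -> None:
    pd.DataFrame({"speed_m_per_s": curve.speed, "mu": curve.mu}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_friction_curve(path: str | Path, surface: str = "smooth_pdms", **plate_kwargs) -> FrictionCurve:
    """Read either friction dialect; torque sweeps are converted via mu = M/(R F_N)."""
    path = Path(path)
    df = pd.read_csv(path)
    if {"speed_m_per_s", "mu"} <= set(df.columns):
        return FrictionCurve(
            speed=df["speed_m_per_s"].to_numpy(), mu=df["mu"].to_numpy(), surface=surface
        )
    if {"omega_per_s", "torque_n_m"} <= set(df.columns):
        sweep = PlateOnPlate(
            angular_speed=df["omega_per_s"].to_numpy(),
            torque=df["torque_n_m"].to_numpy(),
            **plate_kwargs,
        )
        return sweep.to_friction_curve(surface=surface)
    raise ParameterError(
        f"{path}: expected columns speed_m_per_s,mu or omega_per_s,torque_n_m"
    )


def write_qcmd_trace(path: str | Path, trace: QcmdTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "delta_f_hz": trace.delta_f}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_qcmd_trace(path: str | Path, injection_time: float, rinse_time: float) -> QcmdTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "delta_f_hz"], path)
    return QcmdTrace(
        time=df["time_s"].to_numpy(),
        delta_f=df["delta_f_hz"].to_numpy(),
        injection_time=injection_time,
        rinse_time=rinse_time,
    )


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_manifest(path: str | Path, manifest: dict) -> None:
    """Record ground-truth parameters and seeds alongside generated files."""
    with open(path, "w") as fh:
        yaml.safe_dump(_as_plain(manifest), fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
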