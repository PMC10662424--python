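"""End-to-end benchmarking of lubricant samples.

``run_benchmark`` executes the four analysis stages (shear classification,
CaBER thinning fits, Stribeck tribology, QCM-D adsorption) over a manifest of
samples and assembles a benchmark table mirroring the per-sample summary a
comparative lubricant study reports: format class, viscosity at 50 1/s,
breakup time, maximum extensional viscosity and Trouton ratio, boundary
friction at the reference speed per surface, desorption extent and saturation
time.

Manifest schema (YAML/dict)::

    reference_rate: 50.0                # 1/s
    reference_speeds:                   # m/s, per tribometer surface
      smooth_pdms: 0.01
      biomimetic_tongue: 0.0007
    n_replicates: 3
    samples:
      - name: gel-like
        preset: gel                     # generate all four modalities
        seed: 11
      - name: measured
        sigma: 0.06                     # N/m, needed for CaBER analysis
        flow_curve: flow.csv
        thinning: caber.csv
        friction: {smooth_pdms: stribeck.csv}
        qcmd: {file: qcmd.csv, injection_time: 300, rinse_time: 2700}

Per-sample failures are recorded in the table, not fatal to the run.
Statistical significance marks are not computed here; the rendered CSV keeps
an empty ``p_value`` hook column for externally computed tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .exceptions import SalibenchError
from .extensional_rheology import ThinningTrace, detect_breakup, extensional_profile, select_model
from .qcmd_adsorption import QcmdTrace, summarize
from .shear_rheology import (
    REFERENCE_SHEAR_RATE,
    FlowCurve,
    aggregate_replicates,
    classify,
    fit_shear_model,
    viscosity_at,
)
from .synthetic_data import (
    PresetBundle,
    generate_flow_curve,
    generate_friction_curve,
    generate_qcmd_trace,
    generate_thinning_trace,
    preset,
)
from .tribology import REFERENCE_SPEEDS, FrictionCurve, friction_at, percent_reduction, segment_regimes

__all__ = ["SampleRecord", "BenchmarkTable", "run_benchmark", "reduction_matrix", "render"]

_CSV_COLUMNS = [
    "name", "viscosity_class", "eta_at_50_pa_s", "thinning_model", "t_b_s",
    "max_eta_extensional_pa_s", "max_trouton",
    "mu_smooth_pdms", "mu_biomimetic_tongue", "boundary_mu",
    "delta_f_before_hz", "delta_f_after_hz", "removal_percent", "t_saturation_min",
    "p_value", "error",
]


@dataclass
class SampleRecord:
    """Per-sample benchmark summary; absent modalities leave fields at None."""

    name: str
    viscosity_class: Optional[str] = None
    eta_at_50: Optional[float] = None
    thinning_model: Optional[str] = None
    t_b: Optional[float] = None
    max_eta_extensional: Optional[float] = None
    max_trouton: Optional[float] = None
    boundary_mu_by_surface: dict = field(default_factory=dict)
    boundary_mu_plateau: Optional[float] = None
    delta_f_before: Optional[float] = None
    delta_f_after: Optional[float] = None
    removal_percent: Optional[float] = None
    t_saturation: Optional[float] = None
    error: Optional[str] = None
    # raw analysed curves kept for plotting and reduction matrices (not serialised)
    friction_curves: dict = field(default_factory=dict, repr=False)
    raw: dict = field(default_factory=dict, repr=False)


@dataclass
class BenchmarkTable:
    """Collection of sample records plus the reference conditions used."""

    records: list[SampleRecord]
    reference_speeds: dict
    reference_rate: float = REFERENCE_SHEAR_RATE

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")

    def get(self, name: str) -> SampleRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)


def _derived_seed(seed: int, *tags: int) -> int:
    """Deterministic per-modality child seed below 2**31."""
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _analyze_sample(sample: dict, defaults: dict) -> SampleRecord:
    name = str(sample["name"])
    rec = SampleRecord(name=name)
    n_rep = int(sample.get("n_replicates", defaults.get("n_replicates", 3)))
    ref_rate = defaults["reference_rate"]
    ref_speeds = defaults["reference_speeds"]
    base = Path(defaults.get("base_dir", "."))

    bundle: Optional[PresetBundle] = None
    if "preset" in sample:
        bundle = preset(sample["preset"])
        seed = int(sample.get("seed", 0))
        sigma = float(sample.get("sigma", bundle.thinning.sigma))
    else:
        sigma = float(sample["sigma"]) if "sigma" in sample else None

    # --- shear rheology ---------------------------------------------------
    if bundle is not None:
        curves = generate_flow_curve(
            dataclasses.replace(bundle.flow, n_replicates=max(n_rep, 2)),
            _derived_seed(seed, 1),
        )
    elif "flow_curve" in sample:
        curves = sio.read_flow_curves(base / sample["flow_curve"])
    else:
        curves = None
    shear_fit = None
    if curves is not None:
        mean_curve, _ = aggregate_replicates(curves) if len(curves) > 1 else (curves[0], None)
        rec.eta_at_50 = viscosity_at(mean_curve, ref_rate)
        rec.viscosity_class = classify(rec.eta_at_50, reference_rate=ref_rate).label
        shear_fit = fit_shear_model(mean_curve)
        rec.raw["flow_curve"] = mean_curve

    # --- extensional rheology --------------------------------------------
    traces: list[ThinningTrace] = []
    if bundle is not None:
        traces = [
            generate_thinning_trace(bundle.thinning, _derived_seed(seed, 2, i)) for i in range(n_rep)
        ]
    elif "thinning" in sample:
        traces = [sio.read_thinning_trace(base / sample["thinning"])]
    if traces:
        if sigma is None:
            raise SalibenchError(f"sample {name!r}: thinning analysis requires sigma")
        choices, t_bs, etas, trs = [], [], [], []
        for tr in traces:
            choice, efit, pfit = select_model(tr, sigma)
            choices.append(choice)
            tb = detect_breakup(tr)
            if tb is None and pfit is not None and choice == "power_law":
                tb = pfit.t_b
            if tb is not None:
                t_bs.append(tb)
            if shear_fit is not None:
                prof = extensional_profile(tr, sigma, shear_fit)
                etas.append(prof.max_eta_extensional)
                trs.append(prof.max_trouton)
        rec.thinning_model = max(set(choices), key=choices.count)
        rec.t_b = float(np.mean(t_bs)) if t_bs else None
        rec.max_eta_extensional = float(np.mean(etas)) if etas else None
        rec.max_trouton = float(np.mean(trs)) if trs else None
        rec.raw["thinning"] = traces[0]

    # --- tribology --------------------------------------------------------
    friction_sources: dict[str, FrictionCurve] = {}
    if bundle is not None:
        reps = [
            generate_friction_curve(bundle.stribeck, _derived_seed(seed, 3, i)) for i in range(n_rep)
        ]
        mean_mu = np.mean(np.vstack([c.mu for c in reps]), axis=0)
        friction_sources["smooth_pdms"] = FrictionCurve(
            speed=reps[0].speed, mu=mean_mu, surface="smooth_pdms"
        )
    elif "friction" in sample:
        fr = sample["friction"]
        if isinstance(fr, str):
            fr = {"smooth_pdms": fr}
        for surface, fname in fr.items():
            friction_sources[surface] = sio.read_friction_curve(base / fname, surface=surface)
    for surface, curve in friction_sources.items():
        ref_speed = ref_speeds.get(surface)
        if ref_speed is not None:
            rec.boundary_mu_by_surface[surface] = friction_at(curve, ref_speed)
        seg = segment_regimes(curve)
        rec.boundary_mu_plateau = seg.boundary_mu
        rec.friction_curves[surface] = curve

    # --- QCM-D ------------------------------------------------------------
    qtrace: Optional[QcmdTrace] = None
    if bundle is not None:
        reps = [generate_qcmd_trace(bundle.qcmd, _derived_seed(seed, 4, i)) for i in range(n_rep)]
        mean_f = np.mean(np.vstack([t.delta_f for t in reps]), axis=0)
        qtrace = QcmdTrace(
            time=reps[0].time, delta_f=mean_f,
            injection_time=bundle.qcmd.injection_time, rinse_time=bundle.qcmd.rinse_time,
        )
    elif "qcmd" in sample:
        q = sample["qcmd"]
        qtrace = sio.read_qcmd_trace(
            base / q["file"], injection_time=float(q["injection_time"]),
            rinse_time=float(q["rinse_time"]),
        )
    if qtrace is not None:
        summary = summarize(qtrace)
        rec.delta_f_before = summary.delta_f_before
        rec.delta_f_after = summary.delta_f_after
        rec.removal_percent = summary.removal_percent
        rec.t_saturation = summary.t_saturation
        rec.raw["qcmd"] = qtrace
    return rec


def run_benchmark(manifest: dict, base_dir: str | Path = ".") -> BenchmarkTable:
    """Run every analysis stage over each sample in the manifest.

    Samples either name a preset (with a seed) or point at instrument CSV
    files; missing modalities leave the corresponding fields absent.  A
    failing sample is recorded with its error message and does not abort the
    other samples.
    """
    defaults = {
        "reference_rate": float(manifest.get("reference_rate", REFERENCE_SHEAR_RATE)),
        "reference_speeds": {**REFERENCE_SPEEDS, **manifest.get("reference_speeds", {})},
        "n_replicates": int(manifest.get("n_replicates", 3)),
        "base_dir": base_dir,
    }
    records = []
    for sample in manifest.get("samples", []):
        try:
            records.append(_analyze_sample(sample, defaults))
        except Exception as exc:  # error isolation: flag the row, keep going
            records.append(SampleRecord(name=str(sample.get("name", "?")), error=str(exc)))
    return BenchmarkTable(
        records=records,
        reference_speeds=defaults["reference_speeds"],
        reference_rate=defaults["reference_rate"],
    )


def reduction_matrix(
    table: BenchmarkTable,
    reference_class: str,
    speed: Optional[float] = None,
    surface: str = "smooth_pdms",
) -> pd.DataFrame:
    """Pairwise percent friction reduction against every sample of ``reference_class``.

    Entry (i, j) is 100 * (1 - mu_i / mu_j) at the given speed (default: the
    table's reference speed for the surface).  Cells with missing friction
    data are left absent (NaN).
    """
    if speed is None:
        speed = table.reference_speeds.get(surface)

    def mu_of(rec: SampleRecord) -> Optional[float]:
        curve = rec.friction_curves.get(surface)
        if curve is None:
            return rec.boundary_mu_by_surface.get(surface)
        try:
            return friction_at(curve, speed)
        except SalibenchError:
            return None

    refs = [r for r in table.records if r.viscosity_class == reference_class]
    out = pd.DataFrame(
        index=[r.name for r in table.records], columns=[r.name for r in refs], dtype=float
    )
    for rec in table.records:
        mu_s = mu_of(rec)
        for ref in refs:
            mu_r = mu_of(ref)
            if mu_s is not None and mu_r is not None and mu_r > 0:
                out.loc[rec.name, ref.name] = percent_reduction(mu_s, mu_r)
    return out


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def table_frame(table: BenchmarkTable) -> pd.DataFrame:
    """Benchmark table as a string DataFrame with stable column order."""
    rows = []
    for r in table.records:
        rows.append(
            {
                "name": r.name,
                "viscosity_class": _fmt(r.viscosity_class),
                "eta_at_50_pa_s": _fmt(r.eta_at_50),
                "thinning_model": _fmt(r.thinning_model),
                "t_b_s": _fmt(r.t_b),
                "max_eta_extensional_pa_s": _fmt(r.max_eta_extensional),
                "max_trouton": _fmt(r.max_trouton),
                "mu_smooth_pdms": _fmt(r.boundary_mu_by_surface.get("smooth_pdms")),
                "mu_biomimetic_tongue": _fmt(r.boundary_mu_by_surface.get("biomimetic_tongue")),
                "boundary_mu": _fmt(r.boundary_mu_plateau),
                "delta_f_before_hz": _fmt(r.delta_f_before),
                "delta_f_after_hz": _fmt(r.delta_f_after),
                "removal_percent": _fmt(r.removal_percent),
                "t_saturation_min": _fmt(r.t_saturation / 60.0 if r.t_saturation is not None else None),
                "p_value": "",  # hook for externally computed significance tests
                "error": _fmt(r.error),
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS, dtype=str)


def render(table: BenchmarkTable, out_dir: str | Path) -> list[Path]:
    """Write the benchmark CSV, a YAML run log, and comparison plots.

    Re-rendering the same table produces byte-identical CSV output; absent
    fields become empty cells.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "benchmark.csv"
    table_frame(table).to_csv(csv_path, index=False)
    written.append(csv_path)

    log_path = out / "run_log.yaml"
    from . import __version__

    log = {
        "version": __version__,
        "reference_rate_per_s": table.reference_rate,
        "reference_speeds_m_per_s": dict(table.reference_speeds),
        "samples": [{"name": r.name, "error": r.error} for r in table.records],
    }
    with open(log_path, "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    written.append(log_path)

    panels = [
        ("flow_curve", "flow_curves.png", "shear rate (1/s)", "viscosity (Pa s)",
         lambda ax, d, label: ax.loglog(d.shear_rate, d.viscosity, label=label)),
        ("thinning", "thinning_traces.png", "time (s)", "diameter (m)",
         lambda ax, d, label: ax.semilogy(d.time, d.diameter, label=label)),
        ("qcmd", "qcmd_traces.png", "time (s)", "delta f (Hz)",
         lambda ax, d, label: ax.plot(d.time, d.delta_f, label=label)),
    ]
    for key, fname, xlabel, ylabel, plot in panels:
        if not any(key in r.raw for r in table.records):
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for r in table.records:
            if key in r.raw:
                plot(ax, r.raw[key], r.name)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    if any(r.friction_curves for r in table.records):
        fig, ax = plt.subplots(figsize=(5, 4))
        for r in table.records:
            for surface, curve in r.friction_curves.items():
                ax.loglog(curve.speed, curve.mu, label=f"{r.name} ({surface})")
        ax.set_xlabel("entrainment speed (m/s)")
        ax.set_ylabel("friction coefficient")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out / "stribeck_curves.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
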