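"""End-to-end orchestration: simulate or load traces, preprocess, correlate,
fit, calibrate, convert, and aggregate.

The per-cell chain follows the measurement workflow: bleach detrend both
channels, correlate (GG, RR, GR), fit the autocorrelations, correct the
fitted amplitudes for uncorrelated background, convert to D and c with the
channel's calibration, and record the short-lag cross-correlation amplitude
as the co-diffusion readout.  A failing stage flags the affected channel
and excludes it from summaries; the cell stays in the audit log.

Per-cell seeds derive from the master seed by a counter scheme
(SeedSequence([seed, condition_index, cell_index])), so cells are
independent yet individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .calibration import Calibration, calibrate, from_geometry, to_concentration, to_diffusion
from .correlate import CorrelationCurve, correlate_multitau, zero_lag_amplitude
from .ensemble import CellMeasurement, compare_groups, summarize
from .fitting import DiffusionFit, fit_curve
from .preprocess import BackgroundEstimate, detrend, fit_bleach, correct_background
from .synthetic import (DetectionVolume, IntensityTrace, SimulationConfig,
                        SpeciesSpec, mean_count_rate, simulate_trace)

__all__ = ["AnalysisSettings", "CellResult", "RunConfig", "run_cell",
           "run_experiment", "simulate_dye_calibration"]


@dataclass(frozen=True)
class AnalysisSettings:
    m_per_octave: int = 16
    max_lag: float | None = None
    n_blocks: int = 10
    min_lag_factor: float = 5.0   # short-lag cut for fits, in base-bin units
    chi2_max: float = 5.0         # QC threshold on reduced chi^2
    coarse_bin: float | None = None
    cross_points: int = 6
    float_offset: bool = True


@dataclass
class CellResult:
    cell_id: str
    measurements: list[CellMeasurement]
    curves: dict[str, CorrelationCurve]
    fits: dict[str, DiffusionFit]
    cross_amplitude: float
    cross_se: float
    bleach: dict


def run_cell(trace: IntensityTrace, calib_G: Calibration, calib_R: Calibration,
             background: BackgroundEstimate,
             settings: AnalysisSettings = AnalysisSettings(),
             cell_id: str = "", condition: str = "",
             compartment: str = "") -> CellResult:
    """Analyze one two-channel trace into a pair of cell measurements."""
    bleach = {}
    work = trace
    for ch in ("G", "R"):
        model = fit_bleach(work, ch, settings.coarse_bin)
        bleach[ch] = model
        work = detrend(work, model)

    curves = {pair: correlate_multitau(work, pair, settings.m_per_octave,
                                       settings.max_lag, settings.n_blocks)
              for pair in ("GG", "RR", "GR")}
    cross_amp, cross_se = zero_lag_amplitude(curves["GR"], settings.cross_points)

    min_lag = settings.min_lag_factor * trace.bin_width
    calibs = {"G": calib_G, "R": calib_R}
    fits: dict[str, DiffusionFit] = {}
    measurements = []
    for ch, pair in (("G", "GG"), ("R", "RR")):
        cal = calibs[ch]
        fit = fit_curve(curves[pair], cal.kappa, min_lag=min_lag,
                        float_offset=settings.float_offset)
        fits[ch] = fit
        flags = []
        D = c = N_corr = np.nan
        rate = mean_count_rate(work, ch)
        if not fit.converged:
            flags.append("fit_failed")
        else:
            if fit.chi2_reduced > settings.chi2_max:
                flags.append("chi2_high")
            try:
                N_corr, _ = correct_background(fit.N, rate, background, ch)
            except ValueError:
                flags.append("background_exceeds_signal")
            else:
                D = to_diffusion(fit, cal)
                c = to_concentration(N_corr, cal)
        measurements.append(CellMeasurement(
            cell_id=cell_id, compartment=compartment, condition=condition,
            channel=ch, D=D, c=c,
            N_apparent=fit.N if fit.converged else np.nan,
            N_corrected=N_corr, tau_D=fit.tau_D if fit.converged else np.nan,
            chi2_reduced=fit.chi2_reduced, mean_rate=rate,
            cross_amplitude=cross_amp, cross_se=cross_se,
            qc_flags=tuple(flags)))
    return CellResult(cell_id=cell_id, measurements=measurements,
                      curves=curves, fits=fits, cross_amplitude=cross_amp,
                      cross_se=cross_se, bleach=bleach)


# ---------------------------------------------------------------------------
# experiment-level configuration


@dataclass(frozen=True)
class DyeSpec:
    """Reference-dye measurement emulated for calibration of one channel.

    Dilute (few-nM) samples give large correlation amplitudes and hence the
    best diffusion-time precision per unit of acquisition; several repeat
    traces are averaged before fitting, as in routine instrument
    calibration.
    """

    name: str
    D_ref: float               # um^2/s, literature value for the dye
    concentration: float = 5.0    # nM
    brightness: float = 250000.0  # Hz per molecule (bright dye, high power)
    duration: float = 0.8         # s per repeat
    base_bin: float = 1e-6        # s
    time_step: float = 1e-6       # s
    n_repeats: int = 8


@dataclass
class ConditionSpec:
    name: str
    species: list[SpeciesSpec]
    compartment: str = "cytosol"
    n_cells: int | None = None


@dataclass
class RunConfig:
    seed: int = 0
    n_cells: int = 10
    duration: float = 1.0
    base_bin: float = 2e-5
    time_step: float = 2e-5
    box_factor: float = 5.0
    volume: DetectionVolume = field(default_factory=DetectionVolume)
    conditions: list[ConditionSpec] = field(default_factory=list)
    background: dict[str, BackgroundEstimate] = field(default_factory=dict)
    dyes: dict[str, DyeSpec] | None = None
    geometry: dict | None = None   # {"omega_xy": .., "kappa": ..} alternative
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        vol = DetectionVolume(**doc.get("volume", {}))
        conditions = []
        for c in doc.get("conditions", []):
            species = [SpeciesSpec(**s) for s in c.get("species", [])]
            conditions.append(ConditionSpec(
                name=c["name"], species=species,
                compartment=c.get("compartment", "cytosol"),
                n_cells=c.get("n_cells")))
        background = {}
        for comp, b in doc.get("background", {}).items():
            background[comp] = BackgroundEstimate(
                B_G=float(b.get("G", 0.0)), B_R=float(b.get("R", 0.0)),
                source=comp, n_cells=int(b.get("n_cells", 1)))
        cal = doc.get("calibration", {})
        dyes = None
        if "dye" in cal:
            dyes = {ch: DyeSpec(**d) for ch, d in cal["dye"].items()}
        geometry = cal.get("geometry")
        settings = AnalysisSettings(**doc.get("analysis", {}))
        return cls(seed=int(doc.get("seed", 0)),
                   n_cells=int(doc.get("n_cells", 10)),
                   duration=float(doc.get("duration", 1.0)),
                   base_bin=float(doc.get("base_bin", 2e-5)),
                   time_step=float(doc.get("time_step", 2e-5)),
                   box_factor=float(doc.get("box_factor", 5.0)),
                   volume=vol, conditions=conditions, background=background,
                   dyes=dyes, geometry=geometry, settings=settings)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return vars(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        blob = json.dumps(vars(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cell_seed(master: int, cond_index: int, cell_index: int) -> int:
    ss = np.random.SeedSequence([int(master), int(cond_index), int(cell_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_dye_calibration(dye: DyeSpec, channel: str, volume: DetectionVolume,
                             box_factor: float, seed: int,
                             settings: AnalysisSettings = AnalysisSettings(),
                             ) -> tuple[Calibration, DiffusionFit]:
    """Simulate repeat dye measurements and calibrate one channel.

    The ``n_repeats`` traces share one lag grid; their correlation curves
    are averaged pointwise before the single calibration fit, and the fit
    window is capped at 50 expected diffusion times so the baseline cannot
    trade against tau_D deep in the noise-dominated tail.
    """
    bright = {"brightness_G": dye.brightness} if channel == "G" else \
             {"brightness_R": dye.brightness}
    tau_expected = volume.omega_xy**2 / (4.0 * dye.D_ref)
    max_lag = min(50.0 * tau_expected, dye.duration / 5.0)
    seeds = np.random.SeedSequence(seed).generate_state(dye.n_repeats)
    curves = []
    for s in seeds:
        cfg = SimulationConfig(
            volume=volume,
            species=(SpeciesSpec(name=dye.name, D=dye.D_ref,
                                 concentration=dye.concentration, **bright),),
            duration=dye.duration, base_bin=dye.base_bin,
            time_step=dye.time_step, box_factor=box_factor,
            seed=int(s % (2**31)))
        trace = simulate_trace(cfg, metadata={"sample": dye.name})
        curves.append(correlate_multitau(trace, channel * 2,
                                         settings.m_per_octave, max_lag,
                                         settings.n_blocks))
    avg = CorrelationCurve(
        lags=curves[0].lags,
        G=np.mean([c.G for c in curves], axis=0),
        G_err=np.mean([c.G_err for c in curves], axis=0)
        / np.sqrt(len(curves)),
        pair=curves[0].pair,
        mean_rate_A=float(np.mean([c.mean_rate_A for c in curves])),
        mean_rate_B=float(np.mean([c.mean_rate_B for c in curves])),
        duration=curves[0].duration)
    fit = fit_curve(avg, volume.kappa,
                    min_lag=settings.min_lag_factor * dye.base_bin,
                    float_offset=settings.float_offset)
    return calibrate(fit, dye.D_ref, volume.kappa, dye.name), fit


def _calibrations(config: RunConfig) -> dict[str, Calibration]:
    if config.dyes:
        out = {}
        for i, (ch, dye) in enumerate(sorted(config.dyes.items())):
            seed = _cell_seed(config.seed, 10_000 + i, 0)
            cal, _ = simulate_dye_calibration(dye, ch, config.volume,
                                              config.box_factor, seed,
                                              config.settings)
            out[ch] = cal
        return out
    if config.geometry:
        cal = from_geometry(float(config.geometry["omega_xy"]),
                            float(config.geometry["kappa"]))
    else:
        cal = from_geometry(config.volume.omega_xy, config.volume.kappa)
    return {"G": cal, "R": cal}


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Simulate and analyze all conditions of a run configuration.

    Returns a bundle with the per-cell results table, condition summaries,
    pairwise comparisons for D and c, the calibrations used, and an audit
    list of per-cell artifacts.  Deterministic for a fixed seed.
    """
    if not config.conditions:
        raise ValueError("run configuration has no conditions")
    calibs = _calibrations(config)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    all_measurements: list[CellMeasurement] = []
    audit = []
    for ci, cond in enumerate(config.conditions):
        n_cells = cond.n_cells or config.n_cells
        background = config.background.get(
            cond.compartment, BackgroundEstimate(0.0, 0.0, cond.compartment))
        bg_G = background.B_G
        bg_R = background.B_R
        for cell in range(n_cells):
            seed = _cell_seed(config.seed, ci, cell)
            sim = SimulationConfig(
                volume=config.volume, species=tuple(cond.species),
                background_G=bg_G, background_R=bg_R,
                duration=config.duration, base_bin=config.base_bin,
                time_step=config.time_step, box_factor=config.box_factor,
                seed=seed)
            cell_id = f"{cond.name}_{cond.compartment}_{cell:03d}"
            trace = simulate_trace(sim, metadata={
                "condition": cond.name, "compartment": cond.compartment,
                "cell_id": cell_id})
            try:
                result = run_cell(trace, calibs["G"], calibs["R"], background,
                                  config.settings, cell_id=cell_id,
                                  condition=cond.name,
                                  compartment=cond.compartment)
            except ValueError as exc:
                warnings.warn(f"cell {cell_id} failed: {exc}")
                audit.append({"cell_id": cell_id, "error": str(exc)})
                continue
            all_measurements.extend(result.measurements)
            audit.append({"cell_id": cell_id, "seed": seed,
                          "flags": [m.qc_flags for m in result.measurements]})
            if out_dir is not None:
                fio.write_trace(out_dir / f"trace_{cell_id}.tsv", trace)
                for pair, curve in result.curves.items():
                    fio.write_curve(out_dir / f"curve_{cell_id}_{pair}.tsv", curve)

    results = _measurement_frame(all_measurements)
    clean = [m for m in all_measurements if m.qc_pass]
    summary = summarize(clean) if clean else pd.DataFrame()
    comparisons = []
    if clean and len({m.condition for m in clean}) > 1:
        for value in ("D", "c"):
            comparisons.append(compare_groups(clean, value=value))
    comparisons = pd.concat(comparisons, ignore_index=True) if comparisons \
        else pd.DataFrame()

    if out_dir is not None:
        results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        if not summary.empty:
            summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        if not comparisons.empty:
            comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
        fio.write_calibrations(out_dir / "calibration.yaml", calibs)
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump({"config_hash": config.config_hash(), "audit": audit},
                      fh, indent=1, default=str)

    return {"results": results, "summary": summary, "comparisons": comparisons,
            "calibrations": calibs, "audit": audit}


def _measurement_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        d = dict(vars(m))
        d["qc_flags"] = ";".join(m.qc_flags)
        rows.append(d)
    return pd.DataFrame(rows)
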