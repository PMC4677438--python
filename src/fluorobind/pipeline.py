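"""End-to-end study orchestration.

Runs the whole analysis chain on a set of titration series — read (or
simulate) → average replicates → extract intensities → Stern-Volmer fits →
mechanism call → double-log binding fits → Van't Hoff → Gibbs → force call
→ dual-excitation residue attribution — and assembles a
:class:`StudyReport` that mirrors the three standard result tables of a
quenching study (Stern-Volmer constants, thermodynamic parameters, binding
constants) plus the qualitative calls.

The study configuration is a plain mapping (typically loaded from YAML)
with either a ``simulate`` block (forwarded to
:class:`~fluorobind.simulate.SimulationConfig`) or an ``inputs`` list of
titration files, and an optional ``analysis`` block of thresholds and
method choices.  Any stage failure raises :class:`StageError` carrying the
stage name; no partial report is produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .binding import DoubleLogFit, double_log_fit
from .quenching import (
    MechanismCall,
    ResidueAttribution,
    SternVolmerFit,
    classify_mechanism,
    compare_excitations,
    stern_volmer_fit,
)
from .simulate import SimulationConfig, simulate_study
from .spectra_io import (
    ColumnSchema,
    IntensityTable,
    TitrationSeries,
    _conc_factor,
    average_replicates,
    extract_intensities,
    read_titration,
)
from .thermodynamics import (
    ForceCall,
    GibbsResult,
    VantHoffFit,
    classify_forces,
    gibbs_free_energy,
    vant_hoff_fit,
)

__all__ = ["StageError", "StudyReport", "run_study", "write_report"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class StudyReport:
    """Assembled results of a full quenching/binding/thermodynamics study."""

    stern_volmer: list[SternVolmerFit]
    mechanism: MechanismCall | None
    binding: list[DoubleLogFit]
    thermo: VantHoffFit
    gibbs: list[GibbsResult]
    force: ForceCall
    residue: ResidueAttribution | None
    warnings: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)


_ANALYSIS_DEFAULTS = {
    "extraction": "peak-max",
    "window": (320.0, 460.0),
    "fixed_wavelength": None,
    "reference_excitation": 280.0,
    "mechanism_threshold": 0.05,
    "residue_threshold": 0.05,
    "epsilon_enthalpy": 1000.0,
    "conc_unit": "uM",
    "k_source": "stern_volmer",
}


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_series(
    config: Mapping[str, Any], seed: int | None
) -> tuple[dict[tuple[float, float], TitrationSeries], dict[str, Any]]:
    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        for key in ("concentrations", "temperatures", "excitation_wavelengths"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        if "excitation_quench_factors" in sim_kwargs:
            sim_kwargs["excitation_quench_factors"] = {
                float(k): float(v)
                for k, v in sim_kwargs["excitation_quench_factors"].items()
            }
        sim = SimulationConfig(**sim_kwargs)
        return simulate_study(sim), {
            "inputs": "simulated",
            "seed": sim.seed,
            "model": sim.model,
        }
    if "inputs" in config:
        series_map = {}
        paths = []
        for entry in config["inputs"]:
            schema_kwargs = dict(entry.get("schema", {}))
            series = read_titration(entry["path"], ColumnSchema(**schema_kwargs))
            series_map[(series.temperature, series.excitation_wavelength)] = series
            paths.append(str(entry["path"]))
        return series_map, {"inputs": paths, "seed": seed}
    raise ValueError("config needs a 'simulate' block or an 'inputs' list")


def run_study(config: Mapping[str, Any], seed: int | None = None) -> StudyReport:
    """Execute the full analysis chain described by ``config``.

    Raises :class:`StageError` (naming the failing stage) on any error;
    deterministic for a fixed config and seed.
    """
    opts = {**_ANALYSIS_DEFAULTS, **dict(config.get("analysis", {}))}
    warnings: list[str] = []

    try:
        series_map, origin = _load_series(config, seed)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("load", str(exc)) from exc

    try:
        tables: dict[tuple[float, float], IntensityTable] = {}
        for key, series in series_map.items():
            avg = average_replicates(series)
            tables[key] = extract_intensities(
                avg,
                method=opts["extraction"],
                window=tuple(opts["window"]),
                fixed_wavelength=opts["fixed_wavelength"],
            )
    except Exception as exc:
        raise StageError("extract", str(exc)) from exc

    try:
        sv_fits = {key: stern_volmer_fit(tab) for key, tab in tables.items()}
        for key, f in sv_fits.items():
            if abs(f.intercept - 1.0) > 0.1:
                warnings.append(
                    f"Stern-Volmer intercept {f.intercept:.4f} at "
                    f"T={key[0]} K, ex={key[1]} nm deviates from 1"
                )
    except Exception as exc:
        raise StageError("stern_volmer", str(exc)) from exc

    ref_exc = float(opts["reference_excitation"])
    ref_fits = sorted(
        (f for (t, e), f in sv_fits.items() if e == ref_exc),
        key=lambda f: f.temperature,
    )
    if not ref_fits:  # fall back to whatever excitation is present
        ref_exc = sorted({e for _, e in sv_fits})[0]
        ref_fits = sorted(
            (f for (t, e), f in sv_fits.items() if e == ref_exc),
            key=lambda f: f.temperature,
        )

    mechanism: MechanismCall | None = None
    if len(ref_fits) >= 2:
        try:
            mechanism = classify_mechanism(
                ref_fits, threshold=float(opts["mechanism_threshold"])
            )
        except Exception as exc:
            raise StageError("mechanism", str(exc)) from exc
    else:
        warnings.append(
            "mechanism call skipped: fewer than 2 temperatures at the "
            "reference excitation"
        )

    try:
        binding_fits = []
        for f in ref_fits:
            tab = tables[(f.temperature, ref_exc)]
            n_flat = int(np.count_nonzero(tab.f_values >= tab.f0))
            if n_flat:
                warnings.append(
                    f"{n_flat} unquenched point(s) dropped from the double-log "
                    f"fit at T={f.temperature} K"
                )
            binding_fits.append(double_log_fit(tab, conc_unit=opts["conc_unit"]))
    except Exception as exc:
        raise StageError("binding", str(exc)) from exc

    try:
        if opts["k_source"] == "stern_volmer":
            pairs = [(f.temperature, f.ksv) for f in ref_fits]
        elif opts["k_source"] == "double_log":
            # convert Ka from (conc_unit)^-n to an L mol^-1 scale
            pairs = [
                (b.temperature, b.ka / _conc_factor(b.conc_unit) ** b.n)
                for b in binding_fits
            ]
        else:
            raise ValueError(f"unknown k_source {opts['k_source']!r}")
        if len(pairs) < 2:
            raise ValueError(
                "Van't Hoff analysis needs Stern-Volmer constants at >= 2 "
                "temperatures; configure a second temperature"
            )
        thermo = vant_hoff_fit(pairs, k_source=opts["k_source"])
        gibbs = [
            gibbs_free_energy(thermo.delta_h, thermo.delta_s, t) for t, _ in pairs
        ]
        force = classify_forces(
            thermo.delta_h, thermo.delta_s, epsilon=float(opts["epsilon_enthalpy"])
        )
    except Exception as exc:
        raise StageError("thermodynamics", str(exc)) from exc

    residue: ResidueAttribution | None = None
    temps = sorted({t for t, _ in tables})
    excs = sorted({e for _, e in tables})
    if 280.0 in excs and 293.0 in excs:
        try:
            t0 = temps[0]
            residue = compare_excitations(
                tables[(t0, 280.0)],
                tables[(t0, 293.0)],
                threshold=float(opts["residue_threshold"]),
            )
        except Exception as exc:
            raise StageError("residue", str(exc)) from exc
    else:
        warnings.append(
            "residue attribution skipped: needs both 280 and 293 nm series"
        )

    provenance = {
        **origin,
        "config_hash": _config_hash(config),
        "software_version": __version__,
        "reference_excitation": ref_exc,
        "series": [
            {"temperature_K": t, "excitation_nm": e} for t, e in sorted(tables)
        ],
    }
    return StudyReport(
        stern_volmer=sorted(
            sv_fits.values(), key=lambda f: (f.temperature, f.excitation_wavelength)
        ),
        mechanism=mechanism,
        binding=binding_fits,
        thermo=thermo,
        gibbs=gibbs,
        force=force,
        residue=residue,
        warnings=warnings,
        provenance=provenance,
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        obj = obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None  # JSON has no NaN; undefined-flagged values become null
    return obj


def write_report(report: StudyReport, output_dir: str | Path) -> dict[str, Path]:
    """Write report.json plus the three presentation CSV tables.

    The JSON carries full precision; the CSVs round to the precision these
    quantities are conventionally printed at (Ksv 3 s.f.; ΔH, ΔS 3
    decimals; Ka 4 decimals; n 3 decimals).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(_jsonable(report), indent=2) + "\n")

    t1 = pd.DataFrame(
        {
            "temperature_K": [f.temperature for f in report.stern_volmer],
            "excitation_nm": [f.excitation_wavelength for f in report.stern_volmer],
            "Ksv_L_per_mol": [float(f"{f.ksv:.3g}") for f in report.stern_volmer],
            "intercept": [round(f.intercept, 4) for f in report.stern_volmer],
            "r_squared": [round(f.r_squared, 5) for f in report.stern_volmer],
            "slope_stderr": [float(f"{f.slope_stderr:.3g}") for f in report.stern_volmer],
        }
    )
    paths["table1"] = out / "table1_sternvolmer.csv"
    t1.to_csv(paths["table1"], index=False)

    gibbs_by_t = {g.temperature: g for g in report.gibbs}
    t2 = pd.DataFrame(
        {
            "temperature_K": sorted(gibbs_by_t),
            "delta_H_kJ_per_mol": [
                round(report.thermo.delta_h / 1e3, 3) for _ in gibbs_by_t
            ],
            "delta_S_J_per_mol_K": [
                round(report.thermo.delta_s, 3) for _ in gibbs_by_t
            ],
            "delta_G_kJ_per_mol": [
                round(gibbs_by_t[t].delta_g / 1e3, 2) for t in sorted(gibbs_by_t)
            ],
            "force_call": [report.force.call for _ in gibbs_by_t],
        }
    )
    paths["table2"] = out / "table2_thermo.csv"
    t2.to_csv(paths["table2"], index=False)

    t3 = pd.DataFrame(
        {
            "temperature_K": [b.temperature for b in report.binding],
            "Ka": [round(b.ka, 4) for b in report.binding],
            "Ka_unit": [f"{b.conc_unit}^-n" for b in report.binding],
            "n": [round(b.n, 3) for b in report.binding],
            "r_squared": [round(b.r_squared, 5) for b in report.binding],
        }
    )
    paths["table3"] = out / "table3_binding.csv"
    t3.to_csv(paths["table3"], index=False)
    return paths
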