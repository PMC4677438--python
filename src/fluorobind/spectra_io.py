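"""Data model and file I/O for fluorescence emission titration spectra.

A titration experiment records the intrinsic emission of a protein (here a
serum albumin at fixed concentration) while a quencher ligand is added in
increasing amounts.  Each scan is an :class:`EmissionSpectrum`; the ordered
set of scans sharing one excitation wavelength and one temperature is a
:class:`TitrationSeries`.  Downstream fitting consumes an
:class:`IntensityTable` — one representative intensity ``F`` per quencher
concentration plus the zero-quencher reference ``F0``.

Internal units are mol L⁻¹ (concentration), K (temperature) and nm
(wavelength); any unit conversion happens only when reading or writing
files.  Files are long-format delimited text with one row per
(concentration, replicate, emission wavelength) sample; column names and
the concentration unit are configurable through :class:`ColumnSchema`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "IntensityTable",
    "ColumnSchema",
    "read_titration",
    "write_titration",
    "average_replicates",
    "extract_intensities",
]

logger = logging.getLogger(__name__)

#: multiplicative factors to convert a concentration *to* mol L⁻¹
_CONC_FACTORS = {
    "M": 1.0,
    "mol/L": 1.0,
    "mol/l": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "μM": 1e-6,  # μM
    "nM": 1e-9,
}


def _conc_factor(unit: str) -> float:
    try:
        return _CONC_FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(set(_CONC_FACTORS))}"
        ) from None


@dataclass(eq=False)
class EmissionSpectrum:
    """One emission scan at fixed excitation wavelength, temperature and
    quencher concentration.

    Parameters
    ----------
    excitation_wavelength : float
        Excitation wavelength in nm.
    temperature : float
        Thermodynamic temperature in K (> 0).
    quencher_concentration : float
        Total added quencher concentration in mol L⁻¹ (>= 0).
    replicate_id : int
        Identifier distinguishing repeat scans of the same condition.
    wavelengths : array-like
        Strictly increasing emission wavelengths in nm.
    intensities : array-like
        Fluorescence intensities (arbitrary units, finite, >= 0), one per
        wavelength.
    """

    excitation_wavelength: float
    temperature: float
    quencher_concentration: float
    replicate_id: int
    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D array")
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.quencher_concentration < 0:
            raise ValueError("quencher_concentration must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmissionSpectrum):
            return NotImplemented
        return (
            self.excitation_wavelength == other.excitation_wavelength
            and self.temperature == other.temperature
            and self.quencher_concentration == other.quencher_concentration
            and self.replicate_id == other.replicate_id
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(eq=False)
class TitrationSeries:
    """Ordered set of emission spectra over a quencher-concentration series.

    All member spectra share the excitation wavelength, the temperature and
    an identical emission-wavelength grid.  The series must contain the
    zero-quencher reference scan and at least two distinct nonzero
    concentrations to be fittable.
    """

    protein_concentration: float
    excitation_wavelength: float
    temperature: float
    spectra: list[EmissionSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("TitrationSeries requires at least one spectrum")
        grid = self.spectra[0].wavelengths
        for sp in self.spectra:
            if sp.excitation_wavelength != self.excitation_wavelength:
                raise ValueError("spectrum excitation wavelength differs from series")
            if sp.temperature != self.temperature:
                raise ValueError("spectrum temperature differs from series")
            if not np.array_equal(sp.wavelengths, grid):
                raise ValueError("all spectra must share one wavelength grid")
        concs = self.concentrations
        if 0.0 not in concs:
            raise ValueError("series lacks the zero-quencher reference spectrum")
        if np.count_nonzero(concs) < 2:
            raise ValueError("series needs >= 2 distinct nonzero concentrations")

    @property
    def concentrations(self) -> np.ndarray:
        """Sorted unique quencher concentrations (mol L⁻¹)."""
        return np.unique([sp.quencher_concentration for sp in self.spectra])

    @property
    def wavelength_grid(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def spectra_at(self, concentration: float) -> list[EmissionSpectrum]:
        """All replicate spectra recorded at one quencher concentration."""
        return [
            sp for sp in self.spectra if sp.quencher_concentration == concentration
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TitrationSeries):
            return NotImplemented
        return (
            self.protein_concentration == other.protein_concentration
            and self.excitation_wavelength == other.excitation_wavelength
            and self.temperature == other.temperature
            and self.spectra == other.spectra
        )


@dataclass(eq=False)
class IntensityTable:
    """Per-concentration fluorescence intensities with the F0 reference.

    ``concentrations`` holds the strictly increasing *nonzero* quencher
    concentrations (mol L⁻¹); ``f_values`` the matching intensities F;
    ``f0`` the intensity of the unquenched protein.
    """

    concentrations: np.ndarray
    f_values: np.ndarray
    f0: float
    extraction_method: str
    temperature: float
    excitation_wavelength: float

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.f_values = np.asarray(self.f_values, dtype=float)
        if self.concentrations.shape != self.f_values.shape:
            raise ValueError("concentrations and f_values differ in length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be nonzero and positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")
        if np.any(self.f_values <= 0):
            raise ValueError("all f_values must be positive")

    def quench_ratio(self) -> np.ndarray:
        """F0/F at each nonzero concentration (the Stern-Volmer ordinate)."""
        return self.f0 / self.f_values

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTable):
            return NotImplemented
        return (
            np.array_equal(self.concentrations, other.concentrations)
            and np.array_equal(self.f_values, other.f_values)
            and self.f0 == other.f0
            and self.extraction_method == other.extraction_method
            and self.temperature == other.temperature
            and self.excitation_wavelength == other.excitation_wavelength
        )


@dataclass
class ColumnSchema:
    """Column-name mapping and unit declarations for titration files.

    The defaults match the files this package writes.  ``conc_unit`` is used
    when the file has no per-row unit column; ``protein_concentration`` (mol
    L⁻¹) is used when the file has no protein-concentration column.
    """

    excitation: str = "excitation_nm"
    temperature: str = "temperature_K"
    quencher_conc: str = "quencher_conc"
    conc_unit_col: str = "conc_unit"
    replicate: str = "replicate"
    emission: str = "emission_nm"
    intensity: str = "intensity"
    protein_conc_col: str = "protein_conc"
    conc_unit: str = "M"
    protein_concentration: float = 20e-6
    delimiter: str = ","


def read_titration(path: str | Path, schema: ColumnSchema | None = None) -> TitrationSeries:
    """Read a long-format delimited titration file into a TitrationSeries.

    Raises
    ------
    KeyError
        If a required column is missing.
    ValueError
        If wavelength grids are non-monotone or the series fails validation
        (e.g. no zero-quencher scan).
    """
    schema = schema or ColumnSchema()
    path = Path(path)
    # round_trip parsing so write/read preserves float64 values exactly
    df = pd.read_csv(path, sep=schema.delimiter, float_precision="round_trip")

    required = [
        schema.excitation,
        schema.temperature,
        schema.quencher_conc,
        schema.replicate,
        schema.emission,
        schema.intensity,
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"missing required column(s) {missing} in {path}")

    if schema.conc_unit_col in df.columns:
        factors = df[schema.conc_unit_col].map(_conc_factor)
    else:
        factors = _conc_factor(schema.conc_unit)
    conc_molar = df[schema.quencher_conc].astype(float) * factors

    if schema.protein_conc_col in df.columns:
        protein = float(df[schema.protein_conc_col].iloc[0]) * (
            factors.iloc[0] if hasattr(factors, "iloc") else factors
        )
    else:
        protein = schema.protein_concentration

    df = df.assign(_conc=conc_molar)
    spectra: list[EmissionSpectrum] = []
    for (conc, rep), grp in df.groupby(["_conc", schema.replicate], sort=True):
        grp = grp.sort_values(schema.emission)
        spectra.append(
            EmissionSpectrum(
                excitation_wavelength=float(grp[schema.excitation].iloc[0]),
                temperature=float(grp[schema.temperature].iloc[0]),
                quencher_concentration=float(conc),
                replicate_id=int(rep),
                wavelengths=grp[schema.emission].to_numpy(float),
                intensities=grp[schema.intensity].to_numpy(float),
            )
        )
    return TitrationSeries(
        protein_concentration=protein,
        excitation_wavelength=spectra[0].excitation_wavelength,
        temperature=spectra[0].temperature,
        spectra=spectra,
    )


def write_titration(
    series: TitrationSeries, path: str | Path, schema: ColumnSchema | None = None
) -> Path:
    """Write a TitrationSeries as a long-format delimited file.

    Concentrations are written in mol L⁻¹ with full float precision so that
    ``read_titration(write_titration(s)) == s`` exactly.
    """
    schema = schema or ColumnSchema()
    path = Path(path)
    frames = []
    for sp in series.spectra:
        frames.append(
            pd.DataFrame(
                {
                    schema.excitation: sp.excitation_wavelength,
                    schema.temperature: sp.temperature,
                    schema.quencher_conc: sp.quencher_concentration,
                    schema.conc_unit_col: "M",
                    schema.replicate: sp.replicate_id,
                    schema.emission: sp.wavelengths,
                    schema.intensity: sp.intensities,
                    schema.protein_conc_col: series.protein_concentration,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep=schema.delimiter, index=False, float_format="%.17g")
    return path


def average_replicates(series: TitrationSeries) -> TitrationSeries:
    """Average replicate spectra pointwise, one spectrum per concentration.

    The triplicate scans recorded per condition are reduced to their
    arithmetic mean before any fitting.  Idempotent: averaging an already
    averaged series returns an equal series.
    """
    averaged: list[EmissionSpectrum] = []
    for conc in series.concentrations:
        reps = series.spectra_at(conc)
        grid = reps[0].wavelengths
        for sp in reps[1:]:
            if not np.array_equal(sp.wavelengths, grid):
                raise ValueError(
                    f"replicates at concentration {conc} have mismatched grids"
                )
        mean_int = np.mean([sp.intensities for sp in reps], axis=0)
        averaged.append(
            replace(reps[0], replicate_id=0, intensities=mean_int)
        )
    return TitrationSeries(
        protein_concentration=series.protein_concentration,
        excitation_wavelength=series.excitation_wavelength,
        temperature=series.temperature,
        spectra=averaged,
    )


def extract_intensities(
    series: TitrationSeries,
    method: str = "peak-max",
    window: Sequence[float] = (320.0, 460.0),
    fixed_wavelength: float | None = None,
) -> IntensityTable:
    """Reduce each averaged spectrum to one intensity F per concentration.

    Parameters
    ----------
    method : {"peak-max", "fixed-wavelength"}
        ``peak-max`` (default) takes the maximum intensity inside ``window``;
        ``fixed-wavelength`` reads the intensity at ``fixed_wavelength``.
        Both are near-equivalent here because quenching does not shift the
        emission maximum of the albumin band.
    window : (low, high)
        Emission window in nm for peak-max extraction.

    The series must already be replicate-averaged (one spectrum per
    concentration); F0 is taken from the zero-quencher spectrum by the same
    method.
    """
    for conc in series.concentrations:
        if len(series.spectra_at(conc)) != 1:
            raise ValueError(
                "series has unaveraged replicates; call average_replicates first"
            )

    grid = series.wavelength_grid
    lo, hi = float(window[0]), float(window[1])
    mask = (grid >= lo) & (grid <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no grid wavelengths")

    if method == "peak-max":
        def f_of(sp: EmissionSpectrum) -> float:
            return float(np.max(sp.intensities[mask]))
    elif method == "fixed-wavelength":
        if fixed_wavelength is None:
            raise ValueError("fixed-wavelength extraction needs fixed_wavelength")
        idx = np.nonzero(grid == float(fixed_wavelength))[0]
        if idx.size == 0:
            raise ValueError(
                f"fixed_wavelength {fixed_wavelength} nm is not on the grid"
            )
        i = int(idx[0])

        def f_of(sp: EmissionSpectrum) -> float:
            return float(sp.intensities[i])
    else:
        raise ValueError(f"unknown extraction method {method!r}")

    concs = series.concentrations
    f0 = f_of(series.spectra_at(0.0)[0])
    nonzero = concs[concs > 0]
    f_values = np.array([f_of(series.spectra_at(c)[0]) for c in nonzero])
    if f0 <= 0 or np.any(f_values <= 0):
        raise ValueError("extracted intensities must be positive")
    return IntensityTable(
        concentrations=nonzero,
        f_values=f_values,
        f0=f0,
        extraction_method=method,
        temperature=series.temperature,
        excitation_wavelength=series.excitation_wavelength,
    )
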