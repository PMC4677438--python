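"""Seeded simulation of fluorescence quenching titrations.

Emulates a spectrofluorometer titration of a serum albumin (default 20 μM)
with a quencher ligand at 0–320 μM, excitation at 280 and 293 nm, emission
scanned 320–460 nm, at 298 and 308 K, triplicate scans — with known
ground-truth parameters, so every analysis step can be validated by round
trip.

Forward models for the peak amplitude at quencher concentration [Q]:

* ``dynamic-sv``        F = F0 / (1 + Ksv·[Q])
* ``static-doublelog``  F = F0 / (1 + Ka·[Q]ⁿ)   ([Q] in the Ka unit)
* ``vant-hoff-family``  as dynamic-sv with K(T) = exp(−ΔH/RT + ΔS/R)

Each spectrum is a Gaussian band (center 348 nm, σ 25 nm by default —
typical of albumin tryptophan emission) scaled to the model amplitude, on a
1 nm grid.  The band position is independent of [Q], mirroring the absence
of an emission-maximum shift in real albumin quenching, and its shape is
irrelevant to all fitted constants (they are invariant under common
intensity rescaling).  Noise is multiplicative Gaussian per point per
replicate (detector shot noise scales with signal).  An excitation-specific
efficiency factor multiplies the quenching constant so that the 280 nm
(Trp+Tyr) series can quench differently from 293 nm (Trp only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .spectra_io import EmissionSpectrum, TitrationSeries, _conc_factor
from .thermodynamics import GAS_CONSTANT

__all__ = ["SimulationConfig", "simulate_titration", "simulate_study"]

_MODELS = ("dynamic-sv", "static-doublelog", "vant-hoff-family")

#: the experimental quencher series, mol L^-1 (0 to 320 μM)
DEFAULT_CONCENTRATIONS = tuple(
    c * 1e-6 for c in (0.0, 20.0, 40.0, 80.0, 120.0, 160.0, 240.0, 320.0)
)


@dataclass
class SimulationConfig:
    """Ground-truth parameters and experimental design for a simulated study.

    Defaults reproduce the reference experimental design: 20 μM albumin,
    quencher at 0/20/40/80/120/160/240/320 μM, 298 and 308 K, excitation at
    280 and 293 nm, triplicate scans, 2% multiplicative noise.
    """

    model: str = "dynamic-sv"
    true_ksv: float = 1.27e5  # L mol^-1 (dynamic-sv)
    true_ka: float = 0.1021  # (ka_conc_unit)^-n (static-doublelog)
    true_n: float = 1.036
    ka_conc_unit: str = "uM"
    delta_h: float = 14051.0  # J mol^-1 (vant-hoff-family)
    delta_s: float = 144.913  # J mol^-1 K^-1
    f0_amplitude: float = 1000.0  # a.u.
    band_center: float = 348.0  # nm
    band_width_sigma: float = 25.0  # nm
    emission_range: tuple[float, float, float] = (320.0, 460.0, 1.0)  # start, stop, step
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS  # mol L^-1
    temperatures: tuple[float, ...] = (298.0, 308.0)  # K
    excitation_wavelengths: tuple[float, ...] = (280.0, 293.0)  # nm
    excitation_quench_factors: Mapping[float, float] = field(
        default_factory=lambda: {280.0: 1.2, 293.0: 1.0}
    )
    protein_concentration: float = 20e-6  # mol L^-1
    noise_sigma: float = 0.02  # fractional multiplicative noise
    replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        concs = np.asarray(self.concentrations, float)
        if np.any(concs < 0) or 0.0 not in concs:
            raise ValueError("concentrations must be >= 0 and include 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.f0_amplitude <= 0:
            raise ValueError("f0_amplitude must be positive")

    def wavelength_grid(self) -> np.ndarray:
        start, stop, step = self.emission_range
        return np.arange(start, stop + step / 2, step)


def _quench_factor(config: SimulationConfig, excitation: float) -> float:
    return float(config.excitation_quench_factors.get(excitation, 1.0))


def vant_hoff_k(delta_h: float, delta_s: float, temperature: float) -> float:
    """Closed-form equilibrium constant K(T) = exp(−ΔH/RT + ΔS/R)."""
    return float(
        np.exp(-delta_h / (GAS_CONSTANT * temperature) + delta_s / GAS_CONSTANT)
    )


def _amplitudes(
    config: SimulationConfig, temperature: float, excitation: float
) -> np.ndarray:
    """Noise-free peak amplitude F for every configured concentration."""
    conc = np.asarray(config.concentrations, float)
    g = _quench_factor(config, excitation)
    if config.model == "dynamic-sv":
        denom = 1.0 + g * config.true_ksv * conc
    elif config.model == "vant-hoff-family":
        k = vant_hoff_k(config.delta_h, config.delta_s, temperature)
        denom = 1.0 + g * k * conc
    else:  # static-doublelog
        conc_u = conc / _conc_factor(config.ka_conc_unit)
        denom = 1.0 + g * config.true_ka * conc_u**config.true_n
    return config.f0_amplitude / denom


def simulate_titration(
    config: SimulationConfig,
    temperature: float | None = None,
    excitation: float | None = None,
    rng: np.random.Generator | None = None,
) -> TitrationSeries:
    """Simulate one titration series at a single temperature and excitation.

    Defaults to the first configured temperature and excitation wavelength.
    Deterministic given ``config.seed`` (or an explicitly supplied ``rng``).
    """
    config.validate()
    temperature = config.temperatures[0] if temperature is None else temperature
    excitation = (
        config.excitation_wavelengths[0] if excitation is None else excitation
    )
    rng = np.random.default_rng(config.seed) if rng is None else rng

    grid = config.wavelength_grid()
    band = np.exp(
        -((grid - config.band_center) ** 2) / (2.0 * config.band_width_sigma**2)
    )
    amplitudes = _amplitudes(config, temperature, excitation)

    spectra = []
    for conc, amp in zip(config.concentrations, amplitudes):
        clean = amp * band
        for rep in range(1, config.replicates + 1):
            if config.noise_sigma > 0:
                noisy = clean * (1.0 + config.noise_sigma * rng.standard_normal(grid.size))
                noisy = np.maximum(noisy, 0.0)
            else:
                noisy = clean
            spectra.append(
                EmissionSpectrum(
                    excitation_wavelength=float(excitation),
                    temperature=float(temperature),
                    quencher_concentration=float(conc),
                    replicate_id=rep,
                    wavelengths=grid,
                    intensities=noisy,
                )
            )
    return TitrationSeries(
        protein_concentration=config.protein_concentration,
        excitation_wavelength=float(excitation),
        temperature=float(temperature),
        spectra=spectra,
    )


def simulate_study(
    config: SimulationConfig,
) -> dict[tuple[float, float], TitrationSeries]:
    """Simulate the full study grid: one series per (temperature, excitation).

    For the ``vant-hoff-family`` model the quenching constant at each
    temperature follows the closed-form Van't Hoff line, so the full
    analysis chain can recover the generating ΔH and ΔS.  Each series gets
    an independent noise stream spawned from the master seed.
    """
    config.validate()
    if not config.excitation_wavelengths:
        raise ValueError("study needs >= 1 excitation wavelength")
    if config.model == "vant-hoff-family" and len(set(config.temperatures)) < 2:
        raise ValueError("vant-hoff-family study needs >= 2 distinct temperatures")

    combos = [
        (t, exc)
        for t in config.temperatures
        for exc in config.excitation_wavelengths
    ]
    children = np.random.SeedSequence(config.seed).spawn(len(combos))
    out: dict[tuple[float, float], TitrationSeries] = {}
    for (t, exc), child in zip(combos, children):
        out[(t, exc)] = simulate_titration(
            config, temperature=t, excitation=exc, rng=np.random.default_rng(child)
        )
    return out
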