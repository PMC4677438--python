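"""Stern-Volmer quenching analysis.

Fluorescence quenching of a protein by a ligand follows, in the simplest
collisional or 1:1 static picture, the Stern-Volmer relation

    F0/F = 1 + Ksv * [Q]

where F0 and F are the intensities without and with quencher, [Q] is the
total quencher concentration (mol L⁻¹) and Ksv (L mol⁻¹) measures quenching
strength.  The temperature dependence of Ksv distinguishes mechanisms:
collisional (dynamic) quenching is diffusion-limited, so Ksv rises with
temperature; ground-state complexation (static quenching) destabilises on
heating, so Ksv falls.

Comparing quenching curves at 280 nm excitation (tryptophan + tyrosine
emission) against 293 nm (tryptophan only) attributes the interaction to
specific residue classes: curves that clearly differ imply tyrosine
participates alongside tryptophan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .spectra_io import IntensityTable

__all__ = [
    "SternVolmerFit",
    "MechanismCall",
    "ResidueAttribution",
    "SternVolmerRegressor",
    "stern_volmer_fit",
    "classify_mechanism",
    "compare_excitations",
]

logger = logging.getLogger(__name__)


def _linefit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line y = a + b*x -> (slope, intercept, r², slope stderr).

    r² is NaN-flagged when the ordinate is constant (undefined correlation).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(y) == 0.0:
        # flat response: slope 0 exactly, correlation undefined
        return 0.0, float(y[0]), float("nan"), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.stderr)


@dataclass(frozen=True)
class SternVolmerFit:
    """Result of an ordinary least-squares Stern-Volmer regression."""

    ksv: float  # L mol^-1
    intercept: float
    r_squared: float  # NaN when F is unquenched (constant F0/F)
    slope_stderr: float  # L mol^-1
    n_points: int
    temperature: float  # K
    excitation_wavelength: float  # nm


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism classification from Ksv(T).

    ``relative_change`` is (Ksv_high − Ksv_low)/Ksv_low between the extreme
    temperatures; calls are ``dynamic`` above +threshold, ``static`` below
    −threshold, ``ambiguous`` in between.
    """

    call: str
    relative_change: float
    threshold: float
    evidence: tuple[tuple[float, float], ...]  # ordered (temperature, ksv)


@dataclass(frozen=True)
class ResidueAttribution:
    """Residue-class attribution from dual-excitation quenching curves."""

    statistic: float  # max |F/F0(280) - F/F0(293)| over matched concentrations
    threshold: float
    call: str  # "both-Trp-and-Tyr" | "Trp-dominant"


class SternVolmerRegressor(BaseEstimator, RegressorMixin):
    """Linear Stern-Volmer model fitted by ordinary least squares.

    Regresses F0/F on quencher concentration.  The intercept is estimated,
    not constrained to the theoretical value of 1, so that poorly behaved
    data reveal themselves; a fitted intercept further than
    ``intercept_warn_tol`` from 1 emits a log warning.

    Attributes
    ----------
    ksv_ : float
        Slope, the Stern-Volmer constant in L mol⁻¹.
    intercept_ : float
    r_squared_ : float
        Coefficient of determination (NaN for a constant ordinate).
    slope_stderr_ : float
    n_points_ : int
    """

    def __init__(self, intercept_warn_tol: float = 0.1):
        self.intercept_warn_tol = intercept_warn_tol

    def fit(self, X, y):
        """Fit to concentrations ``X`` (n, 1) in mol L⁻¹ and ratios ``y`` = F0/F."""
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("X must be a single concentration column")
        if np.any(y <= 0):
            raise ValueError("F0/F ratios must be positive")
        slope, intercept, r2, stderr = _linefit(X[:, 0], y)
        self.ksv_ = slope
        self.intercept_ = intercept
        self.r_squared_ = r2
        self.slope_stderr_ = stderr
        self.n_points_ = int(y.size)
        if abs(self.intercept_ - 1.0) > self.intercept_warn_tol:
            logger.warning(
                "Stern-Volmer intercept %.4f deviates from 1 by more than %.2f",
                self.intercept_,
                self.intercept_warn_tol,
            )
        return self

    def predict(self, X):
        """Predicted F0/F at concentrations ``X`` (mol L⁻¹)."""
        check_is_fitted(self, "ksv_")
        X = check_array(X)
        return self.intercept_ + self.ksv_ * X[:, 0]


def stern_volmer_fit(table: IntensityTable) -> SternVolmerFit:
    """Fit the Stern-Volmer line to an intensity table.

    Requires at least three nonzero concentrations for a reportable fit.
    """
    if table.concentrations.size < 3:
        raise ValueError(
            f"Stern-Volmer fit needs >= 3 nonzero concentrations, "
            f"got {table.concentrations.size}"
        )
    reg = SternVolmerRegressor().fit(
        table.concentrations[:, None], table.quench_ratio()
    )
    return SternVolmerFit(
        ksv=reg.ksv_,
        intercept=reg.intercept_,
        r_squared=reg.r_squared_,
        slope_stderr=reg.slope_stderr_,
        n_points=reg.n_points_,
        temperature=table.temperature,
        excitation_wavelength=table.excitation_wavelength,
    )


def classify_mechanism(
    fits: Sequence[SternVolmerFit], threshold: float = 0.05
) -> MechanismCall:
    """Classify quenching as dynamic or static from Ksv at >= 2 temperatures.

    Ksv increasing with temperature (relative change above ``threshold``)
    indicates collisional quenching; decreasing indicates static complex
    formation; changes within the threshold are called ambiguous.
    """
    if len(fits) < 2:
        raise ValueError("mechanism classification needs fits at >= 2 temperatures")
    temps = [f.temperature for f in fits]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in Stern-Volmer fits")
    if len({f.excitation_wavelength for f in fits}) != 1:
        raise ValueError("fits must share one excitation wavelength")
    ordered = sorted(fits, key=lambda f: f.temperature)
    low, high = ordered[0], ordered[-1]
    relative_change = (high.ksv - low.ksv) / low.ksv
    if relative_change > threshold:
        call = "dynamic"
    elif relative_change < -threshold:
        call = "static"
    else:
        call = "ambiguous"
    return MechanismCall(
        call=call,
        relative_change=relative_change,
        threshold=threshold,
        evidence=tuple((f.temperature, f.ksv) for f in ordered),
    )


def compare_excitations(
    series280: IntensityTable,
    series293: IntensityTable,
    threshold: float = 0.05,
) -> ResidueAttribution:
    """Attribute quenching to residue classes from 280 vs 293 nm curves.

    Computes F/F0 at each matched concentration for both excitations and
    takes the maximum absolute pointwise difference as the test statistic.
    A difference above ``threshold`` means tyrosine contributes on top of
    tryptophan (the 293 nm curve sees tryptophan only); otherwise the
    quenching is tryptophan-dominant.
    """
    if series280.concentrations.shape != series293.concentrations.shape or not np.allclose(
        series280.concentrations, series293.concentrations
    ):
        raise ValueError("intensity tables have mismatched concentration grids")
    if series280.temperature != series293.temperature:
        raise ValueError("intensity tables were recorded at different temperatures")
    curve280 = series280.f_values / series280.f0
    curve293 = series293.f_values / series293.f0
    statistic = float(np.max(np.abs(curve280 - curve293)))
    call = "both-Trp-and-Tyr" if statistic > threshold else "Trp-dominant"
    return ResidueAttribution(statistic=statistic, threshold=threshold, call=call)
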