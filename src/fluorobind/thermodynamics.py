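"""Van't Hoff thermodynamics and binding-force classification.

The temperature dependence of an equilibrium constant K follows the Van't
Hoff relation ln K = −ΔH/(R T) + ΔS/R, so regressing ln K on 1/T yields the
enthalpy change ΔH from the slope and the entropy change ΔS from the
intercept.  The Gibbs free energy at any temperature is ΔG = ΔH − T·ΔS;
negative ΔG marks spontaneous binding.

The sign pattern of (ΔH, ΔS) classifies the dominant binding force after
Ross and Subramanian: both positive → hydrophobic; both negative →
hydrogen bonding and van der Waals; ΔH ≈ 0 with ΔS > 0 → electrostatic.

Following common practice in quenching studies, the K fed to the Van't
Hoff fit may be the Stern-Volmer constant (treated as analogous to an
association constant) or the double-log binding constant converted to
L mol⁻¹.  Using a dynamic-quenching constant as an equilibrium constant is
thermodynamically loose; the source is therefore recorded on the result
rather than silently hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .quenching import _linefit

__all__ = [
    "GAS_CONSTANT",
    "VantHoffFit",
    "GibbsResult",
    "ForceCall",
    "VantHoffRegressor",
    "vant_hoff_fit",
    "gibbs_free_energy",
    "classify_forces",
    "check_gibbs_consistency",
]

#: universal gas constant, J mol⁻¹ K⁻¹
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class VantHoffFit:
    """Enthalpy and entropy change from a Van't Hoff regression."""

    delta_h: float  # J mol^-1
    delta_s: float  # J mol^-1 K^-1
    r_squared: float  # NaN for exactly 2 temperatures (line is exact)
    n_temperatures: int
    k_source: str  # "stern_volmer" | "double_log"


@dataclass(frozen=True)
class GibbsResult:
    temperature: float  # K
    delta_g: float  # J mol^-1


@dataclass(frozen=True)
class ForceCall:
    """Dominant-force classification from the (ΔH, ΔS) sign pattern."""

    call: str
    epsilon: float  # near-zero enthalpy tolerance, J mol^-1
    rule_trace: str


class VantHoffRegressor(BaseEstimator, RegressorMixin):
    """Van't Hoff model ln K = −ΔH/(R T) + ΔS/R fitted by least squares.

    ``fit`` takes temperatures ``X`` (n, 1) in K and equilibrium constants
    ``y`` (L mol⁻¹, > 0).  Attributes: ``delta_h_`` (J mol⁻¹), ``delta_s_``
    (J mol⁻¹ K⁻¹), ``r_squared_`` (NaN when only two temperatures are
    supplied — a line through two points has no residual), ``n_points_``.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("X must be a single temperature column")
        temps = X[:, 0]
        if np.any(temps <= 0):
            raise ValueError("temperatures must be positive kelvin")
        if np.unique(temps).size < 2:
            raise ValueError("Van't Hoff fit needs >= 2 distinct temperatures")
        if np.any(y <= 0):
            raise ValueError("equilibrium constants must be positive")
        slope, intercept, r2, _ = _linefit(1.0 / temps, np.log(y))
        self.delta_h_ = -slope * GAS_CONSTANT
        self.delta_s_ = intercept * GAS_CONSTANT
        self.r_squared_ = float("nan") if y.size == 2 else r2
        self.n_points_ = int(y.size)
        return self

    def predict(self, X):
        """Predicted equilibrium constant at temperatures ``X`` (K)."""
        check_is_fitted(self, "delta_h_")
        X = check_array(X)
        t = X[:, 0]
        return np.exp(-self.delta_h_ / (GAS_CONSTANT * t) + self.delta_s_ / GAS_CONSTANT)


def vant_hoff_fit(
    k_by_temperature: Sequence[tuple[float, float]],
    k_source: str = "stern_volmer",
) -> VantHoffFit:
    """Estimate ΔH and ΔS from (temperature K, equilibrium constant) pairs.

    For exactly two temperatures the least-squares line coincides with the
    closed-form two-point solution.
    """
    pairs = list(k_by_temperature)
    if len(pairs) < 2:
        raise ValueError("Van't Hoff fit needs >= 2 temperatures")
    temps = np.array([t for t, _ in pairs], float)
    ks = np.array([k for _, k in pairs], float)
    reg = VantHoffRegressor().fit(temps[:, None], ks)
    return VantHoffFit(
        delta_h=reg.delta_h_,
        delta_s=reg.delta_s_,
        r_squared=reg.r_squared_,
        n_temperatures=len(pairs),
        k_source=k_source,
    )


def gibbs_free_energy(delta_h: float, delta_s: float, temperature: float) -> GibbsResult:
    """ΔG = ΔH − T·ΔS (J mol⁻¹) at one temperature."""
    if not temperature > 0:
        raise ValueError("temperature must be positive kelvin")
    return GibbsResult(temperature=temperature, delta_g=delta_h - temperature * delta_s)


def check_gibbs_consistency(
    delta_h: float,
    delta_s: float,
    temperature: float,
    reported_delta_g: float,
    rtol: float = 0.01,
) -> bool:
    """Whether a reported ΔG agrees with ΔH − T·ΔS within relative tolerance.

    Published tables occasionally carry a ΔG that does not follow from the
    tabulated ΔH and ΔS; this check lets the pipeline flag such rows.
    """
    expected = delta_h - temperature * delta_s
    return bool(np.isclose(reported_delta_g, expected, rtol=rtol, atol=0.0))


def classify_forces(
    delta_h: float, delta_s: float, epsilon: float = 1000.0
) -> ForceCall:
    """Classify the dominant binding force from the signs of ΔH and ΔS.

    Ross-Subramanian sign rules with a near-zero enthalpy band of width
    ``epsilon`` (J mol⁻¹):

    * ΔH > ε and ΔS > 0 → hydrophobic
    * ΔH < −ε and ΔS < 0 → hydrogen bonding + van der Waals
    * |ΔH| ≤ ε and ΔS > 0 → electrostatic

    Sign patterns outside these canonical cases are mapped to the nearest
    rule and annotated in ``rule_trace``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if delta_h > epsilon and delta_s > 0:
        return ForceCall(
            "hydrophobic", epsilon, f"dH={delta_h:+.6g} > eps and dS={delta_s:+.6g} > 0"
        )
    if delta_h < -epsilon and delta_s < 0:
        return ForceCall(
            "hydrogen-bond-and-van-der-Waals",
            epsilon,
            f"dH={delta_h:+.6g} < -eps and dS={delta_s:+.6g} < 0",
        )
    if abs(delta_h) <= epsilon and delta_s > 0:
        return ForceCall(
            "electrostatic", epsilon, f"|dH|={abs(delta_h):.6g} <= eps and dS > 0"
        )
    # non-canonical pattern: nearest rule by the enthalpy axis, entropy second
    trace = f"outside canonical patterns (dH={delta_h:+.6g}, dS={delta_s:+.6g}); nearest rule"
    if delta_h < -epsilon:
        return ForceCall("hydrogen-bond-and-van-der-Waals", epsilon, trace)
    if delta_h > epsilon:
        return ForceCall("hydrophobic", epsilon, trace)
    return ForceCall("electrostatic", epsilon, trace)
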