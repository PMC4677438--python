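"""Double-logarithmic binding analysis.

For a ligand binding independently to n equivalent sites on the protein the
quenching data obey

    log10[(F0 - F)/F] = log10(Ka) + n * log10([Q])

so a straight-line fit of log10[(F0-F)/F] against log10[Q] yields the
binding number n from the slope and the binding constant Ka from the
intercept.  Ka carries units of (concentration unit)⁻ⁿ; the unit used for
[Q] in the regression is recorded with the result (μM by default, matching
how albumin-binding constants are usually tabulated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .quenching import _linefit
from .spectra_io import IntensityTable, _conc_factor

__all__ = ["DoubleLogFit", "DoubleLogRegressor", "double_log_fit"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoubleLogFit:
    """Binding constant and binding number from the double-log regression.

    ``ka`` is in (``conc_unit``)⁻ⁿ; ``n`` is dimensionless.
    """

    ka: float
    n: float
    conc_unit: str
    r_squared: float
    n_points: int
    temperature: float  # K

    def __post_init__(self):
        if not (self.ka > 0 and self.n > 0):
            raise ValueError("double-log fit produced nonpositive ka or n")


class DoubleLogRegressor(BaseEstimator, RegressorMixin):
    """Power-law binding model (F0-F)/F = Ka * [Q]^n fitted in log10 space.

    ``fit`` takes quencher concentrations ``X`` (n_samples, 1) in the unit
    of choice and the quenched fractions ``y`` = (F0-F)/F; both must be
    strictly positive.  Attributes: ``ka_``, ``n_``, ``r_squared_``,
    ``n_points_``.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("X must be a single concentration column")
        if np.any(X[:, 0] <= 0) or np.any(y <= 0):
            raise ValueError("concentrations and quenched fractions must be > 0")
        slope, intercept, r2, _ = _linefit(np.log10(X[:, 0]), np.log10(y))
        self.n_ = slope
        self.ka_ = 10.0**intercept
        self.r_squared_ = r2
        self.n_points_ = int(y.size)
        return self

    def predict(self, X):
        """Predicted quenched fraction (F0-F)/F at concentrations ``X``."""
        check_is_fitted(self, "ka_")
        X = check_array(X)
        return self.ka_ * X[:, 0] ** self.n_


def double_log_fit(table: IntensityTable, conc_unit: str = "uM") -> DoubleLogFit:
    """Fit the double-log binding line to an intensity table.

    Concentrations (stored in mol L⁻¹) are expressed in ``conc_unit`` for
    the regression, so the returned Ka is in (``conc_unit``)⁻ⁿ.  Points
    with F >= F0 carry no binding signal and are dropped with a warning;
    at least three usable points must remain.
    """
    # table concentrations are molar; rescale into the requested unit
    conc = table.concentrations / _conc_factor(conc_unit)
    quenched = (table.f0 - table.f_values) / table.f_values
    usable = quenched > 0
    n_dropped = int(np.count_nonzero(~usable))
    if n_dropped:
        logger.warning(
            "double-log fit dropped %d point(s) with F >= F0 (no quenching)",
            n_dropped,
        )
    if np.count_nonzero(usable) < 3:
        raise ValueError(
            f"double-log fit needs >= 3 usable points, got {np.count_nonzero(usable)}"
        )
    reg = DoubleLogRegressor().fit(conc[usable, None], quenched[usable])
    return DoubleLogFit(
        ka=reg.ka_,
        n=reg.n_,
        conc_unit=conc_unit,
        r_squared=reg.r_squared_,
        n_points=reg.n_points_,
        temperature=table.temperature,
    )
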