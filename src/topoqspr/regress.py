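"""Simple linear regression Y = A + B·X with the full QSPR statistics panel.

The panel follows the classical moment formulas: with centred sums
``Sxx``, ``Syy``, ``Sxy``,

* slope ``B = Sxy / Sxx`` and intercept ``A = ybar - B·xbar``,
* Pearson ``r = Sxy / sqrt(Sxx·Syy)``,
* standard error of estimate ``S.E. = sqrt(Syy·(1 - r²) / (n - 2))``,
* ``F = (n - 2)·r² / (1 - r²)`` with p-value from the upper tail of an
  F(1, n-2) distribution (equivalently the two-sided t test on the slope).

A constant response (``Syy == 0``) is defined as ``r = 0, S.E. = 0, F = 0,
p = 1`` rather than an error, so matrix-valued callers survive degenerate
columns; a constant predictor is always an error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RegressionFit",
    "DegenerateInputError",
    "SimpleLinearRegression",
    "fit_ols",
    "predict",
    "pearson_r",
    "round_half_away",
]


class DegenerateInputError(ValueError):
    """Raised on zero-variance predictors or undersized samples."""


def round_half_away(value: float, digits: int = 4) -> float:
    """Round with ties away from zero, as printed report values are.

    Plain ``round`` rounds halves to even, which disagrees with how
    regression software formats coefficients.
    """
    q = Decimal("1" if digits == 0 else "0." + "0" * (digits - 1) + "1")
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegressionFit:
    """One fitted simple-regression model and its statistics panel.

    Attributes
    ----------
    n : sample size
    a : intercept (units of Y)
    b : slope (units of Y per unit X)
    r : Pearson correlation between X and Y
    r2 : coefficient of determination, ``r**2``
    se : standard error of estimate (units of Y)
    f : F statistic of the overall regression, df (1, n-2)
    p : upper-tail p-value of the F test
    """

    n: int
    a: float
    b: float
    r: float
    r2: float
    se: float
    f: float
    p: float

    def predict(self, x: float) -> float:
        return self.a + self.b * x

    def round(self, digits: int = 4) -> "RegressionFit":
        """Panel with every statistic rounded half-away-from-zero.

        Applying a published equation means using its printed coefficients;
        this returns the fit as a report would print it.
        """
        return replace(
            self,
            **{
                k: round_half_away(getattr(self, k), digits)
                for k in ("a", "b", "r", "r2", "se", "f", "p")
            },
        )

    def equation(self, y_name: str = "Y", x_name: str = "X", digits: int = 4) -> str:
        return (
            f"{y_name} = {round_half_away(self.a, digits)} "
            f"+ {round_half_away(self.b, digits)} {x_name}"
        )


class SimpleLinearRegression(RegressorMixin, BaseEstimator):
    """Least-squares line fit exposing the QSPR statistics panel.

    sklearn-compatible: ``fit(X, y)`` with ``X`` of shape ``(n, 1)`` (or a
    1-d vector), ``predict``, ``get_params``/``set_params``. Fitted
    attributes carry the full panel: ``intercept_``, ``slope_``, ``r_``,
    ``r2_``, ``se_``, ``f_``, ``p_``, ``n_``.

    Examples
    --------
    >>> import numpy as np
    >>> m = SimpleLinearRegression().fit(np.arange(5.0), 2*np.arange(5.0)+1)
    >>> float(m.intercept_), float(m.slope_), float(m.r_)
    (1.0, 2.0, 1.0)
    """

    def fit(self, X, y) -> "SimpleLinearRegression":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError(
                    f"simple regression takes exactly one predictor, got {x.shape[1]}"
                )
            x = x[:, 0]
        elif x.ndim != 1:
            raise ValueError(f"X must be 1-d or (n, 1), got shape {x.shape}")
        yv = np.asarray(y, dtype=float)
        if yv.shape != x.shape:
            raise ValueError(f"length mismatch: len(x)={x.size}, len(y)={yv.size}")
        n = x.size
        if n < 3:
            raise DegenerateInputError(f"need n >= 3 observations, got {n}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(yv))):
            raise ValueError("non-finite values in input")

        xm, ym = x.mean(), yv.mean()
        dx, dy = x - xm, yv - ym
        sxx = float(dx @ dx)
        syy = float(dy @ dy)
        sxy = float(dx @ dy)
        if sxx == 0.0:
            raise DegenerateInputError("predictor has zero variance")

        b = sxy / sxx
        a = ym - b * xm
        if syy == 0.0:
            # flat response: perfect but uninformative; see module docstring
            r = se = f = 0.0
            p = 1.0
        else:
            r = sxy / np.sqrt(sxx * syy)
            r2 = r * r
            se = float(np.sqrt(syy * max(0.0, 1.0 - r2) / (n - 2)))
            if r2 >= 1.0:
                f = np.inf
                p = 0.0
            else:
                f = (n - 2) * r2 / (1.0 - r2)
                p = float(stats.f.sf(f, 1, n - 2))

        self.n_ = n
        self.intercept_ = float(a)
        self.slope_ = float(b)
        self.r_ = float(r)
        self.r2_ = float(r) ** 2
        self.se_ = float(se)
        self.f_ = float(f)
        self.p_ = float(p)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.intercept_ + self.slope_ * x

    @property
    def result_(self) -> RegressionFit:
        check_is_fitted(self, "slope_")
        return RegressionFit(
            n=self.n_,
            a=self.intercept_,
            b=self.slope_,
            r=self.r_,
            r2=self.r2_,
            se=self.se_,
            f=self.f_,
            p=self.p_,
        )


def fit_ols(x, y) -> RegressionFit:
    """Fit ``y = A + B·x`` and return the statistics panel."""
    return SimpleLinearRegression().fit(np.asarray(x, float), np.asarray(y, float)).result_


def predict(fit: RegressionFit, x: float) -> float:
    """Value of the fitted line at ``x`` (thin wrapper)."""
    return fit.predict(x)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; errors on zero-variance input."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    dx, dy = xv - xv.mean(), yv - yv.mean()
    sxx, syy = float(dx @ dx), float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateInputError("zero-variance input to pearson_r")
    return float((dx @ dy) / np.sqrt(sxx * syy))
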