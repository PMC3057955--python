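"""Two-state chemical denaturation by the linear extrapolation method (LEM).

The free energy of unfolding is assumed linear in denaturant,
ΔG(D) = ΔGu − m·D, giving an unfolded fraction
fU(D) = 1/(1 + exp(ΔG(D)/(R·T))) and an observed signal that mixes
sloped native and unfolded baselines.  Six parameters
(ΔGu, m, yN, sN, yU, sU) are fitted by nonlinear least squares; the
transition midpoint Cm = ΔGu/m is reported with a covariance-aware SE.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constants import R, T_REF
from .quantity import Quantity

__all__ = ["DenaturationCurve", "LEMFit", "lem_model",
           "LinearExtrapolationRegressor", "fit_lem"]


@dataclass(frozen=True)
class DenaturationCurve:
    D: np.ndarray  # denaturant, M
    y: np.ndarray  # observed signal, arbitrary units
    T: float = T_REF

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if D.shape != y.shape:
            raise ValueError("D and y must have equal lengths")
        if np.any(D < 0):
            raise ValueError("denaturant concentrations must be nonnegative")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class LEMFit:
    dGu: Quantity  # kJ mol⁻¹
    m_value: Quantity  # kJ mol⁻¹ M⁻¹
    Cm: Quantity  # M, = dGu/m with covariance-propagated SE
    baselines: tuple  # (yN, slope_N, yU, slope_U)
    rss: float


def unfolded_fraction(D, dGu: float, m: float, T: float = T_REF):
    """fU(D) for a two-state unfolder with ΔG(D) = ΔGu − m·D (kJ mol⁻¹)."""
    from scipy.special import expit
    D = np.asarray(D, dtype=float)
    return expit(-(dGu - m * D) * 1000.0 / (R * T))


def lem_model(D, dGu, m, yN, sN, yU, sU, T: float = T_REF):
    """Observed signal: baseline-weighted mixture of native and unfolded."""
    D = np.asarray(D, dtype=float)
    fU = unfolded_fraction(D, dGu, m, T)
    return (1.0 - fU) * (yN + sN * D) + fU * (yU + sU * D)


class LinearExtrapolationRegressor(RegressorMixin, BaseEstimator):
    """Six-parameter two-state LEM fit of a denaturation curve.

    X is a column of denaturant concentrations (M); y the observable
    (fluorescence, ellipticity, ... — the fit is observable-agnostic and
    its ΔGu and m are invariant under affine transforms of y).

    Fitted attributes: ``dGu_``, ``dGu_se_`` (kJ mol⁻¹), ``m_value_``,
    ``m_se_``, ``Cm_``, ``Cm_se_``, ``baselines_``, ``cov_``, ``rss_``.
    """

    def __init__(self, T: float = T_REF):
        self.T = T

    def fit(self, X, y):
        X = check_array(np.reshape(X, (-1, 1)))
        y = np.asarray(y, dtype=float).ravel()
        D = X[:, 0]
        if D.size != y.size:
            raise ValueError("X and y have inconsistent lengths")
        order = np.argsort(D)
        D, y = D[order], y[order]

        # initial guesses: flat baselines from the curve ends, midpoint
        # from the half-signal crossing, m from a ~1 M transition width
        yN0, yU0 = float(y[0]), float(y[-1])
        mid = 0.5 * (yN0 + yU0)
        Cm0 = float(D[np.argmin(np.abs(y - mid))])
        Cm0 = max(Cm0, 0.1)
        m0 = 4.0 * R * self.T / 1000.0  # kJ/mol/M: 10–90% width ≈ 1.1 M
        p0 = (m0 * Cm0, m0, yN0, 0.0, yU0, 0.0)

        def f(D, dGu, m, yN, sN, yU, sU):
            return lem_model(D, dGu, m, yN, sN, yU, sU, T=self.T)

        try:
            popt, pcov = curve_fit(f, D, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"LEM fit did not converge: {exc}") from exc
        dGu, m, yN, sN, yU, sU = map(float, popt)
        self.cov_ = np.asarray(pcov, dtype=float)
        ses = np.sqrt(np.diag(pcov))
        self.dGu_, self.m_value_ = dGu, m
        self.dGu_se_, self.m_se_ = float(ses[0]), float(ses[1])
        self.baselines_ = (yN, sN, yU, sU)
        self.Cm_ = dGu / m
        # var(Cm) from the (dGu, m) covariance block
        J = np.array([1.0 / m, -dGu / m**2])
        block = pcov[:2, :2]
        if np.all(np.isfinite(block)):
            self.Cm_se_ = float(math.sqrt(max(J @ block @ J, 0.0)))
        else:
            self.Cm_se_ = float("nan")
        resid = y - f(D, *popt)
        self.rss_ = float(resid @ resid)

        fU = unfolded_fraction(D, dGu, m, self.T)
        if np.count_nonzero((fU > 0.1) & (fU < 0.9)) < 3:
            warnings.warn("fewer than 3 points in the transition region "
                          "(0.1 < fU < 0.9); ΔGu and m are poorly constrained",
                          stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "dGu_")
        D = check_array(np.reshape(X, (-1, 1)))[:, 0]
        return lem_model(D, self.dGu_, self.m_value_, *self.baselines_, T=self.T)


def fit_lem(curve: DenaturationCurve) -> LEMFit:
    """Fit a DenaturationCurve, returning the frozen parameter record."""
    est = LinearExtrapolationRegressor(T=curve.T).fit(curve.D, curve.y)
    return LEMFit(
        dGu=Quantity(est.dGu_, est.dGu_se_),
        m_value=Quantity(est.m_value_, est.m_se_),
        Cm=Quantity(est.Cm_, est.Cm_se_),
        baselines=est.baselines_,
        rss=est.rss_,
    )
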