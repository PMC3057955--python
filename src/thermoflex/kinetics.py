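"""Michaelis–Menten and Arrhenius analysis of enzyme assay data.

Initial-rate data v(S) at a fixed temperature are fitted to
v = kcat·E0·S/(Km + S); the per-temperature kcat values are then
regressed as ln kcat on 1/T (Arrhenius) to obtain the activation energy
Ea = −slope·R.  Both fits are exposed as scikit-learn style estimators
so they compose with pipelines and model selection, plus thin functional
wrappers that return frozen result records.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constants import R
from .quantity import Quantity, as_quantity

__all__ = [
    "MMFit",
    "ArrheniusFit",
    "MichaelisMentenRegressor",
    "ArrheniusRegressor",
    "fit_michaelis_menten",
    "fit_arrhenius",
    "activation_energy_two_point",
    "extrapolate_kcat",
    "crossover_temperature",
    "read_assay_csv",
]

# typical assay temperature window, K; warn outside
_T_LO, _T_HI = 283.0, 318.0


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameters at one temperature."""

    kcat: Quantity  # s⁻¹
    Km: Quantity  # mM
    T: float  # K
    n_points: int
    rss: float


@dataclass(frozen=True)
class ArrheniusFit:
    """ln kcat vs 1/T regression: Ea = −slope·R."""

    Ea: Quantity  # kJ mol⁻¹
    lnA: Quantity  # ln(s⁻¹)
    cov: np.ndarray  # 2×2 covariance of (slope, intercept)
    points: tuple  # ((T, kcat, se), ...)
    r_squared: float


class MichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of v = kcat·E0·S/(Km + S).

    X has two columns, substrate concentration S (mM) and enzyme
    concentration E0 (nM); y is the initial rate in the same
    concentration unit per second as S (E0 is converted nM → mM
    internally so kcat comes out in s⁻¹).

    Fitted attributes: ``kcat_``, ``kcat_se_``, ``Km_``, ``Km_se_``,
    ``rss_``, ``n_points_``.
    """

    def __init__(self, max_nfev: int = 10000):
        self.max_nfev = max_nfev

    @staticmethod
    def _model(SE, kcat, Km):
        S, E0_mM = SE
        return kcat * E0_mM * S / (Km + S)

    def fit(self, X, y):
        X = check_array(X, ensure_min_features=2)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        S = X[:, 0]
        E0_mM = X[:, 1] * 1e-6  # nM → mM
        if np.any(S <= 0):
            raise ValueError("substrate concentrations S must be positive")
        if np.any(E0_mM <= 0):
            raise ValueError("enzyme concentrations E0 must be positive")
        if np.unique(S).size < 4:
            raise ValueError("need >=4 distinct substrate concentrations")

        # initial guesses: kcat from the highest observed v/E0,
        # Km from the S closest to half-maximal rate
        v_per_E = y / E0_mM
        kcat0 = float(np.max(v_per_E))
        half = kcat0 / 2.0
        Km0 = float(S[np.argmin(np.abs(v_per_E - half))])
        Km0 = max(Km0, 1e-6)
        try:
            popt, pcov = curve_fit(
                self._model, (S, E0_mM), y, p0=(kcat0, Km0),
                maxfev=self.max_nfev,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        self.kcat_, self.Km_ = map(float, popt)
        ses = np.sqrt(np.diag(pcov))
        self.kcat_se_, self.Km_se_ = map(float, ses)
        resid = y - self._model((S, E0_mM), *popt)
        self.rss_ = float(resid @ resid)
        self.n_points_ = int(y.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "kcat_")
        X = check_array(X, ensure_min_features=2)
        return self._model((X[:, 0], X[:, 1] * 1e-6), self.kcat_, self.Km_)


class ArrheniusRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares of ln kcat on 1/T.

    X is a column of absolute temperatures (K); y the turnover numbers
    (s⁻¹).  Per-point weights may be supplied via ``sample_weight``
    (inverse-variance weighting of ln kcat); the default is unweighted.

    Fitted attributes: ``Ea_`` (kJ mol⁻¹), ``Ea_se_``, ``lnA_``,
    ``lnA_se_``, ``cov_`` (2×2, (slope, intercept) of the ln kcat vs 1/T
    line), ``r_squared_``.
    """

    def __init__(self):
        pass

    def fit(self, X, y, sample_weight=None):
        X = check_array(np.reshape(X, (-1, 1)))
        y = np.asarray(y, dtype=float).ravel()
        T = X[:, 0]
        if T.size != y.size:
            raise ValueError("X and y have inconsistent lengths")
        if T.size < 3:
            raise ValueError("need >=3 temperatures for an Arrhenius fit")
        if np.any(T <= 0):
            raise ValueError("temperatures must be positive (K)")
        if np.any(y <= 0):
            raise ValueError("kcat values must be positive")
        x = 1.0 / T
        ly = np.log(y)
        w = np.ones_like(ly) if sample_weight is None else np.asarray(sample_weight, float)
        A = np.column_stack([x, np.ones_like(x)])
        Aw = A * w[:, None]
        XtX_inv = np.linalg.inv(Aw.T @ A)
        beta = XtX_inv @ (Aw.T @ ly)
        slope, intercept = map(float, beta)
        resid = ly - A @ beta
        dof = x.size - 2
        s2 = float(w @ resid**2) / dof if dof > 0 else 0.0
        self.cov_ = s2 * XtX_inv
        self.Ea_ = float(-slope * R / 1000.0)
        self.Ea_se_ = float(math.sqrt(self.cov_[0, 0]) * R / 1000.0)
        self.lnA_ = float(intercept)
        self.lnA_se_ = float(math.sqrt(self.cov_[1, 1]))
        fitted = slope * x + intercept
        ss_res = float(np.sum((ly - fitted) ** 2))
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self._points = tuple((float(t), float(k)) for t, k in zip(T, y))
        return self

    def predict(self, X):
        """kcat(T) = exp(lnA − Ea·1000/(R·T))."""
        check_is_fitted(self, "Ea_")
        T = check_array(np.reshape(X, (-1, 1)))[:, 0]
        return np.exp(self.lnA_ - 1000.0 * self.Ea_ / (R * T))

    def predict_with_se(self, T: float) -> Quantity:
        """Extrapolated kcat at one temperature with SE from the line covariance."""
        check_is_fitted(self, "Ea_")
        if not T > 0:
            raise ValueError(f"T must be positive, got {T}")
        x = 1.0 / T
        lnk = self.lnA_ - 1000.0 * self.Ea_ / (R * T)
        J = np.array([x, 1.0])
        var_lnk = float(J @ self.cov_ @ J)
        k = math.exp(lnk)
        return Quantity(k, k * math.sqrt(max(var_lnk, 0.0)))


def fit_michaelis_menten(points: pd.DataFrame) -> MMFit:
    """Fit one temperature's assay points (columns S_mM, rate, E0_nM, T).

    Emits a warning when the assay temperature is outside the usual
    283–318 K window for the substrate.
    """
    T_vals = np.unique(np.asarray(points["T"], dtype=float))
    if T_vals.size != 1:
        raise ValueError("fit_michaelis_menten expects points at a single temperature")
    T = float(T_vals[0])
    if not (_T_LO <= T <= _T_HI):
        warnings.warn(f"assay temperature {T} K outside typical range "
                      f"[{_T_LO}, {_T_HI}] K", stacklevel=2)
    est = MichaelisMentenRegressor().fit(
        np.column_stack([points["S_mM"], points["E0_nM"]]),
        np.asarray(points["rate"], dtype=float),
    )
    return MMFit(
        kcat=Quantity(est.kcat_, est.kcat_se_),
        Km=Quantity(est.Km_, est.Km_se_),
        T=T, n_points=est.n_points_, rss=est.rss_,
    )


def fit_arrhenius(series) -> ArrheniusFit:
    """Fit ln kcat vs 1/T from a sequence of (T, kcat) pairs.

    kcat entries may be Quantity, float, or (value, se).
    """
    T = np.array([float(t) for t, _ in series])
    q = [as_quantity(k) for _, k in series]
    k = np.array([x.value for x in q])
    est = ArrheniusRegressor().fit(T, k)
    pts = tuple((float(t), x.value, x.se) for t, x in zip(T, q))
    return ArrheniusFit(
        Ea=Quantity(est.Ea_, est.Ea_se_),
        lnA=Quantity(est.lnA_, est.lnA_se_),
        cov=est.cov_, points=pts, r_squared=est.r_squared_,
    )


def activation_energy_two_point(T1: float, k1: float, T2: float, k2: float) -> float:
    """Closed-form Ea (kJ mol⁻¹) through two (T, kcat) points.

    Ea = R·ln(k2/k1)/(1/T1 − 1/T2)/1000 — the algebraic limit of the
    Arrhenius regression, useful as an independent cross-check.
    """
    return R * math.log(k2 / k1) / (1.0 / T1 - 1.0 / T2) / 1000.0


def _regressor_from_fit(fit: ArrheniusFit) -> ArrheniusRegressor:
    est = ArrheniusRegressor.__new__(ArrheniusRegressor)
    est.Ea_, est.Ea_se_ = fit.Ea.value, fit.Ea.se or 0.0
    est.lnA_, est.lnA_se_ = fit.lnA.value, fit.lnA.se or 0.0
    est.cov_ = np.asarray(fit.cov, dtype=float)
    return est


def extrapolate_kcat(fit: ArrheniusFit, T: float) -> Quantity:
    """kcat(T) on the fitted Arrhenius line, with covariance-propagated SE."""
    return _regressor_from_fit(fit).predict_with_se(T)


def crossover_temperature(fit_a: ArrheniusFit, fit_b: ArrheniusFit) -> float | None:
    """Temperature where two Arrhenius lines intersect, K.

    T* = (Ea_a − Ea_b)·1000 / (R·(lnA_a − lnA_b)); None when the lines
    are parallel (equal slopes) or the algebraic crossing is unphysical
    (T* ≤ 0).
    """
    dEa = fit_a.Ea.value - fit_b.Ea.value
    dlnA = fit_a.lnA.value - fit_b.lnA.value
    if dEa == 0 or dlnA == 0:
        return None
    T = 1000.0 * dEa / (R * dlnA)
    return T if T > 0 else None


def read_assay_csv(path) -> pd.DataFrame:
    """Read an assay CSV with columns variant,T,S_mM,rate,E0_nM,replicate."""
    df = pd.read_csv(path)
    required = {"T", "S_mM", "rate", "E0_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns: {sorted(missing)}")
    return df
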