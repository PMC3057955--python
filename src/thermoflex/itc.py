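"""Single-site isothermal titration calorimetry (ITC) analysis.

Forward model: the closed-form (Wiseman) cumulative heat for 1:1 binding
of a titrant X to a macromolecule M in a perfused cell of volume V0,
with displacement dilution applied multiplicatively to both species at
each injection.  Fitting recovers (Ka, ΔHb, n) from the per-injection
heats; the thermodynamic decomposition uses ΔGb = −RT·ln Ka and
TΔSb = ΔHb − ΔGb.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .constants import R, T_REF
from .quantity import Quantity, as_quantity, quadrature
from .thermo import DeltaDelta

__all__ = [
    "TitrationProtocol",
    "BindingFit",
    "BindingThermo",
    "simulate_injection_heats",
    "SingleSiteBindingRegressor",
    "fit_single_site",
    "binding_decompose",
    "binding_delta_delta",
    "read_itc_csv",
    "write_itc_csv",
]


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell/syringe geometry and concentrations of one titration.

    Defaults correspond to a common microcalorimeter setup: 25 × 4 µl
    injections of 30 mM titrant into 1.5 mM macromolecule in a 1 ml cell.
    """

    V0_ml: float = 1.0
    M0_mM: float = 1.5
    X0_mM: float = 30.0
    injection_volumes_ul: tuple = tuple([4.0] * 25)
    T: float = T_REF

    def __post_init__(self):
        if min(self.V0_ml, self.M0_mM, self.X0_mM, self.T) <= 0:
            raise ValueError("protocol parameters must be positive")
        if len(self.injection_volumes_ul) == 0 or min(self.injection_volumes_ul) <= 0:
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class BindingFit:
    """Fitted single-site parameters."""

    Ka: Quantity  # M⁻¹
    dHb: Quantity  # kJ mol⁻¹
    n_sites: Quantity
    rss: float  # µJ²


@dataclass(frozen=True)
class BindingThermo:
    """Binding thermodynamics at temperature T."""

    Ka: Quantity  # M⁻¹
    dGb: Quantity  # kJ mol⁻¹
    dHb: Quantity  # kJ mol⁻¹
    dSb: Quantity  # J mol⁻¹ K⁻¹
    TdSb: Quantity  # kJ mol⁻¹
    T: float
    label: str = ""


def _cumulative_heats(protocol: TitrationProtocol, Ka: float, dHb_kJ: float,
                      n_sites: float) -> np.ndarray:
    """Cumulative heat Q_i (J) after each injection, Wiseman closed form."""
    V0 = protocol.V0_ml * 1e-3  # L
    dH = dHb_kJ * 1000.0  # J/mol
    X0 = protocol.X0_mM * 1e-3  # M
    Mt = protocol.M0_mM * 1e-3
    Xt = 0.0
    Q = np.empty(len(protocol.injection_volumes_ul))
    for i, dv_ul in enumerate(protocol.injection_volumes_ul):
        f = dv_ul * 1e-6 / V0  # injected fraction of the cell volume
        dil = 1.0 - f
        Mt *= dil
        Xt = Xt * dil + X0 * f
        r = Xt / (n_sites * Mt)
        inv_c = 1.0 / (n_sites * Ka * Mt)
        b = 1.0 + r + inv_c
        disc = b * b - 4.0 * r
        assert disc >= 0.0, "binding quadratic discriminant went negative"
        Q[i] = n_sites * Mt * dH * V0 / 2.0 * (b - math.sqrt(disc))
    return Q


def simulate_injection_heats(protocol: TitrationProtocol, Ka: float, dHb: float,
                             n_sites: float = 1.0, noise_sd: float = 0.0,
                             rng=None) -> np.ndarray:
    """Per-injection heats (µJ) for a single-site titration.

    Parameters
    ----------
    Ka : float
        Association constant, M⁻¹ (> 0).
    dHb : float
        Molar binding enthalpy, kJ mol⁻¹.
    n_sites : float
        Binding stoichiometry.
    noise_sd : float
        Additive Gaussian noise on each injection heat, µJ.

    The i-th injection heat is the cumulative-heat increment corrected
    for the heat carried out by cell displacement:
    q_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2.
    """
    if Ka <= 0:
        raise ValueError(f"Ka must be positive, got {Ka}")
    Q = _cumulative_heats(protocol, Ka, dHb, n_sites)
    V0 = protocol.V0_ml * 1e-3
    q = np.empty_like(Q)
    prev = 0.0
    for i, dv_ul in enumerate(protocol.injection_volumes_ul):
        f = dv_ul * 1e-6 / V0
        q[i] = Q[i] - prev + f * (Q[i] + prev) / 2.0
        prev = Q[i]
    q *= 1e6  # J → µJ
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        q = q + rng.normal(0.0, noise_sd, size=q.size)
    return q


class SingleSiteBindingRegressor(BaseEstimator):
    """Least-squares fit of per-injection heats to the single-site model.

    Parameterized internally as (ln Ka, ΔHb, n) for conditioning.  X is
    ignored (the injection schedule comes from ``protocol``); y is the
    heat vector in µJ.

    Fitted attributes: ``Ka_``, ``Ka_se_`` (M⁻¹), ``dH_``, ``dH_se_``
    (kJ mol⁻¹), ``n_sites_``, ``n_se_``, ``rss_``.
    """

    def __init__(self, protocol: TitrationProtocol | None = None,
                 fix_n: bool = False, drop_first: bool = False):
        self.protocol = protocol
        self.fix_n = fix_n
        self.drop_first = drop_first

    def fit(self, X=None, y=None):
        if y is None:
            X, y = None, X  # allow fit(heats)
        protocol = self.protocol or TitrationProtocol()
        q = np.asarray(y, dtype=float).ravel()
        if q.size != len(protocol.injection_volumes_ul):
            raise ValueError("number of heats does not match the protocol")
        if q.size < 10:
            raise ValueError("need >=10 injections for a single-site fit")
        if not np.all(np.isfinite(q)):
            raise ValueError("heats must be finite")
        mask = np.ones(q.size, dtype=bool)
        if self.drop_first:
            mask[0] = False

        # crude initial guesses: total heat sets dH·n, midpoint sets Ka scale
        V0 = protocol.V0_ml * 1e-3
        M_tot = protocol.M0_mM * 1e-3 * V0  # mol (ignoring dilution, good enough)
        dH0 = float(np.sum(q[mask]) * 1e-6 / M_tot / 1000.0)  # kJ/mol, n≈1
        if dH0 == 0:
            dH0 = -1.0
        lnKa0 = math.log(10.0 / (protocol.M0_mM * 1e-3))  # c ≈ 10

        xdummy = np.arange(int(mask.sum()), dtype=float)

        def model(_x, lnKa, dH, n):
            return simulate_injection_heats(protocol, math.exp(lnKa), dH, n)[mask]

        if self.fix_n:
            def model_fixed(_x, lnKa, dH):
                return model(_x, lnKa, dH, 1.0)
            popt, pcov = curve_fit(model_fixed, xdummy, q[mask], p0=(lnKa0, dH0))
            lnKa, dH = popt
            n, n_se = 1.0, 0.0
            lnKa_se, dH_se = np.sqrt(np.diag(pcov))
            resid = q[mask] - model_fixed(xdummy, *popt)
        else:
            popt, pcov = curve_fit(model, xdummy, q[mask], p0=(lnKa0, dH0, 1.0))
            lnKa, dH, n = popt
            lnKa_se, dH_se, n_se = np.sqrt(np.diag(pcov))
            resid = q[mask] - model(xdummy, *popt)

        self.Ka_ = float(math.exp(lnKa))
        self.Ka_se_ = float(self.Ka_ * lnKa_se)
        self.dH_ = float(dH)
        self.dH_se_ = float(dH_se)
        self.n_sites_ = float(n)
        self.n_se_ = float(n_se)
        self.rss_ = float(resid @ resid)
        c = self.n_sites_ * self.Ka_ * protocol.M0_mM * 1e-3
        if not (1.0 <= c <= 1000.0):
            warnings.warn(f"c-value {c:.3g} outside [1, 1000]; the isotherm "
                          "is poorly determined", stacklevel=2)
        return self

    def predict(self, X=None):
        check_is_fitted(self, "Ka_")
        protocol = self.protocol or TitrationProtocol()
        return simulate_injection_heats(protocol, self.Ka_, self.dH_, self.n_sites_)


def fit_single_site(protocol: TitrationProtocol, heats,
                    fix_n: bool = False, drop_first: bool = False) -> BindingFit:
    """Fit (Ka, ΔHb, n) to per-injection heats (µJ)."""
    est = SingleSiteBindingRegressor(protocol=protocol, fix_n=fix_n,
                                     drop_first=drop_first).fit(heats)
    return BindingFit(
        Ka=Quantity(est.Ka_, est.Ka_se_),
        dHb=Quantity(est.dH_, est.dH_se_),
        n_sites=Quantity(est.n_sites_, est.n_se_),
        rss=est.rss_,
    )


def binding_decompose(Ka, dHb, T: float = T_REF, label: str = "") -> BindingThermo:
    """ΔGb = −(R·T/1000)·ln Ka; TΔSb = ΔHb − ΔGb; ΔSb = 1000·TΔSb/T.

    se(ΔGb) = (R·T/1000)·se(Ka)/Ka; downstream SEs by quadrature.
    """
    Ka = as_quantity(Ka)
    dHb = as_quantity(dHb)
    if not Ka.value > 0:
        raise ValueError(f"Ka must be positive, got {Ka.value}")
    RT = R * T / 1000.0
    dGb = Quantity(-RT * math.log(Ka.value),
                   None if Ka.se is None else RT * Ka.se / Ka.value)
    TdSb = dHb - dGb
    dSb = TdSb.scaled(1000.0 / T)
    return BindingThermo(Ka=Ka, dGb=dGb, dHb=dHb, dSb=dSb, TdSb=TdSb, T=T, label=label)


def binding_delta_delta(a: BindingThermo, b: BindingThermo) -> DeltaDelta:
    """ΔΔ binding parameters ``a − b`` (a: without the interaction)."""
    if a.T != b.T:
        raise ValueError(f"temperature mismatch: {a.T} vs {b.T}")
    return DeltaDelta(
        label_a=a.label, label_b=b.label,
        ddG=a.dGb - b.dGb, ddH=a.dHb - b.dHb,
        TddS=a.TdSb - b.TdSb, ddS=a.dSb - b.dSb,
        T_ref=a.T,
    )


def read_itc_csv(path) -> tuple[TitrationProtocol, np.ndarray]:
    """Read injection heats plus a '#'-prefixed protocol header.

    Header lines: ``# cell_ml: 1.0`` etc (cell_ml, protein_mM,
    syringe_mM, T_K); body columns: injection,volume_ul,heat_uJ.
    """
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = float(val)
            body_start = i + 1
        else:
            break
    import io
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    protocol = TitrationProtocol(
        V0_ml=meta.get("cell_ml", 1.0),
        M0_mM=meta.get("protein_mM", 1.5),
        X0_mM=meta.get("syringe_mM", 30.0),
        injection_volumes_ul=tuple(df["volume_ul"].astype(float)),
        T=meta.get("T_K", T_REF),
    )
    return protocol, df["heat_uJ"].to_numpy(dtype=float)


def write_itc_csv(path, protocol: TitrationProtocol, heats) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_ml: {protocol.V0_ml}\n")
        fh.write(f"# protein_mM: {protocol.M0_mM}\n")
        fh.write(f"# syringe_mM: {protocol.X0_mM}\n")
        fh.write(f"# T_K: {protocol.T}\n")
        fh.write("injection,volume_ul,heat_uJ\n")
        for i, (v, q) in enumerate(zip(protocol.injection_volumes_ul, heats), 1):
            fh.write(f"{i},{v:.6g},{q:.10g}\n")
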