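"""Transition-state-theory decomposition of enzyme turnover rates.

The Eyring equation with unit transmission coefficient links a turnover
number to an activation free energy,

    kcat = (kB·T/h)·exp(−ΔG#/(R·T)),

so ΔG# = R·T·(ln(kB·T/h) − ln kcat).  Combined with the Arrhenius
activation energy Ea, the enthalpic and entropic parts follow from
ΔH# = Ea − R·T and TΔS# = ΔH# − ΔG#.  Paired differences between an
enzyme variant lacking a structural interaction and the variant bearing
it (ΔΔG#, ΔΔH#, TΔΔS#) isolate the thermodynamic signature of that
interaction; when ΔΔH# and TΔΔS# are of similar sign and size, the
variants show enthalpy–entropy compensation with a crossing temperature
Tc = ΔΔH#/ΔΔS# where ΔΔG# changes sign.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import H, KB, R, T_REF
from .quantity import Quantity, as_quantity, quadrature

__all__ = [
    "ActivationThermo",
    "DeltaDelta",
    "CompensationCurve",
    "eyring_decompose",
    "delta_delta",
    "compensation_curve",
    "entropic_fold_change",
]


@dataclass(frozen=True)
class ActivationThermo:
    """Activation thermodynamics of one enzyme variant at T_ref.

    Energies (kcat excepted) are kJ mol⁻¹; dS is J mol⁻¹ K⁻¹.
    """

    T_ref: float
    kcat: Quantity
    Ea: Quantity
    dG: Quantity
    dH: Quantity
    dS: Quantity
    TdS: Quantity
    label: str = ""


@dataclass(frozen=True)
class DeltaDelta:
    """Paired difference of thermodynamic parameters between two variants.

    Sign convention: ``a − b`` where *a* is the variant without the
    interaction under study and *b* the variant with it.
    """

    label_a: str
    label_b: str
    ddG: Quantity
    ddH: Quantity
    TddS: Quantity
    ddS: Quantity
    T_ref: float = T_REF


@dataclass(frozen=True)
class CompensationCurve:
    """ΔΔG#(T) under temperature-independent ΔΔH# and ΔΔS#."""

    T: np.ndarray
    ddG: np.ndarray
    ddH: float
    TddS: np.ndarray
    Tc: float | None  #: compensation temperature where ΔΔG crosses zero, K


def eyring_decompose(kcat, Ea, T_ref: float = T_REF, label: str = "") -> ActivationThermo:
    """Decompose (kcat, Ea) into ΔG#, ΔH#, ΔS# and TΔS# at ``T_ref``.

    Parameters
    ----------
    kcat : Quantity | float | (value, se)
        Turnover number at ``T_ref``, s⁻¹.  Must be positive.
    Ea : Quantity | float | (value, se)
        Arrhenius activation energy, kJ mol⁻¹.
    T_ref : float
        Temperature, K.

    Standard errors: se(ΔG#) = R·T·se(kcat)/kcat (first order in ln kcat),
    se(ΔH#) = se(Ea), se(TΔS#) by quadrature of the two.
    """
    kcat = as_quantity(kcat)
    Ea = as_quantity(Ea)
    if not T_ref > 0:
        raise ValueError(f"T_ref must be positive, got {T_ref}")
    if not kcat.value > 0:
        raise ValueError(f"kcat must be positive, got {kcat.value}")

    RT = R * T_ref / 1000.0  # kJ mol⁻¹
    dG_val = RT * (math.log(KB * T_ref / H) - math.log(kcat.value))
    dG_se = None if kcat.se is None else RT * kcat.se / kcat.value
    dG = Quantity(dG_val, dG_se)
    dH = Quantity(Ea.value - RT, Ea.se)
    TdS = dH - dG
    dS = TdS.scaled(1000.0 / T_ref)
    return ActivationThermo(T_ref=T_ref, kcat=kcat, Ea=Ea, dG=dG, dH=dH, dS=dS,
                            TdS=TdS, label=label)


def delta_delta(a: ActivationThermo, b: ActivationThermo) -> DeltaDelta:
    """ΔΔ parameters ``a − b`` (a: no interaction, b: with interaction).

    Both records must be decomposed at the same reference temperature.
    Standard errors combine in quadrature.
    """
    if a.T_ref != b.T_ref:
        raise ValueError(f"T_ref mismatch: {a.T_ref} vs {b.T_ref}")
    return DeltaDelta(
        label_a=a.label,
        label_b=b.label,
        ddG=a.dG - b.dG,
        ddH=a.dH - b.dH,
        TddS=a.TdS - b.TdS,
        ddS=a.dS - b.dS,
        T_ref=a.T_ref,
    )


def compensation_curve(dd: DeltaDelta, T_grid) -> CompensationCurve:
    """ΔΔG#(T) = ΔΔH# − T·ΔΔS# over ``T_grid``, assuming ΔΔH#, ΔΔS# constant.

    Also returns the compensation temperature Tc = ΔΔH#/ΔΔS# (in K) where
    the free-energy difference crosses zero; absent when ΔΔS# = 0.
    """
    T = np.asarray(T_grid, dtype=float)
    ddH = dd.ddH.value
    ddS = 1000.0 * dd.TddS.value / dd.T_ref  # J mol⁻¹ K⁻¹
    TddS = T * ddS / 1000.0
    ddG = ddH - TddS
    Tc = 1000.0 * ddH / ddS if ddS != 0 else None
    return CompensationCurve(T=T, ddG=ddG, ddH=ddH, TddS=TddS, Tc=Tc)


def entropic_fold_change(TddS: float, T: float = T_REF) -> float:
    """Rate ratio implied by an activation-entropy change at constant ΔH#.

    exp(TΔΔS#/(R·T)) with TΔΔS# in kJ mol⁻¹; e.g. a 20 kJ mol⁻¹ entropic
    gain at 298 K corresponds to a >3000-fold increase in kcat.
    """
    if not T > 0:
        raise ValueError(f"T must be positive, got {T}")
    return math.exp(1000.0 * TddS / (R * T))
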