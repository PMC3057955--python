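"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here: assay
rate tables (Michaelis–Menten kinetics on an Arrhenius temperature
dependence), ITC injection heats, denaturation curves, and dihedral /
distance trajectories (hidden-Markov rotamer dynamics with von Mises
angular noise).  Generators are pure functions of (parameters, seed):
the same seed always yields the same dataset.

Noise models: multiplicative Gaussian for assay rates (CV-parameterized),
additive Gaussian for ITC heats and denaturation signals, von Mises for
dihedral angles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .constants import R, T_REF
from .flexibility import DihedralTrace, DistanceTrace
from .itc import TitrationProtocol, simulate_injection_heats
from .stability import DenaturationCurve, lem_model

__all__ = [
    "KineticsScenario", "TrajectoryScenario", "ROTAMER_CANONICAL",
    "kcat_at", "generate_assay_data", "generate_kcat_series",
    "generate_itc_data", "generate_denaturation_curve",
    "generate_dihedral_trajectory", "kinetics_scenario_for",
    "trajectory_scenario_for",
]

#: canonical χ angles (degrees) of the rotamers seen in the simulations
ROTAMER_CANONICAL = {
    "mtm180": (300.0, 180.0, 300.0, 180.0),
    "ptt180": (60.0, 180.0, 180.0, 180.0),
    "ttp180": (180.0, 180.0, 60.0, 180.0),
    "mtt180": (300.0, 180.0, 180.0, 180.0),
}

#: substrate levels, mM (8 levels spanning 0.05–2.0, bracketing Km = 0.10)
S_LEVELS = (0.05, 0.1, 0.2, 0.4, 0.8, 1.2, 1.6, 2.0)


@dataclass(frozen=True)
class KineticsScenario:
    """Ground truth for one variant's assay dataset."""

    kcat_ref: float  # s⁻¹ at 298 K
    Ea: float  # kJ mol⁻¹
    Km: float = presets.KM_MM  # mM
    temperatures: tuple = presets.TEMPERATURES_THERMO
    E0_nM: float = 1.0
    noise_cv: float = 0.03
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.kcat_ref, self.Ea, self.Km, self.E0_nM) <= 0:
            raise ValueError("scenario parameters must be positive")


@dataclass(frozen=True)
class TrajectoryScenario:
    """Hidden-Markov rotamer dynamics plus a coupled distance trace."""

    states: tuple = tuple(ROTAMER_CANONICAL)
    transition_matrix: np.ndarray | None = None
    kappa: float = 50.0  # von Mises concentration per angle
    n_frames: int = 10000
    dt_ps: float = 1.0
    seed: int = 0
    bridge_present: bool = True
    bridge_d_mean: float = 3.2  # Å, donor–acceptor distance when bridged
    broken_d_mean: float = 6.0  # Å when the bridge is absent
    d_sd: float = 0.15

    def matrix(self) -> np.ndarray:
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
        elif self.bridge_present:
            # native rotamer strongly dominant: rare, short excursions
            k = len(self.states)
            P = np.full((k, k), 0.0005)
            np.fill_diagonal(P, 0.0)
            P[0, :] = 0.0005 / (k - 1)
            P[0, 0] = 0.0
            P[1:, 0] = 0.05
            P += np.diag(1.0 - P.sum(axis=1))
        else:
            # free side chain: frequent transitions among all wells
            k = len(self.states)
            P = np.full((k, k), 0.005)
            np.fill_diagonal(P, 0.0)
            P += np.diag(1.0 - P.sum(axis=1))
        if P.shape[0] != P.shape[1] or P.shape[0] != len(self.states):
            raise ValueError("transition matrix shape does not match states")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be stochastic")
        return P


def kcat_at(kcat_ref: float, Ea: float, T, T_ref: float = T_REF):
    """Arrhenius temperature dependence anchored at ``kcat_ref`` (T_ref)."""
    T = np.asarray(T, dtype=float)
    return kcat_ref * np.exp(-(Ea * 1000.0 / R) * (1.0 / T - 1.0 / T_ref))


def kinetics_scenario_for(variant: str, noise_cv: float = 0.03,
                          seed: int = 0) -> KineticsScenario:
    """Scenario preset for a named variant (published kcat/Ea, Km 0.10 mM)."""
    _, kcat, _, Ea, _ = presets.KINETICS[variant]
    return KineticsScenario(kcat_ref=kcat, Ea=Ea,
                            temperatures=presets.temperatures_for(variant),
                            noise_cv=noise_cv, seed=seed)


def generate_assay_data(scenario: KineticsScenario) -> pd.DataFrame:
    """Triplicate Michaelis–Menten rates over the temperature grid.

    Columns: T, S_mM, rate, E0_nM, replicate.  Rates carry multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    E0_mM = scenario.E0_nM * 1e-6
    for T in scenario.temperatures:
        kc = float(kcat_at(scenario.kcat_ref, scenario.Ea, T))
        for S in S_LEVELS:
            v = kc * E0_mM * S / (scenario.Km + S)
            for rep in range(scenario.n_replicates):
                noise = rng.normal(0.0, scenario.noise_cv) if scenario.noise_cv > 0 else 0.0
                rows.append((T, S, v * (1.0 + noise), scenario.E0_nM, rep))
    return pd.DataFrame(rows, columns=["T", "S_mM", "rate", "E0_nM", "replicate"])


def generate_kcat_series(scenario: KineticsScenario) -> list:
    """Noise-free (T, kcat) pairs on the scenario's Arrhenius line."""
    return [(T, float(kcat_at(scenario.kcat_ref, scenario.Ea, T)))
            for T in scenario.temperatures]


def generate_itc_data(protocol: TitrationProtocol, Ka: float, dHb: float,
                      n_sites: float = 1.0, noise_sd: float = 0.0,
                      seed: int = 0) -> np.ndarray:
    """Per-injection heats (µJ) with seeded additive Gaussian noise."""
    return simulate_injection_heats(protocol, Ka, dHb, n_sites,
                                    noise_sd=noise_sd,
                                    rng=np.random.default_rng(seed))


def generate_denaturation_curve(dGu: float = 58.0, m_value: float = 10.9,
                                baselines=(1.0, 0.0, 0.0, 0.0),
                                D_grid=None, noise_sd: float = 0.0,
                                seed: int = 0, T: float = T_REF) -> DenaturationCurve:
    """Two-state LEM signal on a denaturant grid, with additive noise.

    The default grid (0–7.5 M in 0.25 M steps) spans both baselines and
    the transition for the default (ΔGu, m) = (58, 10.9), Cm ≈ 5.3 M.
    """
    if D_grid is None:
        D_grid = np.arange(0.0, 7.51, 0.25)
    D = np.asarray(D_grid, dtype=float)
    y = lem_model(D, dGu, m_value, *baselines, T=T)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=D.size)
    return DenaturationCurve(D=D, y=y, T=T)


def trajectory_scenario_for(bridge_present: bool, n_frames: int = 10000,
                            seed: int = 0) -> TrajectoryScenario:
    """Preset emulating the with/without-salt-bridge simulation regimes."""
    return TrajectoryScenario(bridge_present=bridge_present,
                              n_frames=n_frames, seed=seed)


def generate_dihedral_trajectory(scenario: TrajectoryScenario):
    """Markov rotamer path with von Mises angles and a coupled distance trace.

    Returns ``(DihedralTrace, DistanceTrace)``.  The distance is drawn
    around 3.2 Å (bridge present) or 6.0 Å (absent); non-native rotamer
    frames sit slightly farther out, correlating the two observables.
    """
    rng = np.random.default_rng(scenario.seed)
    P = scenario.matrix()
    k = len(scenario.states)
    n = scenario.n_frames
    path = np.empty(n, dtype=int)
    path[0] = 0
    # vectorized-ish simulation: cumulative rows sampled with one uniform each
    cums = P.cumsum(axis=1)
    u = rng.random(n - 1)
    for i in range(1, n):
        path[i] = np.searchsorted(cums[path[i - 1]], u[i - 1], side="right")
    canon = np.array([ROTAMER_CANONICAL[s] for s in scenario.states])
    jitter = np.degrees(rng.vonmises(0.0, scenario.kappa, size=(n, 4)))
    chi = np.mod(canon[path] + jitter, 360.0)
    time = np.arange(n) * scenario.dt_ps
    base = scenario.bridge_d_mean if scenario.bridge_present else scenario.broken_d_mean
    d = base + 0.3 * (path != 0) + rng.normal(0.0, scenario.d_sd, size=n)
    d = np.maximum(d, 0.5)
    return (DihedralTrace(time=time, chi=chi, residue_label="active-site Arg"),
            DistanceTrace(time=time, d=d))
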