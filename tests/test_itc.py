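"""Single-site titration calorimetry: forward model, fitting, decomposition.

The forward model's independent oracle is a per-injection equilibrium
solver: the bound-complex concentration is found by bisection on the
binding polynomial Ka·(n·Mt − C)·(Xt − C) − C = 0 instead of the closed
form, and cumulative heats are compared injection by injection.
"""
import math

import numpy as np
import pytest

from thermoflex.constants import R
from thermoflex.itc import (TitrationProtocol, binding_decompose, binding_delta_delta,
                            fit_single_site, simulate_injection_heats)
from thermoflex.quantity import Quantity
from thermoflex.simulate import generate_itc_data


def bisection_heats(protocol, Ka, dHb_kJ, n_sites=1.0, tol=1e-15):
    """Oracle: per-injection heats from a root-bracketing equilibrium solve."""
    V0 = protocol.V0_ml * 1e-3
    X0 = protocol.X0_mM * 1e-3
    Mt, Xt = protocol.M0_mM * 1e-3, 0.0
    q, Q_prev = [], 0.0
    for dv_ul in protocol.injection_volumes_ul:
        f = dv_ul * 1e-6 / V0
        Mt *= 1.0 - f
        Xt = Xt * (1.0 - f) + X0 * f
        lo, hi = 0.0, min(n_sites * Mt, Xt)

        def g(C):
            return Ka * (n_sites * Mt - C) * (Xt - C) - C

        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol * max(hi, 1.0):
                break
        C = 0.5 * (lo + hi)
        Q = C * V0 * dHb_kJ * 1000.0
        q.append((Q - Q_prev + f * (Q + Q_prev) / 2.0) * 1e6)
        Q_prev = Q
    return np.array(q)


def test_zero_enthalpy_gives_zero_heats(protocol):
    assert np.all(simulate_injection_heats(protocol, 6.6e3, 0.0) == 0.0)


def test_infinite_affinity_limit_is_stoichiometric(protocol):
    """At Ka→∞ before saturation, each injection heat ≈ ΔH × moles injected."""
    q = simulate_injection_heats(protocol, 1e12, -6.7)
    moles_per_inj = 30e-3 * 4e-6  # syringe M × injection L
    expected_uJ = -6.7e3 * moles_per_inj * 1e6
    # early injections (well before the 1:1 equivalence point)
    assert q[:5] == pytest.approx(np.full(5, expected_uJ), rel=5e-3)


def test_closed_form_matches_bisection_oracle(protocol):
    for Ka in (1e2, 1e3, 6.6e3, 1e5, 1e7):
        q = simulate_injection_heats(protocol, Ka, -6.7)
        oracle = bisection_heats(protocol, Ka, -6.7)
        np.testing.assert_allclose(q, oracle, rtol=1e-8,
                                   atol=1e-8 * float(np.max(np.abs(oracle))))


def test_cumulative_heat_approaches_bound_fraction_total(protocol):
    Ka, dHb = 6.6e3, -6.7
    q = simulate_injection_heats(protocol, Ka, dHb)
    # against the oracle's final bound concentration
    oracle_total = bisection_heats(protocol, Ka, dHb).sum()
    assert q.sum() == pytest.approx(oracle_total, rel=1e-8)


def test_fit_noiseless_round_trip(protocol):
    q = simulate_injection_heats(protocol, 6.6e3, -6.7, 1.0)
    f = fit_single_site(protocol, q)
    assert f.Ka.value == pytest.approx(6.6e3, rel=1e-6)
    assert f.dHb.value == pytest.approx(-6.7, rel=1e-6)
    assert f.n_sites.value == pytest.approx(1.0, rel=1e-6)


@pytest.mark.parametrize("Ka,dHb,n", [(3.5e3, -12.0, 0.9), (6.6e4, -5.0, 1.1)])
def test_fit_identity_across_c_values(protocol, Ka, dHb, n):
    q = simulate_injection_heats(protocol, Ka, dHb, n)
    f = fit_single_site(protocol, q)
    assert f.Ka.value == pytest.approx(Ka, rel=1e-5)
    assert f.dHb.value == pytest.approx(dHb, rel=1e-5)
    assert f.n_sites.value == pytest.approx(n, rel=1e-5)


def test_fit_noisy_median_ka_within_published_band(protocol):
    """2% heat noise, many seeds → median Ka inside the published 6.6±0.4 mM⁻¹."""
    clean = simulate_injection_heats(protocol, 6.6e3, -6.7)
    sd = 0.02 * float(np.max(np.abs(clean)))
    kas = []
    for seed in range(100):
        q = generate_itc_data(protocol, 6.6e3, -6.7, noise_sd=sd, seed=seed)
        kas.append(fit_single_site(protocol, q).Ka.value)
    assert 6.2e3 <= float(np.median(kas)) <= 7.0e3


def test_fit_warns_outside_c_window(protocol):
    q = simulate_injection_heats(protocol, 100.0, -6.7)  # c = 0.15
    with pytest.warns(UserWarning, match="c-value"):
        fit_single_site(protocol, q, fix_n=True)


def test_fit_input_validation(protocol):
    with pytest.raises(ValueError, match="match the protocol"):
        fit_single_site(protocol, np.zeros(10))
    short = TitrationProtocol(injection_volumes_ul=(4.0,) * 5)
    with pytest.raises(ValueError, match=">=10"):
        fit_single_site(short, np.zeros(5))


@pytest.mark.parametrize(
    "Ka, dHb, expected",  # (dGb, TdSb, dSb) at 298 K
    [
        ((6.6e3, 0.4e3), (-6.7, 0.4), (-21.8, 15.1, 51)),
        ((5.0e3, None), (-10.6, None), (-21.1, 10.5, 35)),
    ],
)
def test_binding_decompose_published_rows(Ka, dHb, expected):
    th = binding_decompose(Quantity(*Ka) if Ka[1] else Quantity(Ka[0]),
                           Quantity(*dHb) if dHb[1] else Quantity(dHb[0]))
    dGb, TdSb, dSb = expected
    assert round(th.dGb.value, 1) == dGb
    assert round(th.TdSb.value, 1) == TdSb
    assert round(th.dSb.value) == dSb


def test_binding_decompose_unit_ka_and_round_trip():
    th = binding_decompose(Quantity(1.0), Quantity(-5.0))
    assert th.dGb.value == 0.0
    assert th.TdSb.value == -5.0
    th2 = binding_decompose(Quantity(6.6e3), Quantity(-6.7))
    assert math.exp(-1000.0 * th2.dGb.value / (R * 298.0)) == pytest.approx(6.6e3, rel=1e-12)
    with pytest.raises(ValueError):
        binding_decompose(Quantity(0.0), Quantity(-5.0))


def test_binding_delta_delta_published_pairs():
    ph_wt = binding_decompose(Quantity(6.6e3, 0.4e3), Quantity(-6.7, 0.4), label="PhWT")
    ph_mut = binding_decompose(Quantity(7.5e3, 0.4e3), Quantity(-13.1, 1.0), label="PhG91A")
    d = binding_delta_delta(ph_mut, ph_wt)
    assert round(d.ddH.value, 1) == -6.4
    assert round(d.TddS.value, 1) == -6.1
    hu_g99 = binding_decompose(Quantity(5.4e3), Quantity(-7.0), label="HuG99")
    hu_a99 = binding_decompose(Quantity(5.0e3), Quantity(-10.6), label="HuA99")
    assert round(binding_delta_delta(hu_a99, hu_g99).TddS.value, 1) == -3.8
    z = binding_delta_delta(ph_wt, ph_wt)
    assert z.ddG.value == 0 and z.ddH.value == 0 and z.TddS.value == 0


def test_binding_entropy_loss_smaller_than_activation_entropy_loss():
    """The entropic cost of removing the bridge is much larger in the
    transition state than in the enzyme–substrate complex, for both the
    thermophilic and the mesophilic pair."""
    from thermoflex import presets
    from thermoflex.thermo import delta_delta, eyring_decompose
    for a, b in [("PhG91A", "PhWT"), ("HuA99", "HuG99")]:
        _, kc_a, se_a, ea_a, ease_a = presets.KINETICS[a]
        _, kc_b, se_b, ea_b, ease_b = presets.KINETICS[b]
        dk = delta_delta(
            eyring_decompose(Quantity(kc_a, se_a), Quantity(ea_a, ease_a), label=a),
            eyring_decompose(Quantity(kc_b, se_b), Quantity(ea_b, ease_b), label=b))
        Ka_a, _, dh_a, _ = presets.BINDING[a]
        Ka_b, _, dh_b, _ = presets.BINDING[b]
        db = binding_delta_delta(
            binding_decompose(Quantity(Ka_a), Quantity(dh_a), label=a),
            binding_decompose(Quantity(Ka_b), Quantity(dh_b), label=b))
        assert db.TddS.value > dk.TddS.value  # less negative
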