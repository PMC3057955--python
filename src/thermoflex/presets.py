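"""Published parameter sets for the five acylphosphatase variants.

PhWT is the thermophilic wild type (active-site Arg–C-terminal
carboxylate salt bridge present); PhG91A removes the bridge.  HuG99
introduces the bridge into the mesophilic human enzyme; HuA99 is the
bridge-free pseudo-wild-type and HuWT the K99 wild type.  Values are
the measured (kcat, Ea) at 298 K, ITC (Ka, ΔHb), and guanidine
denaturation parameters, used both as generator ground truth and as the
inputs for regenerating the derived thermodynamic tables.
"""
from __future__ import annotations

#: variant → (salt_bridge, kcat s⁻¹, kcat_se, Ea kJ/mol, Ea_se)
KINETICS = {
    "PhWT":   (True,  228.0,  15.0, 49.1, 1.4),
    "PhG91A": (False, 211.0,  25.0, 32.1, 1.7),
    "HuG99":  (True,  1405.0, 225.0, 52.5, 2.5),
    "HuA99":  (False, 1268.0, 100.0, 29.5, 1.9),
    "HuWT":   (False, 1214.0, 196.0, 37.6, 3.1),
}

#: variant → (Ka M⁻¹, Ka_se, ΔHb kJ/mol, ΔHb_se) at 298 K
BINDING = {
    "PhWT":   (6.6e3, 0.4e3, -6.7, 0.4),
    "PhG91A": (7.5e3, 0.4e3, -13.1, 1.0),
    "HuG99":  (5.4e3, 0.2e3, -7.0, 0.4),
    "HuA99":  (5.0e3, 0.6e3, -10.6, 0.8),
    "HuWT":   (5.1e3, 0.1e3, -12.1, 3.4),
}

#: variant → (ΔGu kJ/mol, se, m kJ/mol/M, se, Cm M, se) from guanidine curves
STABILITY = {
    "PhWT":   (58.0, 7.0, 10.9, 1.2, 5.30, 0.04),
    "PhG91A": (51.0, 6.0, 9.7, 1.1, 5.23, 0.05),
}

#: apparent melting temperatures (°C) from irreversible thermal unfolding;
#: carried as metadata only — no thermal-unfolding model is fitted.
APPARENT_TM_C = {"PhWT": 107.0, "PhG91A": 106.0}

#: comparison pairs (variant without the bridge, variant with it)
PAIRS = [("PhG91A", "PhWT"), ("HuA99", "HuG99"), ("HuWT", "HuG99")]

#: Michaelis constant shared by all variants over the assay range, mM
KM_MM = 0.10

#: assay temperature grids, K
TEMPERATURES_MESO = (283.0, 288.0, 293.0, 298.0, 303.0)
TEMPERATURES_THERMO = TEMPERATURES_MESO + (308.0, 313.0, 318.0)

#: temperature grid per variant (thermophilic enzymes assayed up to 318 K)
def temperatures_for(variant: str) -> tuple:
    return TEMPERATURES_THERMO if variant.startswith("Ph") else TEMPERATURES_MESO
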