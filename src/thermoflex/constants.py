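"""Physical constants (CODATA 2018) and the reference temperature.

All internal energy arithmetic is done in J mol⁻¹; public interfaces use
kJ mol⁻¹ for energies and J mol⁻¹ K⁻¹ for entropies, matching the units
conventional in enzyme-thermodynamics tables.
"""

#: Universal gas constant, J mol⁻¹ K⁻¹.
R = 8.314462618

#: Boltzmann constant, J K⁻¹.
KB = 1.380649e-23

#: Planck constant, J s.
H = 6.62607015e-34

#: Reference temperature for activation/binding thermodynamics, K.
#: 298.00 exactly (25 °C as commonly rounded in kinetics tables); using
#: 298.15 would shift ΔG# by <0.05 kJ mol⁻¹.
T_REF = 298.0
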