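"""Physical constants and package-wide defaults.

Units used throughout the package: nm (length), kJ/mol (energy),
eV (excitation energy), degrees (angles), kelvin (temperature).
"""

#: Boltzmann constant in kJ/(mol K).
KB_KJ_PER_MOL_K: float = 0.0083144626

#: Planck constant times speed of light, in eV nm (lambda = HC / E).
HC_EV_NM: float = 1239.84193

#: Default simulation temperature in kelvin.
DEFAULT_TEMPERATURE_K: float = 300.0

#: Wavenumber (cm^-1) to eV conversion factor.
CM1_TO_EV: float = 1.0 / 8065.543937
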