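"""Physical constants in spectroscopic units.

Values are CODATA-derived, truncated to the precision relevant for
X-band EPR and low-temperature MCD work.
"""

#: h / mu_B in mT per GHz: resonance condition B = (h/mu_B) * nu / g.
H_OVER_MUB_MT_GHZ = 71.44775

#: Boltzmann constant in cm^-1 per K.
KB_CM_PER_K = 0.6950348

#: Bohr magneton in cm^-1 per tesla.
MUB_CM_PER_T = 0.4668645

#: Default one-hole spin-orbit coupling constant for low-spin Fe(III)
#: in a covalent protein site, cm^-1.  Free-ion zeta_Fe3+ is ~460 cm^-1;
#: covalent reduction brings effective values into the 350-430 range.
ZETA_DEFAULT_CM = 380.0
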