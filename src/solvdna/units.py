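"""Unit conversion constants (CODATA)."""

#: 1 Angstrom in Bohr.
ANGSTROM_TO_BOHR = 1.8897261254578281
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR
#: 1 atomic unit of electric dipole moment in Debye.
AU_TO_DEBYE = 2.541746
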