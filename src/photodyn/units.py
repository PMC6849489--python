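"""Unit conversion constants.

All internal quantities are in Hartree atomic units (Hartree, Bohr,
electron mass, hbar = 1).  File I/O and user-facing interfaces use
Angstrom for lengths, femtoseconds for times and eV for energies.
"""

BOHR_PER_ANGSTROM = 1.8897261258369282
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: atomic time units per femtosecond
AU_PER_FS = 41.341373335182114
FS_PER_AU = 1.0 / AU_PER_FS

EV_PER_HARTREE = 27.211386245988
HARTREE_PER_EV = 1.0 / EV_PER_HARTREE

#: electron masses per unified atomic mass unit
ME_PER_AMU = 1822.888486209
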