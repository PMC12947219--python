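"""Physical constants and unit conversions used across the package.

All energies are kcal·mol⁻¹, all lengths Å, all charges elementary-charge
units; these constants are the only place the unit system is pinned down.
"""

#: Coulomb prefactor, kcal·Å·mol⁻¹·e⁻² (CHARMM/AMBER convention).
COULOMB_K = 332.0637

#: Hartree → kcal·mol⁻¹.
HARTREE_TO_KCAL = 627.5095

#: Pair distances below this (Å) are treated as a geometry error in the
#: classical backend — the r⁻¹² wall makes anything closer meaningless.
MIN_PAIR_DISTANCE = 0.1

#: Covalent radii (Å) used for distance-based bond perception.
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "SE": 1.20,
}

#: Tolerance factor applied to the sum of covalent radii when perceiving bonds.
BOND_TOLERANCE = 1.3
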