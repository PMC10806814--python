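"""Physical and format constants shared across the package.

All energies are kcal/mol, distances Å, angles stored in the units their
source format uses (degrees in parameter files) and converted centrally.
"""

import math

#: Coulomb's constant used by AMBER's pmemd (kcal·Å/(mol·e²)).
COULOMB_AMBER = 332.0522173

#: Coulomb's constant compiled into stock NAMD (kcal·Å/(mol·e²)).
COULOMB_NAMD = 332.0636

#: PRMTOP stores charges premultiplied by sqrt(COULOMB_AMBER) = 18.2223.
PRMTOP_CHARGE_SCALE = math.sqrt(COULOMB_AMBER)

#: Default 1-4 electrostatic divisor for AMBER force fields (SCEE).
SCEE_DEFAULT = 1.2

#: The NAMD "1-4scaling" configuration value, 1/1.2 printed to six decimals.
ELEC14_SCALING_PRINTED = 0.833333

#: Single authoritative degree→radian conversion; harmonic-angle deviations
#: between engines trace to the precision of this constant, so it lives in
#: exactly one place.
DEG2RAD = math.pi / 180.0

#: Largest integer an eight-digit PRMTOP field can represent.
PRMTOP_MAX_INT = 99_999_999
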