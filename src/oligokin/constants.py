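"""Physical constants and shared unit conventions.

Energies are in kcal/mol, concentrations in molar (1 M standard state),
temperatures in Kelvin, bimolecular rates in M^-1 s^-1 and unimolecular
rates in s^-1 throughout the package.
"""

# Gas constant, kcal/mol/K. The rounded value is the package default so that
# printed rate/K_D numbers are bit-compatible with the source parameterization;
# pass R_PRECISE to any function taking an ``R`` argument to use CODATA.
R_KCAL = 1.99e-3
R_PRECISE = 1.987e-3

# Boltzmann and Planck constants (SI), used only in the Eyring prefactor.
K_B = 1.38e-23  # J/K
PLANCK_H = 6.63e-34  # J*s

# Default temperature for kinetics, K (room temperature).
T_DEFAULT = 298.15

# Reference temperature of nearest-neighbor dG tabulations, K (37 C).
T_37 = 310.15

# Documented upper bound for four-way strand exchange between duplexes with
# 4-nt overhangs; the pathway is excluded from all reaction networks.
FOUR_WAY_EXCHANGE_UPPER_BOUND = 1.0e2  # M^-1 s^-1


def rt(T: float, R: float = R_KCAL) -> float:
    """R*T in kcal/mol."""
    return R * T
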