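"""Unit conventions and conversions.

Time is in hours, biomass in g_CDW L^-1, substrate in g L^-1 internally;
substrate measurements in mM are converted by molar mass at the boundary.
"""

MOLAR_MASS_ETHANOL = 46.069  # g mol^-1
MOLAR_MASS_GLUCOSE = 180.156  # g mol^-1

#: Default cell-dry-weight per OD600 unit (g_CDW L^-1 per OD); instrument- and
#: strain-specific, configurable wherever it is used.
OD_TO_CDW_DEFAULT = 0.25


def mm_to_gl(conc_mm: float, molar_mass: float) -> float:
    """Convert a concentration in mM to g L^-1."""
    return conc_mm * molar_mass / 1000.0


def gl_to_mm(conc_gl: float, molar_mass: float) -> float:
    """Convert a concentration in g L^-1 to mM."""
    return conc_gl * 1000.0 / molar_mass
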