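"""Unit policy for oxygen quantities.

The canonical internal oxygen unit is mol m^-3 (numerically identical to mM).
Literature values for Michaelis-Menten constants and cellular consumption
rates are commonly quoted in mg L^-1 and g s^-1; everything funnels through
the conversions here so no other module hard-codes the molar mass of O2.
"""

#: Molar mass of O2 (g mol^-1).
O2_MOLAR_MASS = 32.0


def mg_per_l_to_mol_m3(x: float) -> float:
    """Convert an O2 concentration from mg L^-1 to mol m^-3.

    1 mg L^-1 = 1 g m^-3 = (1/32) mol m^-3.
    """
    return x / O2_MOLAR_MASS


def mol_m3_to_mg_per_l(x: float) -> float:
    """Convert an O2 concentration from mol m^-3 to mg L^-1."""
    return x * O2_MOLAR_MASS


def g_per_m3_s_to_mol_m3_s(x: float) -> float:
    """Convert a volumetric O2 rate from g m^-3 s^-1 to mol m^-3 s^-1."""
    return x / O2_MOLAR_MASS
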