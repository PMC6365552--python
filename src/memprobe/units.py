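"""Unit conventions and conversion constants.

Internal units everywhere in this package: length Å, time ns, charge e,
mass amu.  Diffusion coefficients cross the API boundary in μm²/s (the
unit the field reports), so the conversions live here and nowhere else.

1 μm = 1e4 Å and 1 s = 1e9 ns, hence 1 μm²/s = 1e8 Å² / 1e9 ns = 0.1 Å²/ns.
"""

#: multiply a diffusion coefficient in μm²/s by this to get Å²/ns
A2_PER_NS_PER_UM2_PER_S = 0.1

#: e/(ε0·Å) expressed in volts: converts ∫∫ρ dz dz' (ρ in e/Å³, z in Å) to V
E_OVER_EPS0_ANGSTROM_V = 1.602176634e-19 / (8.8541878128e-12 * 1e-10)

#: 1 e·Å in Debye
DEBYE_PER_E_ANGSTROM = 1.0 / 0.2081943


def um2_per_s_to_A2_per_ns(d: float) -> float:
    """Convert a diffusion coefficient from μm²/s to Å²/ns."""
    return d * A2_PER_NS_PER_UM2_PER_S


def A2_per_ns_to_um2_per_s(d: float) -> float:
    """Convert a diffusion coefficient from Å²/ns to μm²/s."""
    return d / A2_PER_NS_PER_UM2_PER_S
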