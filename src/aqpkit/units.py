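"""Unit conversions used throughout the package.

Concentrations cross the public interfaces in the units the assays are
reported in (mOsm for osmolarity, mM for solute concentration) and are
converted to CGS amounts-per-volume exactly once, here.  1 mOsm =
1e-3 osmol/L = 1e-6 osmol/cm^3, and identically for mM.
"""

#: multiply an osmolarity in mOsm to obtain osmol/cm^3
MOSM_TO_OSMOL_PER_CM3: float = 1e-6

#: multiply a concentration in mM to obtain mol/cm^3
MM_TO_MOL_PER_CM3: float = 1e-6


def mosm_to_internal(osm_mosm: float) -> float:
    """Osmolarity, mOsm -> osmol/cm^3."""
    return osm_mosm * MOSM_TO_OSMOL_PER_CM3


def mm_to_internal(conc_mm: float) -> float:
    """Solute concentration, mM -> mol/cm^3."""
    return conc_mm * MM_TO_MOL_PER_CM3
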