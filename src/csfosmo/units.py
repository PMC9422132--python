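"""Unit conversions between reported units and the internal CGS system.

Internally the physical model works in CGS with concentrations in
osmol cm^-3.  The public API accepts and reports the units in which the
quantities are conventionally printed: µl min^-1 for flows, mOsm
(milliosmole per kg, treated as per litre at density 1.00 g ml^-1) for
osmolality, cm s^-1 Osm^-1 for osmotic water permeability.
"""

from __future__ import annotations

S_PER_MIN = 60.0
UL_PER_CM3 = 1000.0
UM_PER_CM = 1e4
MOSM_PER_OSM = 1000.0

#: universal gas constant, J mol^-1 K^-1
R_GAS = 8.314
#: 1 mmHg in Pa
PA_PER_MMHG = 133.322


def ul_min_to_cm3_s(x: float) -> float:
    return x / UL_PER_CM3 / S_PER_MIN


def cm3_s_to_ul_min(x: float) -> float:
    return x * UL_PER_CM3 * S_PER_MIN


def mosm_to_osmol_cm3(x: float) -> float:
    """mOsm (≈ mosmol/L at density 1.00 g ml^-1) → osmol cm^-3."""
    return x * 1e-3 / 1e3


def osmol_cm3_to_mosm(x: float) -> float:
    return x * 1e3 * 1e3


def lp_per_osm_to_cgs(lp: float) -> float:
    """cm s^-1 Osm^-1 → cm s^-1 per (osmol cm^-3).

    1 Osm = 1 osmol/L = 1e-3 osmol/cm^3, so the permeability per unit
    osmol cm^-3 is 1000x larger.
    """
    return lp * 1e3


def lp_cgs_to_per_osm(lp: float) -> float:
    return lp / 1e3


def um_to_cm(x: float) -> float:
    return x / UM_PER_CM


def um2_to_cm2(x: float) -> float:
    return x / UM_PER_CM**2


def cm2_to_um2(x: float) -> float:
    return x * UM_PER_CM**2
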