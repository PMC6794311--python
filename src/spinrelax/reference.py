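"""Published reference values for the myelin-sheath system.

These are literature inputs — the averaged relaxation rates, pool sizes and
membrane composition reported for a 20 ns all-atom simulation of a two-leaflet
myelin-like membrane solvated by 4699 waters — used by the arithmetic
reproduction path (effective rates, field-dependence fits, sheath average)
and as fixtures for downstream consistency checks. Rates in Hz.
"""

from __future__ import annotations

import pandas as pd

FIELDS_T = (1.5, 3.0, 7.0)

#: Averaged relaxation rates per pool and field (Hz): intrinsic (intra-pool),
#: cross- and auto-relaxation for the water pool (WP) and the macromolecular
#: pool (MP).
TABLE1 = pd.DataFrame(
    {
        "B0": [1.5, 3.0, 7.0],
        "R1_WP": [1.175, 0.978, 0.718],
        "R1_WP_cross": [0.061, 0.039, 0.016],
        "R1_WP_auto": [0.165, 0.132, 0.095],
        "R1_MP": [4.95, 3.72, 2.43],
        "R1_MP_cross": [0.042, 0.027, 0.011],
        "R1_MP_auto": [0.112, 0.090, 0.065],
    }
).set_index("B0")

#: Hydrogen counts per pool. The water pool holds 4699 H2O molecules, i.e.
#: 9398 hydrogens; a per-proton partner sum runs over the remaining 9397.
N_WP = 9398
N_WP_PARTNERS = 9397
N_MP = 13810

#: Power-law coefficients of the effective-rate field dependence
#: R1_ef(B0) = n0 * B0**n1 as printed in the source study.
PUBLISHED_POWER_LAW = {
    "WP": {"n0": 1.53, "n1": -0.31},
    "MP": {"n0": 5.98, "n1": -0.45},
}

#: Per-leaflet membrane composition (two leaflets in the full system):
#: cholesterol, DPPC, POPE, galactocerebroside, sulfatide.
LEAFLET_COMPOSITION = {
    "CHL": {"formula": "C27H46O", "count": 27},
    "DPPC": {"formula": "C40H80NO8P", "count": 23},
    "POPE": {"formula": "C39H76NO8P", "count": 23},
    "GalC": {"formula": "C40H77NO7", "count": 23},
    "GalS": {"formula": "C40H76NO11S", "count": 4},
}
N_LEAFLETS = 2
N_WATERS = 4699
N_SODIUM = 8

#: Total water->macromolecule exchange rate reported from magnetization
#: transfer experiments on white matter (Hz); its chemical-exchange part is
#: k_WP minus the dipolar cross-relaxation contribution.
K_WP_EXPERIMENTAL = 12.0


def species_pool_rule() -> dict:
    """Default species -> pool mapping: water to WP, all lipids to MP."""
    rule = {name: "MP" for name in LEAFLET_COMPOSITION}
    rule["SOL"] = "WP"
    rule["TIP4"] = "WP"
    rule["WAT"] = "WP"
    return rule


def macromolecule_hydrogen_count() -> int:
    """Hydrogens in the macromolecular pool implied by the lipid formulas."""
    from .trajectory import parse_formula

    per_leaflet = sum(parse_formula(v["formula"]).get("H", 0) * v["count"]
                      for v in LEAFLET_COMPOSITION.values())
    return N_LEAFLETS * per_leaflet
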