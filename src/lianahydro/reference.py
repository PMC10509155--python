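"""Published study-design constants for the southern temperate rainforest liana survey.

Three sites span a latitudinal cold gradient (warm north to cold south):
Nahuelbuta (37°42' S), Puyehue (40°39' S) and Aysén (45°27' S).  The climate
table and the site-level trait means/standard errors below are the published
field values; the synthetic-data generator uses them as its default targets
and the report module uses them as inputs for the derived fold-change panel.

Units
-----
AGR              cm month^-1   apical growth rate
PLC              %             percent loss of conductivity (freeze-thaw embolism)
Ks_max           kg s^-1 m^-1 MPa^-1  maximum specific hydraulic conductivity
vessel_diameter  µm
vessel_density   vessels mm^-2
wood_density     g cm^-3
root_pressure    kPa
"""

from __future__ import annotations

import pandas as pd

#: Site order along the gradient, warm (north) to cold (south).
SITES = ("Nahuelbuta", "Puyehue", "Aysen")

#: Climate table for the measurement year (DGA station records).
CLIMATE = pd.DataFrame(
    {
        "site": list(SITES),
        "annual_precip_mm": [1290.1, 3521.8, 1968.8],
        "seasonality_months": [7, 6, 2],
        "tmax_mean_C": [16.2, 14.3, 13.4],
        "tmin_mean_C": [4.8, 3.3, 2.7],
        "tmin_abs_C": [-3.2, -5.8, -7.0],
        "frost_events": [56, 81, 54],
        "frost_hours": [237, 260, 359],
    }
)

#: Mean annual temperature (°C) per site (site descriptions).
MEAN_ANNUAL_TEMP_C = {"Nahuelbuta": 16.0, "Puyehue": 10.0, "Aysen": 8.0}

#: Published site-level trait means.
TRAIT_MEANS = pd.DataFrame(
    {
        "site": list(SITES),
        "AGR": [10.6, 5.9, 2.1],
        "PLC": [25.4, 35.5, 37.5],
        "Ks_max": [28.7, 15.09, 1.1],
        "vessel_diameter": [68.8, 55.6, 21.9],
        "vessel_density": [148.04, 264.2, 1090.9],
        "wood_density": [0.38, 0.37, 0.47],
        "root_pressure": [9.9, 32.7, 13.6],
    }
).set_index("site")

#: Published standard errors of the site-level trait means.
TRAIT_SES = pd.DataFrame(
    {
        "site": list(SITES),
        "AGR": [1.2, 1.5, 2.09],
        "PLC": [4.7, 5.6, 5.2],
        "Ks_max": [2.9, 3.5, 3.9],
        "vessel_diameter": [3.5, 3.3, 3.6],
        "vessel_density": [88.1, 136.7, 174.8],
        "wood_density": [0.02, 0.026, 0.02],
        "root_pressure": [4.8, 4.6, 5.3],
    }
).set_index("site")

#: The ten liana species of the regional pool (all distinct genera).
SPECIES_POOL = (
    "Berberidopsis corallina",
    "Boquila trifoliolata",
    "Cissus striata",
    "Hydrangea serratifolia",
    "Elytropus chilensis",
    "Mitraria coccinea",
    "Campsidium valdivianum",
    "Muehlenbeckia hastulata",
    "Griselinia ruscifolia",
    "Lardizabala biternata",
)

#: Species found at each site (7 / 5 / 4; union of 10 species, 16 species-site
#: units).  The per-site species lists are not published; this assignment is
#: fixed so that the two anatomically profiled species occur at all three sites.
SPECIES_BY_SITE = {
    "Nahuelbuta": [
        "Berberidopsis corallina",
        "Boquila trifoliolata",
        "Cissus striata",
        "Hydrangea serratifolia",
        "Elytropus chilensis",
        "Mitraria coccinea",
        "Lardizabala biternata",
    ],
    "Puyehue": [
        "Boquila trifoliolata",
        "Hydrangea serratifolia",
        "Mitraria coccinea",
        "Campsidium valdivianum",
        "Muehlenbeckia hastulata",
    ],
    "Aysen": [
        "Hydrangea serratifolia",
        "Mitraria coccinea",
        "Campsidium valdivianum",
        "Griselinia ruscifolia",
    ],
}

TRAITS = tuple(TRAIT_MEANS.columns)
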