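"""Published survey fixtures: effort accounting and density-estimation inputs.

These tables transcribe the survey's printed accounting so the downstream
arithmetic (column sums, encounter rates, density means, population
extrapolation) can be recomputed and checked. Values that cannot be derived
from deposited inputs — the per-speed densities and their standard errors,
the MaxEnt habitat areas, the overlap ratios and the ANOVA F statistics —
are carried as fixture data and are marked as such wherever reported.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "survey_effort_table",
    "density_input_table",
    "fixture_tables",
    "DISTRIBUTION_AREA_KM2",
    "OPTIMAL_HABITAT_KM2",
    "GROUP_COMPOSITION_COUNTS",
    "DAY_IPS",
    "SPECIES",
]

SPECIES = ("B. taxicolor", "B. whitei")

#: MaxEnt distribution-range areas (index >= 0.5), km^2 — fixture values.
DISTRIBUTION_AREA_KM2 = {"B. taxicolor": 17_314.0, "B. whitei": 25_006.0}

#: MaxEnt highly-suitable areas (index >= 0.7), km^2 — fixture values.
OPTIMAL_HABITAT_KM2 = {"B. taxicolor": 2404.0, "B. whitei": 4156.0}

#: One fully scanned family group of 47 animals, by age/sex class.
GROUP_COMPOSITION_COUNTS = {
    "adult_male": 1,
    "adult_female": 26,
    "juvenile": 9,
    "subadult": 11,
}

#: Daytime independent photographs: totals for the morphology subset and the
#: species split of the recognizable daytime set.
DAY_IPS = {
    "total_ips": 1210,
    "day_ips": 540,
    "recognizable_day_ips": 3365,
    "day_by_species": {"B. taxicolor": 1123, "B. whitei": 2242},
}

_EFFORT_ROWS = [
    # area, stations, elev_lo, elev_hi, camera_days, photographs, ips_taxicolor, ips_whitei
    ("Bixiri Area", 11, 2235, 3479, 2794, 12_294, 832, 0),
    ("Nibi Area", 13, 2256, 3509, 2354, 13_892, 0, 648),
    ("South Bank of the Yarlung Zangbo River Area", 10, 582, 668, 1880, 16_751, 0, 0),
    ("Uma Mountain Area", 6, 1751, 3145, 1374, 6942, 3, 0),
    ("Raj Mountain Area", 8, 1631, 2086, 1968, 8467, 0, 0),
    ("DanGeZhuo Area", 3, 954, 1434, 630, 684, 0, 0),
    ("GeDang Ditch Area", 36, 2230, 4470, 8691, 10_713, 843, 0),
    ("MeiYuLunBa Area", 2, 1751, 2315, 294, 5172, 0, 0),
    ("XiGong River Area", 6, 1124, 1590, 1080, 6532, 0, 0),
    ("DeYang Ditch Area", 8, 815, 1294, 1360, 6359, 7, 0),
    ("North of the Grand Canyon", 31, 3650, 4700, 5580, 4578, 0, 2504),
    ("DeErGong Area", 80, 1750, 2890, 30_500, 11_980, 0, 0),
]

_DENSITY_ROWS = [
    # species, ips, camera_days, printed per-speed densities D1 (v=5) and
    # D2 (v=10), printed SE of the mean density; D and SE columns are fixture
    # data (not derivable from the stated geometry), the rest is recomputed.
    ("B. taxicolor", 1685, 1238, 0.1738, 0.1720, 0.0134),
    ("B. whitei", 3152, 1594, 0.1429, 0.1289, 0.0264),
]


def survey_effort_table() -> pd.DataFrame:
    """Per-area survey effort and independent-photograph counts (12 areas)."""
    return pd.DataFrame(
        _EFFORT_ROWS,
        columns=[
            "survey_area",
            "n_stations",
            "elevation_min",
            "elevation_max",
            "camera_days",
            "n_photographs",
            "ips_B. taxicolor",
            "ips_B. whitei",
        ],
    ).set_index("survey_area")


def density_input_table() -> pd.DataFrame:
    """Density-estimation inputs and the printed per-speed densities / SEs."""
    return pd.DataFrame(
        _DENSITY_ROWS,
        columns=["species", "ips", "camera_days", "d1", "d2", "se_printed"],
    ).set_index("species")


def fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both packaged tables: (survey effort, density inputs)."""
    return survey_effort_table(), density_input_table()
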