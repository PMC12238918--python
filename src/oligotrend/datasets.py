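"""Bundled reference data for nine Scandinavian mountain lakes.

Per-lake, two-period area-specific P and N sequestration densities
(ton·km⁻², period means with their within-period SDs), plus the region
constants used for upscaling.  These serve as a worked example for the
summary/upscaling chain and as regression fixtures.
"""

from __future__ import annotations

__all__ = [
    "LAKE_PERIOD_DENSITIES",
    "REGION_KM2",
    "TUNDRA_KM2",
    "TUNDRA_SHARE",
    "MID_INTERVAL_YEARS",
    "PERIOD_A",
    "PERIOD_B",
    "TOTAL_P_DECLINES",
    "per_lake_diffs",
]

PERIOD_A = (1983, 1994)
PERIOD_B = (2001, 2020)

REGION_KM2 = 46_528.0      # Arctic/alpine ecoregion, Sweden
TUNDRA_KM2 = 33_935.0      # tundra-vegetation share of the ecoregion
TUNDRA_SHARE = 0.73
MID_INTERVAL_YEARS = 22.5  # span between the two period midpoints

# lake -> nutrient -> (mean_a, sd_a, mean_b, sd_b) in ton/km²;
# Abiskojaure's first period is 1983-1992 (early NDVI rise).
LAKE_PERIOD_DENSITIES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "Latnjajaure": {
        "P": (0.88, 0.09, 1.17, 0.06),
        "N": (11.24, 0.86, 14.17, 0.58),
    },
    "Abiskojaure": {
        "P": (0.74, 0.06, 0.96, 0.02),
        "N": (9.80, 0.63, 12.05, 0.20),
    },
    "Batkajaure": {
        "P": (1.16, 0.05, 1.30, 0.04),
        "N": (14.13, 0.55, 15.51, 0.35),
    },
    "Njalakjaure": {
        "P": (0.46, 0.07, 0.96, 0.07),
        "N": (6.93, 0.71, 12.05, 0.75),
    },
    "Louvvajaure": {
        "P": (1.07, 0.03, 1.42, 0.02),
        "N": (13.22, 0.26, 16.75, 0.15),
    },
    "Stor-Tjultrasket": {
        "P": (1.22, 0.05, 1.43, 0.02),
        "N": (14.73, 0.48, 16.89, 0.18),
    },
    "Dunnervattnet": {
        "P": (1.37, 0.03, 1.61, 0.02),
        "N": (16.23, 0.32, 18.68, 0.20),
    },
    "Stor-Bjorsjon": {
        "P": (1.34, 0.03, 1.50, 0.02),
        "N": (15.95, 0.26, 17.63, 0.16),
    },
    "Ovre-Fjatsjon": {
        "P": (1.14, 0.03, 1.36, 0.03),
        "N": (13.93, 0.30, 16.14, 0.29),
    },
}

# lake -> (c_start μg/L, c_end μg/L, year_start, year_end) for the
# endpoint-based Total-P percent-decline examples
TOTAL_P_DECLINES: dict[str, tuple[float, float, int, int]] = {
    "Njalakjaure": (5.3, 1.2, 1996, 2020),
    "Stor-Tjultrasket": (8.5, 1.8, 1989, 2020),
}


def per_lake_diffs(nutrient: str) -> list[float]:
    """Second-period minus first-period density per lake (ton·km⁻²)."""
    return [
        round(v[nutrient][2] - v[nutrient][0], 10)
        for v in LAKE_PERIOD_DENSITIES.values()
    ]
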