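"""Published reference tables for the 2020-2021 Thai three-site PM2.5 campaign.

Site-level statistics of 25 PM2.5-bound elements measured at the Chiang-Mai
(COS), Bangkok (BOS) and Phuket (POS) air-quality observatories, together
with the crustal-composition and exposure/toxicity defaults the downstream
stages consume.  Concentrations are stored in the units the campaign
reported (``ug/m3`` for the major elements, ``ng/m3`` for trace elements);
``None`` marks a not-detected minimum.
"""

from __future__ import annotations

ELEMENTS: tuple[str, ...] = (
    "Na", "Mg", "Al", "Si", "S", "Cl", "K", "Ca", "Sc", "Ti", "V", "Cr",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "As", "Se", "Br", "Sr",
    "Ba", "Pb",
)

#: native reporting unit per element
NATIVE_UNITS: dict[str, str] = {
    **{e: "ng/m3" for e in ELEMENTS},
    **{e: "ug/m3" for e in ("Na", "Mg", "Al", "Si", "S", "Cl", "K", "Ca", "Fe")},
}

SITES: tuple[str, ...] = ("COS", "BOS", "POS")

SITE_N: dict[str, int] = {"COS": 82, "BOS": 48, "POS": 61}

# Per element: {site: (mean, sd, min, max)} in the element's native unit.
# A ``None`` minimum means the element fell below the detection limit in at
# least one sample at that site.
SITE_STATISTICS: dict[str, dict[str, tuple]] = {
    "Na": {"COS": (17.0, 0.930, 15.3, 19.4), "BOS": (25.6, 1.34, 20.2, 28.1), "POS": (17.0, 0.844, 15.5, 19.1)},
    "Mg": {"COS": (17.0, 0.647, 15.8, 18.6), "BOS": (25.3, 0.941, 21.2, 27.1), "POS": (16.9, 0.538, 15.9, 18.2)},
    "Al": {"COS": (64.4, 11.2, 49.8, 91.7), "BOS": (93.7, 16.9, 60.0, 133.0), "POS": (63.2, 9.11, 51.4, 87.6)},
    "Si": {"COS": (596.0, 45.5, 505.0, 692.0), "BOS": (865.0, 64.7, 611.0, 1003.0), "POS": (605.0, 43.1, 529.0, 689.0)},
    "S": {"COS": (1.24, 1.22, 0.138, 7.61), "BOS": (4.69, 2.33, 0.949, 11.9), "POS": (0.541, 0.459, 0.112, 2.54)},
    "Cl": {"COS": (0.738, 0.113, 0.549, 1.11), "BOS": (1.17, 0.310, 0.862, 2.39), "POS": (0.671, 0.191, 0.517, 1.65)},
    "K": {"COS": (3.92, 2.30, 1.86, 12.1), "BOS": (9.80, 4.37, 3.25, 19.4), "POS": (2.09, 0.489, 1.80, 4.73)},
    "Ca": {"COS": (16.4, 1.03, 14.8, 21.1), "BOS": (25.2, 1.63, 22.3, 30.2), "POS": (15.5, 0.285, 14.9, 16.2)},
    "Sc": {"COS": (251.0, 11.0, 225.0, 279.0), "BOS": (365.0, 21.4, 318.0, 409.0), "POS": (247.0, 9.05, 228.0, 270.0)},
    "Ti": {"COS": (210.0, 62.2, 157.0, 533.0), "BOS": (354.0, 75.0, 270.0, 621.0), "POS": (179.0, 15.3, 161.0, 244.0)},
    "V": {"COS": (9.59, 2.65, 3.21, 16.1), "BOS": (18.1, 5.92, 4.82, 33.7), "POS": (9.79, 2.45, 3.21, 16.1)},
    "Cr": {"COS": (47.2, 31.0, 25.7, 318.0), "BOS": (84.9, 19.9, 62.6, 164.0), "POS": (48.1, 7.60, 38.5, 80.3)},
    "Mn": {"COS": (84.5, 27.6, 54.6, 209.0), "BOS": (171.0, 41.4, 106.0, 332.0), "POS": (72.0, 16.1, 54.6, 128.0)},
    "Fe": {"COS": (1.43, 0.634, 0.902, 4.63), "BOS": (2.95, 0.927, 1.73, 6.71), "POS": (1.00, 0.166, 0.809, 1.73)},
    "Co": {"COS": (46.2, 3.63, 38.5, 57.8), "BOS": (67.4, 6.52, 43.4, 77.1), "POS": (46.9, 3.49, 38.5, 54.6)},
    "Ni": {"COS": (85.7, 8.56, 70.6, 116.0), "BOS": (100.0, 46.1, 48.2, 193.0), "POS": (29.6, 5.70, 22.5, 61.0)},
    "Cu": {"COS": (77.0, 95.1, 32.1, 639.0), "BOS": (156.0, 133.0, 81.9, 925.0), "POS": (68.4, 45.3, 35.3, 382.0)},
    "Zn": {"COS": (226.0, 114.0, 116.0, 665.0), "BOS": (896.0, 366.0, 332.0, 1941.0), "POS": (190.0, 58.7, 138.0, 485.0)},
    "Ga": {"COS": (17.3, 2.65, 12.8, 25.7), "BOS": (27.4, 4.57, 19.3, 38.5), "POS": (17.2, 2.12, 12.8, 22.5)},
    "As": {"COS": (9.95, 5.14, None, 22.5), "BOS": (28.4, 16.2, None, 86.7), "POS": (8.16, 6.95, None, 45.0)},
    "Se": {"COS": (3.84, 1.28, 3.21, 6.42), "BOS": (16.3, 11.7, 4.82, 62.6), "POS": (3.63, 1.49, 3.21, 12.8)},
    "Br": {"COS": (34.9, 34.2, 3.21, 138.0), "BOS": (104.0, 63.6, 14.5, 270.0), "POS": (14.7, 13.8, 3.21, 89.9)},
    "Sr": {"COS": (135.0, 8.35, 116.0, 170.0), "BOS": (212.0, 16.0, 183.0, 260.0), "POS": (137.0, 5.23, 125.0, 151.0)},
    "Ba": {"COS": (99.3, 12.7, 61.0, 141.0), "BOS": (169.0, 16.5, 140.0, 217.0), "POS": (108.0, 11.2, 86.7, 148.0)},
    "Pb": {"COS": (65.8, 28.6, 28.9, 180.0), "BOS": (165.0, 93.7, 62.6, 530.0), "POS": (41.9, 11.6, 22.5, 109.0)},
}

# Sampling seasonality (number of 72-h samples per season bin).  Bangkok has
# no July-October samples because of the COVID-19 access restrictions there.
SITE_SEASON_N: dict[str, dict[str, int]] = {
    "COS": {"March-June": 22, "July-October": 31, "November-February": 29},
    "BOS": {"March-June": 24, "July-October": 0, "November-February": 24},
    "POS": {"March-June": 30, "July-October": 13, "November-February": 18},
}

# ---------------------------------------------------------------------------
# Crustal composition (upper continental crust, mass fraction %)
# ---------------------------------------------------------------------------

#: CRC-handbook style crustal abundances; Fe/Al = 5.63/8.23 = 0.68.
CRUSTAL_CRC: dict[str, float] = {
    "O": 46.1, "Si": 28.2, "Al": 8.23, "Fe": 5.63, "Ca": 4.15, "Na": 2.36,
    "Mg": 2.33, "K": 2.09, "Ti": 0.565, "Mn": 0.095, "Ba": 0.0425,
    "Sr": 0.037, "S": 0.035, "Cl": 0.0145, "V": 0.012, "Cr": 0.0102,
    "Ni": 0.0084, "Zn": 0.0070, "Cu": 0.0060, "Co": 0.0025, "Sc": 0.0022,
    "Ga": 0.0019, "Pb": 0.0014, "Br": 0.00024, "As": 0.00018,
    "Se": 0.000005,
}

#: Default table for enrichment factors: same composition but with the
#: Fe/Al mass ratio of 0.33 adopted by the Thai source-apportionment
#: literature (Fe = 0.33 * 8.23 = 2.72%).
CRUSTAL_FE_AL_033: dict[str, float] = {**CRUSTAL_CRC, "Fe": 0.33 * 8.23}

# ---------------------------------------------------------------------------
# Inhalation-exposure and toxicity defaults
# ---------------------------------------------------------------------------

# Exposure factors per age group.  IR m3/day, ED years, EFreq days/year,
# BW kg, averaging times in days (AT_nc = ED*365 for non-carcinogens,
# AT_c = 70*365, a lifetime, for carcinogens).  The campaign's published
# hazard-quotient and cancer-risk tables are reproduced by this set; see
# docs/methods.md for how the values were constrained.
EXPOSURE_DEFAULTS: dict[str, dict[str, float]] = {
    "adolescent": {"IR": 18.0, "ED": 6.0, "EFreq": 350.0, "BW": 43.39,
                   "AT_nc": 6.0 * 365.0, "AT_c": 70.0 * 365.0},
    "adult": {"IR": 18.0, "ED": 24.0, "EFreq": 350.0, "BW": 80.0,
              "AT_nc": 24.0 * 365.0, "AT_c": 70.0 * 365.0},
}

#: Reference doses, ng/kg/day, for the six non-carcinogenic target elements.
RFD_DEFAULTS: dict[str, float] = {
    "Co": 2.01e5,
    "Ni": 200.5,
    "Cu": 4.02e4,
    "Zn": 3.01e5,
    "As": 50.2,
    "Pb": 3520.0,
}

#: Inhalation unit risks, (ug/m3)^-1, for the three carcinogenic elements
#: (EPA IRIS values).
IUR_DEFAULTS: dict[str, float] = {
    "Ni": 2.4e-4,
    "As": 4.3e-3,
    "Pb": 1.2e-5,
}
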