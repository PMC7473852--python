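"""Published global mangrove typology figures used as numeric fixtures.

These are the printed area and model-size figures from the upstream global
typology dataset release. They serve as inputs for arithmetic consistency
checks (type shares, row sums, change rates, degrees of freedom); nothing
here is produced by this package.
"""

#: km² by region and type, 2016 extent
AREAS_2016 = {
    "Australia and New Zealand": {
        "deltaic": 213,
        "estuarine": 5772,
        "lagoonal": 335,
        "open_coast": 3661,
    },
    "East and Southern Africa": {
        "deltaic": 2485,
        "estuarine": 3278,
        "lagoonal": 441,
        "open_coast": 1071,
    },
    "East Asia": {"deltaic": 1, "estuarine": 130, "lagoonal": 1, "open_coast": 27},
    "Middle East": {"deltaic": 12, "estuarine": 0, "lagoonal": 84, "open_coast": 222},
    "North and Central America and the Caribbean": {
        "deltaic": 1950,
        "estuarine": 2663,
        "lagoonal": 11905,
        "open_coast": 4433,
    },
    "Pacific Islands": {
        "deltaic": 2598,
        "estuarine": 695,
        "lagoonal": 334,
        "open_coast": 2674,
    },
    "South America": {
        "deltaic": 12963,
        "estuarine": 3154,
        "lagoonal": 809,
        "open_coast": 2016,
    },
    "South Asia": {
        "deltaic": 7041,
        "estuarine": 516,
        "lagoonal": 212,
        "open_coast": 645,
    },
    "Southeast Asia": {
        "deltaic": 16533,
        "estuarine": 13522,
        "lagoonal": 588,
        "open_coast": 13124,
    },
    "West and Central Africa": {
        "deltaic": 11176,
        "estuarine": 7680,
        "lagoonal": 285,
        "open_coast": 618,
    },
}

#: km² by super-region (ocean basin aggregates), 2016 extent
BASIN_AREAS_2016 = {
    "Atlantic East Pacific": {
        "deltaic": 26089,
        "estuarine": 13497,
        "lagoonal": 12999,
        "open_coast": 7068,
        "total": 59653,
    },
    "Indo West Pacific": {
        "deltaic": 28883,
        "estuarine": 23914,
        "lagoonal": 1994,
        "open_coast": 21425,
        "total": 76217,
    },
}

#: km² global per-type totals, 2016 extent
TYPE_TOTALS_2016 = {
    "deltaic": 54972,
    "estuarine": 37411,
    "lagoonal": 14993,
    "open_coast": 28493,
}

GLOBAL_TOTAL_2016 = 135870  # printed grand total; type totals sum to 135,869
GLOBAL_TOTAL_1996 = 141945

#: printed per-region 2016 totals (regional cells carry rounding, so most
#: rows differ from their cell sums by ±1 km²; Southeast Asia is exact)
REGION_TOTALS_2016 = {
    "Australia and New Zealand": 9982,
    "East and Southern Africa": 7275,
    "East Asia": 158,
    "Middle East": 318,
    "North and Central America and the Caribbean": 20951,
    "Pacific Islands": 6302,
    "South America": 18942,
    "South Asia": 8414,
    "Southeast Asia": 43767,
    "West and Central Africa": 19760,
}

#: km² of the multi-epoch maximal extent and its carbonate share
MAXIMAL_EXTENT_KM2 = 145595
CARBONATE_IN_MAXIMAL_KM2 = 14657

#: per-type unit counts entering the published AGB model
AGB_GROUP_COUNTS = {
    "deltaic": 84,
    "estuarine": 907,
    "lagoonal": 591,
    "open_coast": 2193,
}

#: published per-type mean AGB (Mg/ha) and SD across units
AGB_MEANS = {
    "deltaic": 117.3,
    "estuarine": 126.3,
    "lagoonal": 73.5,
    "open_coast": 111.5,
}
AGB_SDS = {"deltaic": 73.6, "estuarine": 76.3, "lagoonal": 59.8, "open_coast": 73.7}

#: published largest single-unit loss over the study period (km²)
TOP_UNIT_LOSS_KM2 = 316.2

#: published lagoonal change over the study period (%)
LAGOONAL_CHANGE_PCT = -6.9
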