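"""Published national reference figures for Indonesia, 2001-2019.

Summary statistics printed by the national-scale oil-palm mapping
assessment this pipeline operationalizes: regional forest loss and
conversion totals, 2019 mapped plantation extents, the accuracy metrics of
the 2019 map, and the State-Forest-Zone overlap. They serve as worked-
example inputs and cross-checks — pushing them through the package's
estimators reproduces the assessment's derived quantities (shares,
adjusted areas, splits). All areas in hectares unless suffixed ``_mha``;
accuracies as proportions.
"""

from __future__ import annotations

YEARS = (2001, 2019)
N_YEARS = 19

#: forest loss 2001-2019 by region (ha); Bali & Nusa Tenggara from the
#: regional footnote; regions sum exactly to the national total
REGIONAL_FOREST_LOSS_HA = {
    "Sumatra": 4_075_312,
    "Kalimantan": 4_023_971,
    "Papua": 748_640,
    "Sulawesi": 715_737,
    "Java & Maluku": 213_487,
    "Bali & Nusa Tenggara": 12_301,
}

NATIONAL_FOREST_LOSS_HA = 9_789_448

#: national conversion totals (ha)
FOREST_CONVERTED_TO_OILPALM_HA = 3_094_882
RAPID_CONVERSION_HA = 2_849_796
RAPID_CONVERSION_INDUSTRIAL_HA = 2_129_301
RAPID_CONVERSION_SMALLHOLDER_HA = 720_495

#: 2019 mapped plantation extents (ha)
MAPPED_INDUSTRIAL_HA = 10_316_986
MAPPED_SMALLHOLDER_HA = 5_920_061

#: oil palm inside the State Forest Zone, where it is prohibited (Mha)
FOREST_ZONE_OILPALM_MHA = 3.13

#: accuracy of the 2019 map (proportions), from the stratified assessment
#: of 3,440 reference sites (635 industrial / 398 smallholder / 2,407 other)
SAMPLE_SIZES = {"industrial": 635, "smallholder": 398, "other": 2407}
UA = {"industrial": 0.953, "smallholder": 0.874, "other": 0.961}
PA = {"industrial": 0.917, "smallholder": 0.639, "other": 0.990}
OVERALL_ACCURACY = 0.956
KAPPA = 0.85

#: published adjusted (omission-corrected) 2019 extents (Mha)
ADJUSTED_INDUSTRIAL_MHA = 10.72
ADJUSTED_SMALLHOLDER_MHA = 8.11
ADJUSTED_TOTAL_MHA = 18.83
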