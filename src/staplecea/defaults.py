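"""Bundled reference scenario: matched cohorts of manual (MCS) versus powered
(ECPS) circular staplers in left-sided colorectal anastomosis.

The scenario encodes a 330-patient matched comparison (165 per arm) from a
Spanish tertiary public hospital, priced at 2021 regional tariffs: arm-specific
anastomotic-leak rates and severity grades, definitive-stoma counts, and a
per-resource direct-cost ledger (unit price, arm totals, per-patient mean +- SD
in euros).  These constants are the calibration targets of the synthetic cohort
generator and the inputs of the reference decision tree; they are data, not
computed results.

Internal-consistency caveats of the ledger are documented in docs/methods.md
(three rows have means that disagree with total/n; the generator follows the
mean +- SD column, except the ICU row where the mean is reconstructed from the
total).
"""

from __future__ import annotations

ARMS = ("MCS", "ECPS")

#: matched patients per arm
ARM_N = 165

#: resource keys, in ledger order; `circular_stapler` is priced per device arm
RESOURCES = (
    "blood_test",
    "microbiological_study",
    "abdominal_xray",
    "gastrografin_enema",
    "ultrasonography",
    "ct_scan",
    "interventional_radiology",
    "operative_time_min",
    "circular_stapler",
    "blood_transfusion",
    "icu_days",
    "hospital_days",
    "medical_consultation",
    "stomatherapy_consultation",
    "ostomy_device_months",
)

#: unit prices in euros (stapler priced by arm below)
UNIT_PRICES = {
    "blood_test": 16.0,
    "microbiological_study": 40.0,
    "abdominal_xray": 25.67,
    "gastrografin_enema": 119.0,
    "ultrasonography": 65.98,
    "ct_scan": 182.61,
    "interventional_radiology": 1796.13,
    "operative_time_min": 15.0,
    "blood_transfusion": 94.86,
    "icu_days": 1365.29,
    "hospital_days": 341.0,
    "medical_consultation": 40.2,
    "stomatherapy_consultation": 30.3,
    "ostomy_device_months": 200.0,  # per month of stoma carriage
}

STAPLER_PRICES = {"MCS": 425.0, "ECPS": 553.0}

#: anastomotic-leak events per arm (denominator ARM_N)
LEAK_EVENTS = {"MCS": 22, "ECPS": 8}
#: leaks requiring reoperation (grade C); remainder managed conservatively (A|B)
GRADE_C_EVENTS = {"MCS": 15, "ECPS": 8}
#: definitive (permanent) stomas per arm, marginal counts
STOMA_TOTAL = {"MCS": 11, "ECPS": 5}
#: default apportionment of the marginal stoma counts (see docs/methods.md)
STOMA_AFTER_GRADE_C = {"MCS": 9, "ECPS": 4}
STOMA_WITHOUT_LEAK = {"MCS": 2, "ECPS": 1}

#: per-resource per-arm (mean, SD) of per-patient cost in euros
COST_MOMENTS = {
    "blood_test": {"MCS": (94.84, 176.30), "ECPS": (69.33, 93.97)},
    "microbiological_study": {"MCS": (67.88, 266.59), "ECPS": (19.88, 80.44)},
    "abdominal_xray": {"MCS": (51.81, 188.32), "ECPS": (5.67, 112.68)},
    "gastrografin_enema": {"MCS": (7.93, 29.77), "ECPS": (5.77, 25.64)},
    "ultrasonography": {"MCS": (31.19, 76.96), "ECPS": (18.79, 61.74)},
    "ct_scan": {"MCS": (87.50, 213.14), "ECPS": (52.05, 170.98)},
    "interventional_radiology": {"MCS": (152.39, 803.34), "ECPS": (54.42, 367.01)},
    "operative_time_min": {"MCS": (1291.88, 466.80), "ECPS": (1208.00, 466.80)},
    "blood_transfusion": {"MCS": (79.91, 566.84), "ECPS": (21.27, 83.38)},
    # ECPS ICU mean reconstructed as total/n = 15,018.19/165
    "icu_days": {"MCS": (670.23, 5269.79), "ECPS": (91.02, 854.66)},
    "hospital_days": {"MCS": (4127.13, 6182.39), "ECPS": (2986.33, 3308.29)},
    "medical_consultation": {"MCS": (161.04, 54.64), "ECPS": (155.68, 48.66)},
    "stomatherapy_consultation": {"MCS": (32.51, 76.45), "ECPS": (27.91, 76.45)},
    "ostomy_device_months": {"MCS": (1013.33, 6891.57), "ECPS": (180.61, 529.25)},
}

#: per-resource per-arm cost totals in euros (ledger "Total cost" columns)
RESOURCE_TOTALS = {
    "blood_test": {"MCS": 15_648.0, "ECPS": 11_140.0},
    "microbiological_study": {"MCS": 11_200.0, "ECPS": 3_280.0},
    "abdominal_xray": {"MCS": 8_548.11, "ECPS": 4_235.55},
    "gastrografin_enema": {"MCS": 1_309.0, "ECPS": 952.0},
    "ultrasonography": {"MCS": 5_146.44, "ECPS": 3_101.06},
    "ct_scan": {"MCS": 14_434.09, "ECPS": 8_587.37},
    "interventional_radiology": {"MCS": 25_144.0, "ECPS": 8_980.0},
    "operative_time_min": {"MCS": 213_159.86, "ECPS": 199_362.97},
    "circular_stapler": {"MCS": 75_737.0, "ECPS": 93_457.0},
    "blood_transfusion": {"MCS": 13_185.54, "ECPS": 3_509.82},
    "icu_days": {"MCS": 110_588.49, "ECPS": 15_018.19},
    "hospital_days": {"MCS": 680_977.0, "ECPS": 492_745.0},
    "medical_consultation": {"MCS": 26_571.3, "ECPS": 25_686.8},
    "stomatherapy_consultation": {"MCS": 7_919.2, "ECPS": 4_605.6},
    "ostomy_device_months": {"MCS": 92_400.0, "ECPS": 29_800.0},
}

#: overall per-patient direct cost: mean and SD per arm
GROUP_MEAN_COST = {"MCS": 9700.12, "ECPS": 6238.38}
GROUP_SD_COST = {"MCS": 19_446.45, "ECPS": 5_649.2}

#: average direct cost among patients who experienced an anastomotic leak
#: (pooled over arms) -- the generator's calibration constant
LEAK_MEAN_COST = 30_649.0

#: strategy effectiveness figures of the reference evaluation (proportion of
#: patients free of anastomotic complications); external inputs of the
#: reference ICER, not derivable from the stoma counts above
REFERENCE_EFFECTIVENESS = {"MCS": 0.9369, "ECPS": 0.9827}

#: relative leak-excess weights e_r used to split marginal cost moments into
#: leak / no-leak strata (rho_r = 1 + s * e_r; s solved against
#: LEAK_MEAN_COST).  Larger weight = resource consumed disproportionately by
#: leak patients.  The stapler is excluded (point mass at the unit price).
LEAK_EXCESS_WEIGHT = {
    "blood_test": 3.0,
    "microbiological_study": 8.0,
    "abdominal_xray": 6.0,
    "gastrografin_enema": 8.0,
    "ultrasonography": 4.0,
    "ct_scan": 6.0,
    "interventional_radiology": 10.0,
    "operative_time_min": 0.5,
    "blood_transfusion": 6.0,
    "icu_days": 12.0,
    "hospital_days": 6.0,
    "medical_consultation": 2.0,
    "stomatherapy_consultation": 6.0,
    "ostomy_device_months": 8.0,
}
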