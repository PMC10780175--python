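"""Reported benchmark values from the 84-B10 preclinical program.

These printed values — the observed rat and mouse NCA parameters, the
platform-predicted counterparts, the human exposure predictions and the
study dosing/sampling design — are the package's validation anchors: the
calibration targets, validation tables and acceptance checks are computed
against them.  They are data (inputs), not outputs of this package.
"""

from __future__ import annotations

#: Rat plasma sampling schedule (h) after intraperitoneal dosing.
RAT_SAMPLING_TIMES = (0.033, 0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)

#: Doses and schedules used across the study arms.
DOSES = {
    "rat_ip_mg_kg": 0.36,
    "mouse_ip_mg_kg": 5.0,
    "human_iv_mg_kg": 0.41,
    "human_interval_h": 8.0,
}

#: Observed rat NCA after 0.36 mg/kg IP (mean +/- SD, pooled sexes, n = 6);
#: the male/female rows are carried as fixtures only — no statistics are
#: computed on them here.
RAT_OBSERVED_NCA = {
    "t_half_h": (0.44, 0.03),
    "cl_ml_h_kg": (1329.0, 239.0),
    "tmax_h": (0.17, 0.09),
    "cmax_ng_ml": (257.0, 42.4),
    "auc_0_t_h_ng_ml": (269.0, 47.3),
    "auc_0_inf_h_ng_ml": (278.0, 48.9),
}

RAT_OBSERVED_NCA_BY_SEX = {
    "male": {
        "t_half_h": (0.45, 0.02), "cl_ml_h_kg": (1149.0, 119.0),
        "tmax_h": (0.19, 0.10), "cmax_ng_ml": (284.0, 48.2),
        "auc_0_t_h_ng_ml": (305.0, 30.2), "auc_0_inf_h_ng_ml": (315.0, 31.0),
    },
    "female": {
        "t_half_h": (0.43, 0.04), "cl_ml_h_kg": (1509.0, 177.0),
        "tmax_h": (0.14, 0.10), "cmax_ng_ml": (231.0, 2.08),
        "auc_0_t_h_ng_ml": (233.0, 27.0), "auc_0_inf_h_ng_ml": (241.0, 29.0),
    },
}

#: Observed vs platform-predicted PK parameters, (observed, predicted).
OBSERVED_PREDICTED = {
    "mouse": {
        "cmax_ng_ml": (2038.0, 3464.0),
        "auc_0_t_h_ng_ml": (1327.0, 1599.0),
        "vd_l_kg": (11.20, 12.96),
        "cl_ml_min_kg": (56.8, 47.5),
    },
    "rat": {
        "cmax_ng_ml": (257.0, 615.0),
        "auc_0_t_h_ng_ml": (269.0, 260.0),
        "vd_l_kg": (4.13, 4.50),
        "cl_ml_min_kg": (22.2, 19.7),
    },
}

#: Platform-predicted human exposures after 0.41 mg/kg IV (single dose and
#: q8h multiple dosing) in healthy adults and severe-CKD patients.
HUMAN_PREDICTIONS = {
    "healthy": {
        "plasma_cmax_ng_ml": 2735.0,
        "plasma_cmax_ss_ng_ml": 997.0,
        "kidney_cmax_ng_ml": 16888.0,
        "kidney_cmax_ss_ng_ml": 17010.0,
        "t_half_h": 7.88,
    },
    "ckd": {
        "plasma_cmax_ng_ml": 3250.0,
        "plasma_cmax_ss_ng_ml": 1360.0,
        "kidney_cmax_ng_ml": 7787.0,
        "kidney_cmax_ss_ng_ml": 8773.0,
        "t_half_h": 8.31,
    },
}

#: Renal efficacy anchor: kidney concentration stays at or above the LONP1
#: binding-affinity level (~150 ng/mL) until about 17 h post dose in CKD.
KIDNEY_EFFICACY_THRESHOLD_NG_ML = 150.0
KIDNEY_EFFICACY_DURATION_H = 17.0
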