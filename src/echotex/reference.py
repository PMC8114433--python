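"""Published reference values for the 90-patient CKD cohort this pipeline models.

These constants serve two purposes: the Spearman grid is the packaged
fixture behind the ``reproduce`` command (the Fisher-z averaging of the
published feature-by-test correlations is the one desk-checkable output
of the whole analysis), and the cohort summary statistics parameterize
the synthetic cohort generator's defaults.

Values are printed report numbers for a real patient cohort; the raw
per-subject data behind them is not available, so nothing else in the
package treats them as reproduction targets.
"""

from __future__ import annotations

#: Function-test column order used everywhere downstream.
TEST_NAMES = ("iswt", "gait_speed", "tuag", "sts60", "hgs")

#: GLCM feature row order used everywhere downstream.
FEATURE_NAMES = ("asm", "entropy", "idm", "correlation", "contrast")

#: Spearman rho, feature x test, for the published 90-subject cohort.
REFERENCE_RHO: dict[str, dict[str, float]] = {
    "asm":         {"iswt": 0.215, "gait_speed": 0.188, "tuag": -0.104,
                    "sts60": 0.110, "hgs": 0.235},
    "entropy":     {"iswt": -0.259, "gait_speed": -0.275, "tuag": 0.079,
                    "sts60": -0.163, "hgs": -0.255},
    "idm":         {"iswt": 0.216, "gait_speed": 0.244, "tuag": -0.053,
                    "sts60": 0.129, "hgs": 0.289},
    "correlation": {"iswt": 0.141, "gait_speed": 0.289, "tuag": -0.037,
                    "sts60": 0.106, "hgs": 0.244},
    "contrast":    {"iswt": -0.166, "gait_speed": -0.255, "tuag": 0.107,
                    "sts60": -0.136, "hgs": -0.275},
}

#: Published Fisher-z averaged coefficient per feature (3 decimals).
REFERENCE_AVERAGE_R: dict[str, float] = {
    "asm": 0.130,
    "entropy": -0.177,
    "idm": 0.167,
    "correlation": 0.150,
    "contrast": -0.147,
}

#: Feature flagged as largest-magnitude average in the published report.
REFERENCE_BEST_FEATURE = "entropy"

#: Cohort summary statistics (mean, SD) and proportions used as
#: synthetic-cohort defaults. Units: age years; BMI kg/m^2; eGFR
#: mL/min/1.73 m^2; Hb g/L; albumin g/L; ISWT meters; gait speed m/s;
#: HGS kg; TUAG seconds; STS-60 repetitions.
COHORT_SUMMARY = {
    "n_subjects": 90,
    "age": (64.6, 10.9),
    "male_fraction": 0.44,
    "white_fraction": 0.70,
    "bmi": (29.2, 6.0),
    "egfr": (33.8, 15.7),
    "hb": (125.7, 15.9),
    "albumin": (42.1, 2.5),
    "hypertension_fraction": 0.55,
    "diabetes_fraction": 0.19,
    "iswt": (433.0, 178.7),
    "gait_speed": (1.3, 0.4),
    "hgs": (28.9, 10.2),
    "tuag": (9.7, 2.4),
    "sts60": (25.8, 10.4),
}

#: Sign of each feature's association with better physical function:
#: homogeneity features rise with function, disorder features fall.
#: TUAG and the latent-quality link flip accordingly (a *longer*
#: up-and-go time means worse function).
FEATURE_FUNCTION_SIGN = {
    "asm": +1, "entropy": -1, "idm": +1, "correlation": +1, "contrast": -1,
}

#: Tests where a larger value means worse performance.
TESTS_LOWER_IS_BETTER = ("tuag",)
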