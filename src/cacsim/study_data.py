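"""Reference constants of the low-kVp CAC scoring study this package emulates.

The clinical study scanned 169 patients three times (120, 80 and 70 kVp) on
the same scanner, scored coronary calcium with voltage-adapted Agatston
thresholds, and cross-tabulated the resulting risk classes.  Everything a
simulation needs to reproduce the study conditions is collected here: the
threshold tables, the scan-parameter/noise statistics, the cohort risk-class
mix and BMI distribution, the dose-conversion factors, and the three printed
5x5 risk-class contingency tables.
"""

from __future__ import annotations

import math

import numpy as np

SUPPORTED_KVP = (70, 80, 120)

#: Agatston density-score lower bounds (HU) per tube voltage.  The 120 kVp
#: row is the classic 130/200/300/400; the 80 and 70 kVp rows are the
#: voltage-adapted replacements validated by the study.
THRESHOLD_BOUNDS: dict[int, tuple[int, int, int, int]] = {
    120: (130, 200, 300, 400),
    80: (177, 272, 409, 545),
    70: (207, 319, 478, 637),
}

#: HU multiplier applied to calcium when scanning below 120 kVp.  Calcium
#: attenuation rises as photon energy drops; the adapted thresholds encode
#: exactly this rise (each low-kVp bound / its 120 kVp counterpart).
CALCIUM_SCALE: dict[int, float] = {
    120: 1.0,
    80: THRESHOLD_BOUNDS[80][3] / THRESHOLD_BOUNDS[120][3],  # 1.3625
    70: THRESHOLD_BOUNDS[70][3] / THRESHOLD_BOUNDS[120][3],  # 1.5925
}

#: Aortic blood-pool signal (HU) measured in the study per voltage, and the
#: derived soft-tissue/blood HU multiplier (blood attenuation also rises at
#: low kVp, but far less than calcium).
BLOOD_SIGNAL_HU: dict[int, float] = {120: 48.5, 80: 51.0, 70: 53.1}
TISSUE_SCALE: dict[int, float] = {
    kvp: BLOOD_SIGNAL_HU[kvp] / BLOOD_SIGNAL_HU[120] for kvp in SUPPORTED_KVP
}

#: Mean tube current (mA) per voltage under the study's noise-normalized
#: protocol (fixed 200 mA at 120 kVp; noise-index-driven below).
TUBE_CURRENT_MA: dict[int, float] = {120: 200.0, 80: 460.1, 70: 460.6}

#: Mean aortic-ROI noise (HU standard deviation) per voltage — the
#: "normalized" noise level the adaptive tube current achieved.
ROI_NOISE_HU: dict[int, float] = {120: 28.1, 80: 27.7, 70: 28.7}

#: Mean signal-to-noise ratio per voltage as reported (mean of per-patient
#: signal/noise ratios).
ROI_SNR: dict[int, float] = {120: 1.8, 80: 1.9, 70: 1.9}

#: Effective-dose conversion factors (mSv per mGy*cm of DLP).
DOSE_CONVERSION: dict[int, float] = {120: 0.0145, 80: 0.0147, 70: 0.0147}

#: Mean effective dose (mSv) per protocol in the study; used only to anchor
#: the parametric DLP model of the simulator.
MEAN_EFFECTIVE_DOSE_MSV: dict[int, float] = {120: 0.54, 80: 0.42, 70: 0.26}

#: Ordinal cardiovascular risk classes by (rounded) total CAC score.
RISK_CLASS_LABELS = ("0", "1-10", "11-100", "101-400", ">400")

#: Study cohort size and its 120 kVp risk-class counts (reader 1).
N_SUBJECTS = 169
RISK_CLASS_COUNTS = (49, 18, 45, 34, 23)
RISK_CLASS_PROPORTIONS = tuple(c / N_SUBJECTS for c in RISK_CLASS_COUNTS)

#: Cohort BMI distribution: median [IQR] and observed range, kg/m^2.
BMI_MEDIAN = 26.1
BMI_IQR = (23.7, 28.3)
BMI_RANGE = (18.9, 39.9)

# Log-normal parameters matched to the median and IQR above:
# mu = ln(median); sigma chosen so the quartiles of ln(BMI) match the IQR.
BMI_LOG_MU = math.log(BMI_MEDIAN)
_Z75 = 0.6744897501960817  # 75th percentile of the standard normal
BMI_LOG_SIGMA = (math.log(BMI_IQR[1]) - math.log(BMI_IQR[0])) / (2 * _Z75)


def _table(rows: list[list[int]], row_condition: str, col_condition: str):
    # local import to avoid a cycle (agreement imports nothing from here at
    # module level beyond constants)
    from .agreement import RiskContingencyTable

    return RiskContingencyTable(
        counts=np.asarray(rows, dtype=int),
        row_condition=row_condition,
        col_condition=col_condition,
    )


# The three published 5x5 risk-class cross-tabulations (rows = comparison
# condition, columns = 120 kVp reference; class order 0, 1-10, 11-100,
# 101-400, >400).
STUDY_TABLE_ROWS: dict[str, list[list[int]]] = {
    # 80 kVp (adapted thresholds) vs 120 kVp
    "80_vs_120": [
        [49, 2, 0, 0, 0],
        [0, 16, 5, 0, 0],
        [0, 0, 40, 3, 0],
        [0, 0, 0, 31, 2],
        [0, 0, 0, 0, 21],
    ],
    # 70 kVp (adapted thresholds) vs 120 kVp
    "70_vs_120": [
        [49, 6, 3, 0, 0],
        [0, 12, 6, 0, 0],
        [0, 0, 36, 7, 0],
        [0, 0, 0, 26, 6],
        [0, 0, 0, 1, 17],
    ],
    # second reader vs first reader, both on the 120 kVp scans
    "reader2_vs_reader1": [
        [47, 0, 0, 0, 0],
        [2, 17, 2, 0, 0],
        [0, 1, 43, 0, 0],
        [0, 0, 0, 33, 1],
        [0, 0, 0, 1, 22],
    ],
}

#: Agreement statistics as printed alongside each study table (3 decimals),
#: plus the reclassification counts; used by reproduce_printed() to flag
#: pass/fail of the re-computation.
PRINTED_AGREEMENT: dict[str, dict[str, float]] = {
    "80_vs_120": {"kappa": 0.908, "tau_b": 0.967, "n_reclassified": 12, "rate_pct": 7.1},
    "70_vs_120": {"kappa": 0.777, "tau_b": 0.915, "n_reclassified": 29, "rate_pct": 17.2},
    "reader2_vs_reader1": {"kappa": 0.947, "tau_b": 0.980, "n_reclassified": 7, "rate_pct": 4.1},
}


def study_tables() -> dict:
    """Return the three embedded study contingency tables, keyed by
    comparison (``80_vs_120``, ``70_vs_120``, ``reader2_vs_reader1``)."""
    labels = {
        "80_vs_120": ("80 kVp", "120 kVp"),
        "70_vs_120": ("70 kVp", "120 kVp"),
        "reader2_vs_reader1": ("120 kVp reader 2", "120 kVp reader 1"),
    }
    return {
        key: _table(rows, *labels[key]) for key, rows in STUDY_TABLE_ROWS.items()
    }
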