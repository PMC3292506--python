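"""Transcribed summary tables from the published four-population
Holstein reference-sharing study, and arithmetic checks over them.

Every constant below is a transcription of a printed table cell or a
printed summary statistic; nothing here is computed by this package.
``check_published_arithmetic`` recomputes each derived printed number
(row/column means, differences, minima/maxima) from its printed inputs
and reports whether the recomputed value is consistent with the printed
one at the printed precision. Known internal inconsistencies of the
printed tables are reported as such, not raised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "POPULATIONS",
    "TRAITS",
    "REALIZED_GAINS",
    "EXPECTED_GAINS",
    "GENETIC_CORRELATIONS",
    "DRP_RELIABILITY",
    "HERITABILITY",
    "REFERENCE_SIZES",
    "EU_REL_GBV_PI",
    "check_published_arithmetic",
]

POPULATIONS = ["DFS", "DEU", "NLD", "FRA"]
TRAITS = ["protein", "udder_depth", "scs", "fertility"]

# Realized increases in reliability, national → combined reference
# (traits × populations); printed margins follow.
REALIZED_GAINS = pd.DataFrame(
    [
        [0.13, 0.02, 0.05, 0.04],
        [0.13, 0.19, 0.17, 0.12],
        [0.13, 0.15, 0.08, 0.08],
        [0.05, 0.10, 0.03, 0.10],
    ],
    index=TRAITS,
    columns=POPULATIONS,
)
REALIZED_GAINS_PRINTED_ROW_AVG = [0.06, 0.15, 0.11, 0.07]
REALIZED_GAINS_PRINTED_COL_AVG = [0.11, 0.12, 0.08, 0.09]
REALIZED_GAINS_PRINTED_MEAN = 0.10

# Expected increases (same layout, the parenthesized values).
EXPECTED_GAINS = pd.DataFrame(
    [
        [0.12, 0.13, 0.07, 0.13],
        [0.16, 0.15, 0.08, 0.15],
        [0.13, 0.14, 0.08, 0.16],
        [0.11, 0.14, 0.05, 0.08],
    ],
    index=TRAITS,
    columns=POPULATIONS,
)
EXPECTED_GAINS_PRINTED_MEAN = 0.12

# Average genetic correlation of a trait in one country with the same
# trait in the other three, plus the printed row averages.
GENETIC_CORRELATIONS = pd.DataFrame(
    [
        [0.870, 0.883, 0.877, 0.883],
        [0.977, 0.983, 0.977, 0.983],
        [0.890, 0.897, 0.903, 0.823],
        [0.820, 0.803, 0.570, 0.697],
    ],
    index=TRAITS,
    columns=["DEU", "DFS", "FRA", "NLD"],
)
GENETIC_CORRELATIONS_PRINTED_ROW_AVG = [0.878, 0.980, 0.878, 0.697]

# Heritability and mean DRP reliability, national vs. combined reference.
HERITABILITY = pd.DataFrame(
    [
        [0.39, 0.48, 0.50, 0.30],
        [0.37, 0.26, 0.40, 0.36],
        [0.15, 0.23, 0.37, 0.15],
        [0.02, 0.02, 0.22, 0.02],
    ],
    index=TRAITS,
    columns=POPULATIONS,
)
DRP_RELIABILITY = {
    "DFS": pd.DataFrame(
        {"national": [0.93, 0.83, 0.88, 0.58], "combined": [0.82, 0.84, 0.82, 0.48]},
        index=TRAITS,
    ),
    "DEU": pd.DataFrame(
        {"national": [0.95, 0.87, 0.90, 0.65], "combined": [0.82, 0.84, 0.83, 0.56]},
        index=TRAITS,
    ),
    "NLD": pd.DataFrame(
        {"national": [0.95, 0.91, 0.94, 0.90], "combined": [0.84, 0.86, 0.85, 0.72]},
        index=TRAITS,
    ),
    "FRA": pd.DataFrame(
        {"national": [0.91, 0.87, 0.85, 0.61], "combined": [0.77, 0.81, 0.80, 0.39]},
        index=TRAITS,
    ),
}
DRP_RELIABILITY_PRINTED_AVG = {
    "DFS": {"national": 0.81, "combined": 0.74},
    "DEU": {"national": 0.84, "combined": 0.76},
    "NLD": {"national": 0.93, "combined": 0.82},
    "FRA": {"national": 0.81, "combined": 0.69},
}

# Printed average reference sizes (national, combined) and the increases
# quoted in the study's discussion.
REFERENCE_SIZES = {
    "DFS": (3035, 10762),
    "DEU": (3675, 14411),
    "NLD": (3467, 9540),
    "FRA": (3071, 12078),
}
REFERENCE_SIZE_PRINTED_INCREASE = {"DEU": 10736, "DFS": 7727, "FRA": 9007, "NLD": 6073}

# REL_GBV-PI columns of the combined-reference validation blocks for the
# two partners whose printed tables carry a plain average row.
EU_REL_GBV_PI = {
    "DFS": [0.32, 0.42, 0.32, 0.19],
    "NLD": [0.28, 0.36, 0.27, 0.21],
}
EU_REL_GBV_PI_PRINTED_AVG = {"DFS": 0.31, "NLD": 0.28}


def consistent_at_printed_precision(computed: float, printed: float, decimals: int) -> bool:
    """True when the computed value rounds to the printed one under SOME
    half rounding convention: |computed − printed| ≤ half an ulp of the
    printed precision. The source tables are ambiguous exactly at the
    half (different tables are consistent with different conventions), so
    the check must not commit to one rounding mode."""
    return abs(computed - printed) <= 0.5 * 10.0 ** (-decimals) + 1e-12


def check_published_arithmetic() -> pd.DataFrame:
    """Recompute every derived printed number from its printed inputs.

    Returns a frame with one row per check: name, computed, printed,
    match flag and a note. Known inconsistencies in the printed tables
    are flagged with match=False and an explanatory note; they are
    reported, never raised.
    """
    rows = []

    def add(name, computed, printed, decimals, note=""):
        if decimals == 0:
            ok = computed == printed
        else:
            ok = consistent_at_printed_precision(computed, printed, decimals)
        rows.append(
            {
                "check": name,
                "computed": float(computed),
                "printed": float(printed),
                "match": bool(ok),
                "note": note,
            }
        )

    rg16 = REALIZED_GAINS.to_numpy()
    add("realized_gain_mean_16_cells", rg16.mean(), REALIZED_GAINS_PRINTED_MEAN, 2)
    add("realized_gain_min", rg16.min(), 0.02, 2)
    add("realized_gain_max", rg16.max(), 0.19, 2)
    for i, t in enumerate(TRAITS):
        add(f"realized_gain_row_avg_{t}", rg16[i].mean(),
            REALIZED_GAINS_PRINTED_ROW_AVG[i], 2)
    for j, p in enumerate(POPULATIONS):
        add(f"realized_gain_col_avg_{p}", rg16[:, j].mean(),
            REALIZED_GAINS_PRINTED_COL_AVG[j], 2)
    add("expected_gain_mean_16_cells", EXPECTED_GAINS.to_numpy().mean(),
        EXPECTED_GAINS_PRINTED_MEAN, 2)

    for p, col in EU_REL_GBV_PI.items():
        add(f"combined_rel_gbv_pi_avg_{p}", np.mean(col),
            EU_REL_GBV_PI_PRINTED_AVG[p], 2)

    for p, printed in DRP_RELIABILITY_PRINTED_AVG.items():
        tbl = DRP_RELIABILITY[p]
        add(f"drp_reliability_avg_{p}_national", tbl["national"].mean(),
            printed["national"], 2)
        add(f"drp_reliability_avg_{p}_combined", tbl["combined"].mean(),
            printed["combined"], 2)

    for p, printed in REFERENCE_SIZE_PRINTED_INCREASE.items():
        nat, comb = REFERENCE_SIZES[p]
        add(f"reference_size_increase_{p}", comb - nat, printed, 0)

    for i, t in enumerate(TRAITS):
        computed = GENETIC_CORRELATIONS.iloc[i].mean()
        printed = GENETIC_CORRELATIONS_PRINTED_ROW_AVG[i]
        note = ""
        if not consistent_at_printed_precision(computed, printed, 3):
            note = (
                "known inconsistency in the printed table: the row average "
                "does not equal the mean of its printed cells"
            )
        add(f"genetic_correlation_row_avg_{t}", computed, printed, 3, note)

    return pd.DataFrame(rows)
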