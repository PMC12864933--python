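"""Group-level summary tables of the two-site, two-night insomnia study
design this pipeline targets, plus the arithmetic helpers that operate on
such tables.

The raw recordings of the motivating study are confidential, but its
group-level summaries (participant counts per ISI category and per-group
means of the basic sleep variables) are public numbers.  They serve two
roles here: they anchor the synthetic generator's defaults, and they let
summary-level quantities (prevalences, size-weighted means, night
differences) be recomputed exactly from the tables alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Participants per ISI category in the two cohorts (GSC, MI, MSI).
ISI_COUNTS: dict[str, dict[str, int]] = {
    "dataset1": {"GSC": 25, "MI": 21, "MSI": 15},
    "dataset2": {"GSC": 62, "MI": 28, "MSI": 47},
}

# Per-group mean (M) and SD of basic sleep variables, by cohort, night and
# ISI category.  Variables: TST/SOL/WASO in minutes; stage percentages of
# total sleep time; bout lengths in minutes.
_SUMMARY_ROWS = [
    # dataset, variable, night, group, mean, sd
    ("dataset1", "TST_min", 1, "GSC", 426.6, 37.4),
    ("dataset1", "TST_min", 1, "MI", 407.0, 65.2),
    ("dataset1", "TST_min", 1, "MSI", 387.9, 56.3),
    ("dataset1", "TST_min", 2, "GSC", 433.4, 52.9),
    ("dataset1", "TST_min", 2, "MI", 430.6, 55.3),
    ("dataset1", "TST_min", 2, "MSI", 415.0, 35.3),
    ("dataset2", "TST_min", 1, "GSC", 398.6, 57.1),
    ("dataset2", "TST_min", 1, "MI", 372.5, 69.8),
    ("dataset2", "TST_min", 1, "MSI", 376.7, 76.6),
    ("dataset2", "TST_min", 2, "GSC", 414.5, 63.7),
    ("dataset2", "TST_min", 2, "MI", 386.0, 72.0),
    ("dataset2", "TST_min", 2, "MSI", 411.8, 58.8),
    ("dataset1", "SOL_min", 1, "GSC", 16.6, 10.9),
    ("dataset1", "SOL_min", 1, "MI", 26.7, 29.5),
    ("dataset1", "SOL_min", 1, "MSI", 27.2, 26.4),
    ("dataset1", "SOL_min", 2, "GSC", 14.3, 12.8),
    ("dataset1", "SOL_min", 2, "MI", 16.7, 14.2),
    ("dataset1", "SOL_min", 2, "MSI", 18.5, 13.5),
    ("dataset2", "SOL_min", 1, "GSC", 27.7, 23.9),
    ("dataset2", "SOL_min", 1, "MI", 23.2, 22.1),
    ("dataset2", "SOL_min", 1, "MSI", 26.9, 24.2),
    ("dataset2", "SOL_min", 2, "GSC", 28.7, 33.4),
    ("dataset2", "SOL_min", 2, "MI", 17.0, 14.7),
    ("dataset2", "SOL_min", 2, "MSI", 19.0, 16.1),
    ("dataset1", "WASO_min", 1, "GSC", 26.8, 22.6),
    ("dataset1", "WASO_min", 1, "MI", 41.0, 29.8),
    ("dataset1", "WASO_min", 1, "MSI", 57.6, 47.2),
    ("dataset1", "WASO_min", 2, "GSC", 21.0, 18.6),
    ("dataset1", "WASO_min", 2, "MI", 27.2, 26.1),
    ("dataset1", "WASO_min", 2, "MSI", 32.1, 23.7),
    ("dataset2", "WASO_min", 1, "GSC", 48.9, 33.7),
    ("dataset2", "WASO_min", 1, "MI", 59.1, 44.3),
    ("dataset2", "WASO_min", 1, "MSI", 56.3, 47.1),
    ("dataset2", "WASO_min", 2, "GSC", 34.5, 27.9),
    ("dataset2", "WASO_min", 2, "MI", 54.5, 44.2),
    ("dataset2", "WASO_min", 2, "MSI", 55.4, 36.9),
    ("dataset1", "REM_pct", 1, "GSC", 23.7, 5.0),
    ("dataset1", "REM_pct", 1, "MI", 24.1, 4.1),
    ("dataset1", "REM_pct", 1, "MSI", 22.0, 3.5),
    ("dataset1", "REM_pct", 2, "GSC", 25.8, 6.1),
    ("dataset1", "REM_pct", 2, "MI", 25.0, 4.7),
    ("dataset1", "REM_pct", 2, "MSI", 23.9, 5.1),
    ("dataset2", "REM_pct", 1, "GSC", 18.0, 7.3),
    ("dataset2", "REM_pct", 1, "MI", 18.6, 7.2),
    ("dataset2", "REM_pct", 1, "MSI", 17.3, 5.5),
    ("dataset2", "REM_pct", 2, "GSC", 18.6, 7.3),
    ("dataset2", "REM_pct", 2, "MI", 19.3, 6.8),
    ("dataset2", "REM_pct", 2, "MSI", 17.0, 7.5),
    ("dataset1", "N1_pct", 1, "GSC", 2.2, 1.2),
    ("dataset1", "N1_pct", 1, "MI", 3.8, 2.0),
    ("dataset1", "N1_pct", 1, "MSI", 3.7, 2.2),
    ("dataset1", "N1_pct", 2, "GSC", 2.0, 1.2),
    ("dataset1", "N1_pct", 2, "MI", 2.7, 1.6),
    ("dataset1", "N1_pct", 2, "MSI", 3.0, 1.8),
    ("dataset2", "N1_pct", 1, "GSC", 5.4, 4.1),
    ("dataset2", "N1_pct", 1, "MI", 5.5, 4.4),
    ("dataset2", "N1_pct", 1, "MSI", 5.4, 3.5),
    ("dataset2", "N1_pct", 2, "GSC", 4.6, 3.4),
    ("dataset2", "N1_pct", 2, "MI", 5.4, 3.7),
    ("dataset2", "N1_pct", 2, "MSI", 5.7, 3.9),
    ("dataset1", "N2_pct", 1, "GSC", 54.4, 5.8),
    ("dataset1", "N2_pct", 1, "MI", 52.6, 6.2),
    ("dataset1", "N2_pct", 1, "MSI", 54.5, 10.4),
    ("dataset1", "N2_pct", 2, "GSC", 52.1, 6.6),
    ("dataset1", "N2_pct", 2, "MI", 50.2, 8.2),
    ("dataset1", "N2_pct", 2, "MSI", 53.9, 9.0),
    ("dataset2", "N2_pct", 1, "GSC", 55.4, 11.7),
    ("dataset2", "N2_pct", 1, "MI", 53.5, 13.0),
    ("dataset2", "N2_pct", 1, "MSI", 55.6, 7.6),
    ("dataset2", "N2_pct", 2, "GSC", 53.9, 10.6),
    ("dataset2", "N2_pct", 2, "MI", 51.7, 9.8),
    ("dataset2", "N2_pct", 2, "MSI", 54.9, 10.2),
    ("dataset1", "N3_pct", 1, "GSC", 19.8, 5.4),
    ("dataset1", "N3_pct", 1, "MI", 19.5, 5.3),
    ("dataset1", "N3_pct", 1, "MSI", 19.8, 9.2),
    ("dataset1", "N3_pct", 2, "GSC", 20.1, 7.8),
    ("dataset1", "N3_pct", 2, "MI", 22.6, 6.8),
    ("dataset1", "N3_pct", 2, "MSI", 19.2, 6.3),
    ("dataset2", "N3_pct", 1, "GSC", 21.3, 9.5),
    ("dataset2", "N3_pct", 1, "MI", 22.4, 10.4),
    ("dataset2", "N3_pct", 1, "MSI", 21.7, 7.8),
    ("dataset2", "N3_pct", 2, "GSC", 22.9, 10.2),
    ("dataset2", "N3_pct", 2, "MI", 23.6, 9.6),
    ("dataset2", "N3_pct", 2, "MSI", 22.5, 8.5),
]


def summary_table() -> pd.DataFrame:
    """Long-format table of per-group sleep-variable summaries."""
    return pd.DataFrame(
        _SUMMARY_ROWS,
        columns=["dataset", "variable", "night", "group", "mean", "sd"],
    )


def isi_count_matrix() -> np.ndarray:
    """2x3 participant-count table (rows = cohorts, columns = GSC/MI/MSI)."""
    return np.array(
        [
            [ISI_COUNTS["dataset1"][g] for g in ("GSC", "MI", "MSI")],
            [ISI_COUNTS["dataset2"][g] for g in ("GSC", "MI", "MSI")],
        ]
    )


def insomnia_prevalence_pct(dataset: str) -> float:
    """Share of participants in any insomnia category (MI + MSI), percent."""
    c = ISI_COUNTS[dataset]
    total = sum(c.values())
    return 100.0 * (c["MI"] + c["MSI"]) / total


def category_share_pct(dataset: str, group: str) -> float:
    """Share of participants in one ISI category, percent."""
    c = ISI_COUNTS[dataset]
    return 100.0 * c[group] / sum(c.values())


def weighted_night_mean(dataset: str, variable: str, night: int) -> float:
    """Group-size-weighted cohort mean of a sleep variable for one night."""
    tab = summary_table()
    sub = tab[(tab["dataset"] == dataset) & (tab["variable"] == variable)
              & (tab["night"] == night)]
    counts = ISI_COUNTS[dataset]
    w = np.array([counts[g] for g in sub["group"]], dtype=float)
    return float(np.average(sub["mean"].to_numpy(), weights=w))


def night_difference(dataset: str, variable: str) -> float:
    """Night-2 minus Night-1 size-weighted cohort mean of a variable."""
    return (weighted_night_mean(dataset, variable, 2)
            - weighted_night_mean(dataset, variable, 1))


def two_night_group_mean(dataset: str, variable: str, group: str) -> float:
    """Mean of a group's variable across the two nights."""
    tab = summary_table()
    sub = tab[(tab["dataset"] == dataset) & (tab["variable"] == variable)
              & (tab["group"] == group)]
    return float(sub["mean"].mean())
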