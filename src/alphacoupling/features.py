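"""Per-subject scalar features feeding group statistics and the SVM.

Fifteen features per subject: six behavioral (per-condition error rate and
mean RT plus the two flanker effects) and nine electrophysiological
(prestimulus alpha power in each speed × congruency cell, its grand mean,
the slow − fast power differences per condition, and the Fisher-z alpha–RT
correlations per condition).
"""

from __future__ import annotations

import pandas as pd

from .ml import ALL_FEATURES, EEG_FEATURES
from .simulate import CONDITIONS


def build_subject_features(
    behavioral: pd.DataFrame, coupling: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the 15-feature table, one row per subject.

    ``behavioral``: one row per subject (index = subject, plus ``group``)
    with the ``behavioral_summary`` columns.  ``coupling``: tidy per-subject
    × condition frame from ``subject_coupling``.  The alpha grand mean is
    the mean of the four speed × congruency cell means.
    """
    rows = {}
    for subj, brow in behavioral.iterrows():
        row = {
            "group": brow["group"],
            "ER_congruent": brow["ER_congruent"],
            "ER_incongruent": brow["ER_incongruent"],
            "RT_congruent": brow["RT_congruent"],
            "RT_incongruent": brow["RT_incongruent"],
            "flankerER": brow["flankerER"],
            "flankerRT": brow["flankerRT"],
        }
        csub = coupling[coupling["subject"] == subj]
        if set(csub["condition"]) != set(CONDITIONS):
            raise ValueError(f"incomplete coupling rows for subject {subj!r}")
        cells = []
        for cond in CONDITIONS:
            crow = csub[csub["condition"] == cond].iloc[0]
            row[f"alpha_{cond}_fast"] = crow["alpha_fast"]
            row[f"alpha_{cond}_slow"] = crow["alpha_slow"]
            row[f"alphadiff_{cond}"] = crow["alpha_diff"]
            row[f"z_{cond}"] = crow["z"]
            cells += [crow["alpha_fast"], crow["alpha_slow"]]
        row["alpha_grandmean"] = sum(cells) / len(cells)
        rows[subj] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject"
    return out[["group", *ALL_FEATURES]]


def eeg_feature_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """The nine electrophysiological columns (regression inputs)."""
    return features[list(EEG_FEATURES)]
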