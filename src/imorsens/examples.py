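"""Small published example datasets used in the documentation and tests.

Both examples come from smoking-cessation trials, where the event is
smoking at follow-up, ``x = 1`` means smoking at baseline, and the
"missing = event" assumption is the field's Russell Standard.
"""

from __future__ import annotations

import pandas as pd

from .trial_data import CellCounts, TrialTable


def iquit_treatment_arm() -> TrialTable:
    """Treatment arm of the iQuit internet-based cessation trial.

    877 participants: 131 considered not smoking at baseline (65 provided
    outcome data, of whom 41 were smoking) and 746 smoking at baseline
    (286 provided outcome data, of whom 230 were smoking).  The control
    arm's cell counts were not published, so its cells are zero here; the
    table supports the treatment-arm walk-through (observed log-odds,
    missing-cell probabilities, arm probability) but not a full fit.
    """
    cells = {
        (0, 1): CellCounts(41, 24, 66),
        (1, 1): CellCounts(230, 56, 460),
        (0, 0): CellCounts(0, 0, 0),
        (1, 0): CellCounts(0, 0, 0),
    }
    return TrialTable(cells, has_x=True)


def cessation_missingness_counts() -> pd.DataFrame:
    """Known/missing outcome counts from a group-therapy cessation trial.

    489 participants; the outcome was known for 216 of 299 controls (72%)
    and 156 of 190 treated (82%).  The per-cell event split was not
    published, so only the missingness pattern is represented.
    """
    return pd.DataFrame(
        [
            {"arm": "control", "known": 216, "missing": 83},
            {"arm": "treatment", "known": 156, "missing": 34},
        ]
    )
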