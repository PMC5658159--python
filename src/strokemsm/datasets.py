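"""Packaged reference data.

The NINDS t-PA trial's published 90-day mRS distribution (raw observed
counts, 619 subjects with a recorded 90-day mRS) is included as a small
count table.  The full subject-level NINDS dataset is public on request but
is not redistributed here; the count table supports single-endpoint
analyses that depend only on the 90-day marginal distribution (2x2
collapse, shift test, summary reproduction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import ARMS, StateSpace, TrialPanel

#: Published 90-day mRS counts per arm in the NINDS t-PA trial (raw observed
#: values, not the intent-to-treat imputation): state 0..6 by column.
_NINDS_90D = {
    "control":   (33, 50, 37, 45, 61, 21, 63),
    "treatment": (57, 74, 23, 40, 42, 19, 54),
}


def ninds_mrs90_counts() -> pd.DataFrame:
    """Arm x state count table of the NINDS t-PA 90-day mRS distribution."""
    df = pd.DataFrame(_NINDS_90D).T
    df.index.name = "arm"
    df.columns = list(range(7))
    df.columns.name = "state"
    return df.loc[list(ARMS)]


def ninds_mrs90_panel(visit_day: float = 90.0) -> TrialPanel:
    """Expand the 90-day count table to a single-visit subject-level panel.

    Each count becomes that many subjects with one record at `visit_day`.
    Ordering is deterministic (arm, then state, then replicate index).
    """
    counts = ninds_mrs90_counts()
    rows = []
    i = 0
    for arm in counts.index:
        for state in counts.columns:
            for _ in range(int(counts.loc[arm, state])):
                rows.append({"subject_id": f"s{i:04d}", "arm": arm,
                             "time_days": float(visit_day), "state": int(state)})
                i += 1
    data = pd.DataFrame(rows)
    return TrialPanel(data, state_space=StateSpace.general())
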