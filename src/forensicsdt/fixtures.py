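"""Synthetic worked-example datasets matching the published classification tables.

The raw fingerprint-comparison study data are not redistributed here. These
fixtures are synthetic integer-rating datasets constructed so that their
binary and ternary tabulations reproduce the published expert and novice
classification-table counts exactly (1056 decisions each: 515 same-source,
541 different-source, spread over 44 participants x 24 trials). Individual
participant and trial assignments are arbitrary; only the aggregate counts
are meaningful.

Rating values encode the outcome cells: 10 for confident conclusive calls,
7 and 6 for the least-confident conclusive band (the ratings recoded as
inconclusive by the ternary analysis), and 2 for confident "different" calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import DIFFERENT, SAME

# (truth, rating, count) cells. Binary coding (>= 6.5 -> same) recovers the
# expert 2x2 counts 396/119/64/477; recoding ratings 6-7 as inconclusive
# recovers the ternary counts 359/87/69 and 43/420/78.
_EXPERT_CELLS = (
    (SAME, 10.0, 359),
    (SAME, 7.0, 37),
    (SAME, 6.0, 32),
    (SAME, 2.0, 87),
    (DIFFERENT, 10.0, 43),
    (DIFFERENT, 7.0, 21),
    (DIFFERENT, 6.0, 57),
    (DIFFERENT, 2.0, 420),
)

# Novice 2x2 counts 362/153/282/259 (binary only; no 6-7 band is needed).
_NOVICE_CELLS = (
    (SAME, 10.0, 362),
    (SAME, 2.0, 153),
    (DIFFERENT, 10.0, 282),
    (DIFFERENT, 2.0, 259),
)

N_PARTICIPANTS = 44


def _build(cells, group: str, prefix: str) -> pd.DataFrame:
    truth = np.concatenate([[t] * n for t, _, n in cells])
    rating = np.concatenate([[r] * n for _, r, n in cells])
    n = truth.size
    pid = np.array([f"{prefix}{i % N_PARTICIPANTS + 1:02d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "group": group,
            "trial_id": "",
            "truth": truth,
            "rating": rating,
        }
    )
    df["trial_id"] = [
        f"t{j + 1:02d}" for j in df.groupby("participant_id").cumcount()
    ]
    return df


def expert_study_records() -> pd.DataFrame:
    """Synthetic expert dataset whose tabulations match the published tables."""
    return _build(_EXPERT_CELLS, "expert", "e")


def novice_study_records() -> pd.DataFrame:
    """Synthetic novice dataset whose binary tabulation matches the published table."""
    return _build(_NOVICE_CELLS, "novice", "n")
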