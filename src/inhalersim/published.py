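"""Published reference inputs for the budget projection.

The average annual delivery-rate gain schedules below are the published
training-period trajectories for patients who consistently adopted the
proper inhalation technique (percent-of-dose gain over the 59.2% / 67.4%
baseline delivery rates, per training year).  The budget projections treat
them as fixed inputs: the gain of training year 2019 + k phases in as the
cartridge-content reduction of post-training year 2024 + k.  The four-year
schedules fix 2019 at zero because that training programme only starts in
2020.

Our own Monte Carlo models produce comparable (but stochastic) schedules;
these published values decouple the deterministic cost arithmetic from the
simulation calibration.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TRAINING_YEARS",
    "POST_TRAINING_YEARS",
    "PUBLISHED_GAIN_SCHEDULES",
    "published_gains",
    "PUBLISHED_LEARNED_FRACTIONS",
]

TRAINING_YEARS = list(range(2019, 2024))
POST_TRAINING_YEARS = list(range(2024, 2029))

# (training_length, severity) -> gain (%) per training year
PUBLISHED_GAIN_SCHEDULES = {
    ("five_year", "moderate"): [0.714, 1.517, 2.308, 3.101, 3.929],
    ("five_year", "severe"): [0.475, 1.284, 2.069, 2.880, 3.646],
    ("four_year", "moderate"): [0.000, 0.721, 1.520, 2.323, 3.122],
    ("four_year", "severe"): [0.000, 0.478, 1.279, 2.072, 2.873],
}

# Reported share of patients consistently confirming the proper technique.
PUBLISHED_LEARNED_FRACTIONS = {"five_year": 0.32, "four_year": 0.23}


def published_gains(training_length: str, severity: str, post_training: bool = False) -> pd.Series:
    """Published gain schedule as a Series indexed by calendar year.

    With ``post_training=True`` the schedule is re-indexed onto the
    post-training years 2024-2028 (the phase-in rule used by the cost
    projections); otherwise it is indexed by the training years 2019-2023.
    """
    values = PUBLISHED_GAIN_SCHEDULES[(training_length, severity)]
    index = POST_TRAINING_YEARS if post_training else TRAINING_YEARS
    return pd.Series(values, index=index, name="gain_percent", dtype=float)
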