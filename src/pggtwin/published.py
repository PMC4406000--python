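"""Published per-level decision summaries from the two twin experiments.

These are the printed summary statistics (per-level mean and SD of the
conditional decisions, plus the unconditional decision) of the on-site group
experiment (``study1``, levels 1–20, multiplier 1.6) and the web experiment
(``study2``, levels 0–20, multiplier 2.0). They serve as fixed inputs for
the trend regressions and composite-score consistency checks: the raw
individual-level records were never deposited, so these summaries are the
reproducible anchor for the scoring stage.

Values are transcribed at the printed precision (two decimals).
"""

from __future__ import annotations

import numpy as np

from .scores import DecisionSummary

# levels 1..20
_STUDY1_MEAN = [
    2.38, 2.82, 3.25, 3.87, 4.35, 4.69, 5.09, 5.56, 5.99, 6.73,
    7.11, 7.35, 7.51, 7.76, 8.13, 8.32, 8.28, 8.61, 9.01, 9.73,
]
_STUDY1_SD = [
    4.85, 4.59, 4.54, 4.43, 4.45, 4.35, 4.37, 4.53, 4.75, 5.24,
    5.59, 5.79, 6.02, 6.28, 6.68, 7.06, 7.33, 7.70, 8.11, 8.72,
]
_STUDY1_UC = (7.25, 5.74)

# levels 0..20
_STUDY2_MEAN = [
    1.00, 1.67, 2.19, 2.53, 3.01, 3.63, 4.15, 4.52, 5.06, 5.57, 6.22,
    6.84, 7.26, 7.71, 7.89, 8.43, 8.80, 8.89, 9.50, 9.74, 9.98,
]
_STUDY2_SD = [
    3.37, 3.64, 3.70, 3.55, 3.75, 4.04, 4.23, 4.48, 4.79, 5.08, 5.21,
    5.59, 5.84, 6.18, 6.49, 6.98, 7.37, 7.76, 8.13, 8.58, 9.14,
]
_STUDY2_UC = (7.03, 6.21)

#: printed composite band-score means, study 1 (bands over C1–C20)
STUDY1_BAND_MEANS = {"LC": 3.34, "MLC": 5.61, "MHC": 7.57, "HC": 8.79}
#: printed composite band-score means, study 2 (bands over C0–C20)
STUDY2_BAND_MEANS = {"LC2": 2.60, "MC2": 6.17, "HC2": 9.03}


def study1_summary() -> DecisionSummary:
    """Per-level decision summary of the group experiment (levels 1–20)."""
    return DecisionSummary(
        levels=np.arange(1, 21),
        mean=np.array(_STUDY1_MEAN),
        sd=np.array(_STUDY1_SD),
        uc_mean=_STUDY1_UC[0],
        uc_sd=_STUDY1_UC[1],
        n=296,
    )


def study2_summary() -> DecisionSummary:
    """Per-level decision summary of the web experiment (levels 0–20)."""
    return DecisionSummary(
        levels=np.arange(0, 21),
        mean=np.array(_STUDY2_MEAN),
        sd=np.array(_STUDY2_SD),
        uc_mean=_STUDY2_UC[0],
        uc_sd=_STUDY2_UC[1],
        n=282,
    )
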