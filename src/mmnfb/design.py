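"""Experimental design vocabulary and the Group x Day dummy coding.

Four groups cross two factors: genuine vs sham neurofeedback (NT/NC) and
2AFC behavioral training with vs without feedback (BT/BC).  Four
measurement days: the pre-training test plus one test after each of the
three training days.  The binomial mixed model for the BAD test uses
treatment (dummy) coding with reference cell (NTBT, pre), giving 16 fixed
effects: intercept, 3 group mains, 3 day mains, 9 interactions.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

GROUPS = ("NTBT", "NTBC", "NCBT", "NCBC")
DAYS = ("pre", "d1", "d2", "d3")
TRAINING_DAYS = ("d1", "d2", "d3")

COEF_NAMES = (
    "Intercept",
    "Group[NTBC]", "Group[NCBT]", "Group[NCBC]",
    "Day[d1]", "Day[d2]", "Day[d3]",
    "Group[NTBC]:Day[d1]", "Group[NCBT]:Day[d1]", "Group[NCBC]:Day[d1]",
    "Group[NTBC]:Day[d2]", "Group[NCBT]:Day[d2]", "Group[NCBC]:Day[d2]",
    "Group[NTBC]:Day[d3]", "Group[NCBT]:Day[d3]", "Group[NCBC]:Day[d3]",
)

N_COEF = len(COEF_NAMES)

# Fixed-effect estimates, random-intercept SD and log-likelihood reported
# for the original 32-participant cohort; used as simulator defaults and as
# the input table for the published odds-ratio contrasts.
REFERENCE_BETA = np.array([
    0.0892,
    -0.0000, 0.0315, -0.0472,
    1.0430, 0.9467, 1.0790,
    -0.7617, -0.8309, -0.9646,
    -0.3681, -0.3526, -0.6232,
    -0.5295, -0.6297, -0.8255,
])
REFERENCE_SIGMA_U = 0.1525
REFERENCE_LOGLIK = -817.0


def group_nf(group: str) -> str:
    """Neurofeedback factor level of a group: genuine (NT*) or sham (NC*)."""
    _check_group(group)
    return "genuine" if group.startswith("NT") else "sham"


def group_bt(group: str) -> str:
    """Behavioral-training factor level: feedback (*BT) or none (*BC)."""
    _check_group(group)
    return "feedback" if group.endswith("BT") else "none"


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}")


def design_row(group: str, day: str) -> np.ndarray:
    """Dummy-coded fixed-effect row for one (group, day) cell."""
    _check_group(group)
    if day not in DAYS:
        raise ParameterError(f"unknown day {day!r}")
    x = np.zeros(N_COEF)
    x[0] = 1.0
    gi = GROUPS.index(group)   # 0 is the reference NTBT
    di = DAYS.index(day)       # 0 is the reference pre
    if gi > 0:
        x[gi] = 1.0
    if di > 0:
        x[3 + di] = 1.0
    if gi > 0 and di > 0:
        x[7 + (di - 1) * 3 + (gi - 1)] = 1.0
    return x


def cell_logit(beta: np.ndarray, group: str, day: str, u: float = 0.0) -> float:
    """Linear predictor of one design cell plus a random intercept."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (N_COEF,):
        raise ParameterError(f"beta must have length {N_COEF}")
    return float(design_row(group, day) @ beta + u)


def logistic(eta):
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))
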