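"""Test-retest reliability: ICC(3,1) with confidence intervals.

The intra-class correlation ICC(3,1) — two-way mixed/fixed model, single
measure, consistency — is computed from the two-way ANOVA decomposition of
an (subjects x sessions) score table:

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) * MS_E)

where ``MS_R`` is the between-subject mean square, ``MS_E`` the residual
(error) mean square after removing subject and session main effects, and
``k`` the number of sessions per subject (2 here).  Consistency ICC is
insensitive to additive session effects.  Confidence limits and the
p-value come from the F ratio ``MS_R / MS_E`` with (n-1) and (n-1)(k-1)
degrees of freedom (Shrout & Fleiss).  Negative point estimates are kept
in ``icc`` and clipped to 0 in ``icc_clipped`` for interpretation against
the conventional poor/fair/good/excellent bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScorePair",
    "ICCResult",
    "icc_3_1",
    "icc_from_pairs",
    "classify_reliability",
]

#: Interpretation bands, applied to the clipped ICC as contiguous
#: half-open intervals: poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent.
CATEGORY_EDGES = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"))


@dataclass(frozen=True)
class ScorePair:
    """One subject's metric value in both sessions for one analysis cell."""

    subject_id: int
    session1_value: float
    session2_value: float
    metric: str = ""
    method: str = ""
    n_epochs: Optional[int] = None
    epoch_length: Optional[float] = None


@dataclass(frozen=True)
class ICCResult:
    """ICC(3,1) point estimate with 95% CI, p-value and category."""

    icc: float
    icc_clipped: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    category: str


def classify_reliability(icc_clipped: float) -> str:
    """Map a clipped ICC in [0, 1] to poor/fair/good/excellent."""
    if not 0.0 <= icc_clipped <= 1.0:
        raise ValueError("icc_clipped must lie in [0, 1]")
    for edge, name in CATEGORY_EDGES:
        if icc_clipped < edge:
            return name
    return "excellent"


def icc_3_1(scores, confidence: float = 0.95) -> ICCResult:
    """ICC(3,1) of an (n_subjects x k_sessions) score table.

    Requires at least 3 subjects and 2 sessions, all values finite.  A
    fully constant table (zero between- and within-subject variance) is
    reported as ICC 1 with a degenerate CI and logged.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("scores must be (n_subjects, k>=2 sessions)")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("scores contain non-finite values")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_r = ss_rows / df_rows
    ms_e = max(ss_err / df_err, 0.0)  # guard tiny negative round-off

    if ms_r == 0.0 and ms_e == 0.0:
        logger.info("constant score table: ICC defined as 1, degenerate CI")
        return ICCResult(icc=1.0, icc_clipped=1.0, ci_low=1.0, ci_high=1.0,
                         p_value=float("nan"), n_subjects=n,
                         category="excellent")

    if ms_e == 0.0:
        icc = 1.0
        ci = (1.0, 1.0)
        p = 0.0
    else:
        f_obs = ms_r / ms_e
        icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
        alpha = 1.0 - confidence
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df_rows, df_err)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df_err, df_rows)
        ci = ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))
        p = float(stats.f.sf(f_obs, df_rows, df_err))

    clipped = max(icc, 0.0)
    return ICCResult(icc=float(icc), icc_clipped=float(clipped),
                     ci_low=float(ci[0]), ci_high=float(ci[1]),
                     p_value=p, n_subjects=n,
                     category=classify_reliability(min(clipped, 1.0)))


def icc_from_pairs(pairs: Sequence[ScorePair],
                   confidence: float = 0.95) -> ICCResult:
    """ICC(3,1) from a list of per-subject session-1/session-2 score pairs."""
    table = np.array([[p.session1_value, p.session2_value] for p in pairs])
    return icc_3_1(table, confidence=confidence)
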