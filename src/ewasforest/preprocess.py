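"""Beta -> M transformation and skew-adjusted boxplot outlier trimming.

M-values (log2 odds of methylation) approximate normality far better than
raw beta proportions and are the modelling scale for the per-CpG logistic
regressions.  Before those fits, strong outliers are removed per CpG with
the adjusted boxplot of Hubert & Vandervieren, whose fences stretch with
the medcouple, a robust skewness statistic, so that skewed but clean
methylation distributions are not over-trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.stattools import medcouple as _sm_medcouple

from .data import BetaMatrix, MValueMatrix


def beta_to_m(beta: BetaMatrix) -> MValueMatrix:
    """Elementwise M = log2(beta / (1 - beta)); missing values propagate."""
    vals = beta.values
    frame = beta.frame.copy()
    frame.iloc[:, :] = np.log2(vals / (1.0 - vals))
    return MValueMatrix(frame, copy=False)


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse transform beta = 2^M / (1 + 2^M)."""
    vals = m.values
    frame = m.frame.copy()
    frame.iloc[:, :] = 1.0 / (1.0 + np.exp2(-vals))
    return BetaMatrix(frame, copy=False)


def medcouple(x, with_flag: bool = False):
    """Medcouple robust skewness of a 1-d sample, in [-1, 1].

    The medcouple is the median of the kernel
    ``h(x_i, x_j) = ((x_j - m) - (m - x_i)) / (x_j - x_i)`` over all pairs
    with ``x_i <= m <= x_j`` (m the sample median), with the standard
    sign-based kernel for observations tied with the median.  Missing
    values are dropped; at least three non-missing values are required.

    A sample whose values are all identical is degenerate: the statistic is
    defined as 0 and, with ``with_flag=True``, flagged.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("medcouple needs at least 3 non-missing values")
    degenerate = bool(np.ptp(x) == 0)
    mc = 0.0 if degenerate else float(_sm_medcouple(x))
    if with_flag:
        return mc, degenerate
    return mc


@dataclass
class Fences:
    """Adjusted-boxplot fences for one sample/CpG."""

    lower: float
    upper: float
    medcouple: float
    degenerate: bool = False


def adjusted_fences(x) -> Fences:
    """Hubert-Vandervieren skew-adjusted boxplot fences.

    With quartiles Q1, Q3 (linear / type-7 interpolation), IQR = Q3 - Q1
    and MC the medcouple:

    * MC >= 0: ``[Q1 - 1.5 exp(-4 MC) IQR,  Q3 + 1.5 exp(3 MC) IQR]``
    * MC <  0: ``[Q1 - 1.5 exp(-3 MC) IQR,  Q3 + 1.5 exp(4 MC) IQR]``

    MC = 0 recovers the classical Tukey fences.  A zero IQR is degenerate
    and returns ``[Q1, Q3]`` with the flag set.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError("adjusted fences need at least 4 non-missing values")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    mc, degenerate = medcouple(x, with_flag=True)
    if iqr == 0.0:
        return Fences(lower=float(q1), upper=float(q3), medcouple=mc, degenerate=True)
    if mc >= 0:
        lower = q1 - 1.5 * np.exp(-4.0 * mc) * iqr
        upper = q3 + 1.5 * np.exp(3.0 * mc) * iqr
    else:
        lower = q1 - 1.5 * np.exp(-3.0 * mc) * iqr
        upper = q3 + 1.5 * np.exp(4.0 * mc) * iqr
    return Fences(lower=float(lower), upper=float(upper), medcouple=mc, degenerate=degenerate)


@dataclass
class TrimReport:
    """Per-CpG record of adjusted-boxplot trimming."""

    cpg_id: str
    n_trimmed_low: int
    n_trimmed_high: int
    lower_fence: float
    upper_fence: float
    medcouple: float
    skipped: bool = False
    degenerate: bool = False


def trim_outliers(m: MValueMatrix) -> tuple[MValueMatrix, list[TrimReport]]:
    """Set M-values outside the per-CpG adjusted fences to missing.

    Trimming is applied per CpG across the full analysis sample (not within
    case/control strata).  Columns with fewer than 4 non-missing values are
    skipped and flagged; the input matrix is left unmodified.
    """
    frame = m.frame.copy()
    vals = frame.to_numpy()
    reports: list[TrimReport] = []
    for j, cpg in enumerate(frame.columns):
        col = vals[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 4:
            reports.append(
                TrimReport(cpg, 0, 0, np.nan, np.nan, np.nan, skipped=True)
            )
            continue
        fences = adjusted_fences(col[obs])
        low = obs & (col < fences.lower)
        high = obs & (col > fences.upper)
        col[low | high] = np.nan
        reports.append(
            TrimReport(
                cpg_id=cpg,
                n_trimmed_low=int(low.sum()),
                n_trimmed_high=int(high.sum()),
                lower_fence=fences.lower,
                upper_fence=fences.upper,
                medcouple=fences.medcouple,
                degenerate=fences.degenerate,
            )
        )
    frame.iloc[:, :] = vals
    return MValueMatrix(frame, copy=False), reports


def trim_report_frame(reports: list[TrimReport]):
    """Tabulate a list of :class:`TrimReport` as a DataFrame."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in reports]).set_index("cpg_id")
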