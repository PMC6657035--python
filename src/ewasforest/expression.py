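"""Cord-blood expression normalization and the DNAm-expression-wheeze models.

Expression arrays are percentile-shift normalized: each sample's stated
percentile (75th by convention) of log2 intensities is subtracted so that
the anchor percentile of every sample is exactly zero, removing per-array
brightness differences.  The follow-up couples methylation at a candidate
CpG with the expression of its gene (Spearman) and models infant wheeze
with nested logistic regressions: crude; adjusted for infant sex and
season of birth; and further adjusted for cord-blood cell fractions
(nucleated red blood cells retained, granulocytes the omitted reference).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .association import DROPPED_CELL_TYPE, AssociationResult, fit_logistic, results_to_frame
from .data import SEASONS, CellProportions, ExpressionMatrix, PhenotypeTable

logger = logging.getLogger(__name__)


def percentile_shift_normalize(
    raw_log2: ExpressionMatrix, percentile: float = 75.0
) -> ExpressionMatrix:
    """Subtract each sample's percentile (type-7 interpolation) from its values.

    Idempotent and invariant to per-sample constant shifts; after
    normalization the per-sample anchor percentile equals 0 exactly.
    """
    vals = raw_log2.values
    if vals.shape[1] < 2:
        raise ValueError("percentile-shift normalization needs at least 2 probes per sample")
    anchors = np.nanpercentile(vals, percentile, axis=1, keepdims=True)
    frame = raw_log2.frame.copy()
    frame.iloc[:, :] = vals - anchors
    return ExpressionMatrix(frame, copy=False)


def dnam_expression_correlation(m, expr, min_pairs: int = 10) -> tuple[float, float]:
    """Spearman rho and asymptotic p between one CpG's M-values and one probe."""
    m = pd.Series(m).astype(float)
    expr = pd.Series(expr).astype(float)
    if m.index.equals(expr.index):
        paired = pd.concat([m, expr], axis=1, join="inner").dropna()
    else:
        paired = pd.DataFrame({"m": m.to_numpy(), "e": expr.to_numpy()}).dropna()
    if len(paired) < min_pairs:
        raise ValueError(f"need at least {min_pairs} paired complete observations")
    if paired.iloc[:, 0].nunique() < 2 or paired.iloc[:, 1].nunique() < 2:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
    return float(rho), float(p)


def _season_dummies(season: pd.Series) -> pd.DataFrame:
    """Dummy-code season of birth with winter as the reference level."""
    season = season.astype("object")
    present = [s for s in SEASONS if (season == s).any()]
    empty = [s for s in SEASONS if s not in present]
    if empty:
        warnings.warn(f"season_of_birth levels absent and dropped: {empty}", stacklevel=2)
    dummies = {}
    for s in present:
        if s == "winter":
            continue  # reference
        dummies[f"season_{s}"] = (season == s).astype(float)
    return pd.DataFrame(dummies, index=season.index)


def fit_wheeze_models(
    predictor: pd.Series,
    phenotypes: PhenotypeTable,
    cord_props: CellProportions | None = None,
    outcomes: tuple[str, ...] = ("wheeze_no_cold", "any_wheeze"),
    predictor_id: str = "predictor",
) -> pd.DataFrame:
    """Nested logistic models of infant wheeze on one predictor.

    Three models per outcome: ``crude``; ``adjusted1`` adding infant sex
    and season of birth; ``adjusted2`` further adding cord cell fractions
    (granulocytes dropped, nRBC retained).  The predictor may be a CpG's
    M-values or a probe's log2 expression; ORs are per 1 unit.
    """
    pf = phenotypes.frame
    predictor = pd.Series(predictor).astype(float)
    if set(predictor.index.astype(str)) <= set(pf.index):
        predictor.index = predictor.index.astype(str)
    else:  # positional alignment with the phenotype table
        predictor.index = pf.index
    ids = predictor.index

    adj1 = [pf.loc[ids, "sex"].astype(float).rename("sex")]
    if "season_of_birth" in pf.columns:
        adj1.append(_season_dummies(pf.loc[ids, "season_of_birth"]))
    adj1_frame = pd.concat(adj1, axis=1)
    covs = {"crude": None, "adjusted1": adj1_frame}
    if cord_props is not None:
        cells = cord_props.frame.loc[ids].drop(columns=[DROPPED_CELL_TYPE], errors="ignore")
        covs["adjusted2"] = pd.concat([adj1_frame, cells], axis=1)

    results: list[AssociationResult] = []
    for outcome in outcomes:
        if outcome not in pf.columns or pf.loc[ids, outcome].isna().all():
            logger.info("outcome %r unavailable; skipped", outcome)
            continue
        y = pf.loc[ids, outcome].to_numpy(dtype=float)
        for model, cov in covs.items():
            res = fit_logistic(
                y,
                predictor.to_numpy(),
                cov.reset_index(drop=True) if cov is not None else None,
                cpg_id=predictor_id,
                model_kind=model,
            )
            res.model_kind = f"{outcome}:{model}"
            results.append(res)
    frame = results_to_frame(results)
    if not frame.empty:
        frame[["outcome", "model"]] = frame["model_kind"].str.split(":", expand=True)
    return frame
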