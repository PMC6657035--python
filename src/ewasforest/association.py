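"""Per-CpG association models, FDR control and replication assessment.

Stage-2 of the discovery pipeline regresses asthma status on the M-values
of each selected CpG with logistic regression, crude and adjusted for sex
and estimated cell-type proportions; odds ratios are per 1-unit M-value.
The traditional single-stage EWAS instead regresses beta values on asthma
status with ordinary least squares.  False-discovery control uses Storey
q-values with the lambda-grid cubic-smoother pi0 estimate; with pi0 = 1
the q-values reduce exactly to Benjamini-Hochberg step-up adjusted
p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import BetaMatrix, CellProportions, MValueMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

#: Cell type dropped from adjusted models: the seven blood fractions sum to
#: one, so including all of them with an intercept is rank-deficient.  The
#: granulocyte component (the largest) is the omitted reference.
DROPPED_CELL_TYPE = "Gran"


@dataclass
class AssociationResult:
    """Per-feature model output."""

    cpg_id: str
    model_kind: str
    coefficient: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    converged: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def _design_frame(x: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    parts = [x.rename("x")]
    if covariates is not None:
        parts.append(covariates)
    design = pd.concat(parts, axis=1)
    return design


def fit_logistic(
    y,
    x,
    covariates: pd.DataFrame | None = None,
    *,
    cpg_id: str = "x",
    model_kind: str = "logistic_crude",
) -> AssociationResult:
    """Maximum-likelihood logistic fit of a binary outcome on one predictor.

    Complete cases only; OR = exp(coefficient) with a Wald 95% CI.  Perfect
    or quasi-complete separation is flagged (``converged=False``) and the
    result retained with missing estimates rather than raised.
    """
    y = pd.Series(np.asarray(y, dtype=float), name="y").reset_index(drop=True)
    x = pd.Series(np.asarray(x, dtype=float), name="x").reset_index(drop=True)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
    design = _design_frame(x, covariates)
    keep = y.notna() & design.notna().all(axis=1)
    n_used = int(keep.sum())
    yk = y[keep].to_numpy()
    if len(np.unique(yk)) < 2:
        raise ValueError("outcome has a single class among complete cases")
    X = sm.add_constant(design[keep].to_numpy(), has_constant="add")
    converged = True
    params = bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yk, X).fit(disp=0, maxiter=100)
            params = res.params
            bse = res.bse
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # PerfectSeparationError and numerical failures
            converged = False
    if params is not None and (not np.all(np.isfinite(bse)) or np.abs(params).max() > 50):
        converged = False  # quasi-complete separation: exploding estimates
    if not converged or params is None:
        return AssociationResult(
            cpg_id=cpg_id,
            model_kind=model_kind,
            coefficient=np.nan,
            or_value=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            p_value=np.nan,
            n_used=n_used,
            converged=False,
        )
    coef = float(params[1])
    se = float(bse[1])
    z = coef / se if se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        cpg_id=cpg_id,
        model_kind=model_kind,
        coefficient=coef,
        or_value=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        p_value=p,
        n_used=n_used,
        converged=True,
    )


def adjustment_covariates(
    phenotypes: PhenotypeTable,
    cell_props: CellProportions | None,
    sample_ids,
    include_sex: bool = True,
) -> pd.DataFrame:
    """Sex + cell-fraction covariate frame (granulocytes dropped)."""
    parts = []
    if include_sex:
        parts.append(phenotypes.frame.loc[sample_ids, "sex"].astype(float))
    if cell_props is not None:
        cells = cell_props.frame.loc[sample_ids]
        cells = cells.drop(columns=[DROPPED_CELL_TYPE], errors="ignore")
        parts.append(cells)
    if not parts:
        raise ValueError("no covariates requested")
    return pd.concat(parts, axis=1)


def logistic_ewas(
    m: MValueMatrix,
    phenotypes: PhenotypeTable,
    cpgs: list[str] | None = None,
    cell_props: CellProportions | None = None,
    adjusted: bool = False,
    outcome: str = "asthma",
) -> pd.DataFrame:
    """Crude or sex+cell-adjusted logistic models across a CpG set."""
    cpgs = list(cpgs) if cpgs is not None else m.cpg_ids
    ids = m.sample_ids
    y = phenotypes.frame.loc[ids, outcome]
    covariates = (
        adjustment_covariates(phenotypes, cell_props, ids) if adjusted else None
    )
    kind = "logistic_adjusted" if adjusted else "logistic_crude"
    results = [
        fit_logistic(
            y.to_numpy(),
            m.frame.loc[ids, cpg].to_numpy(),
            covariates,
            cpg_id=cpg,
            model_kind=kind,
        )
        for cpg in cpgs
    ]
    return results_to_frame(results)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns loading on the null space
        _, s, vt = np.linalg.svd(X)
        null_vec = np.abs(vt[-1][1:])  # skip intercept entry
        involved = [c for c, w in zip(design.columns, null_vec) if w > 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {involved}")


def ewas_linear(
    beta: BetaMatrix,
    y,
    covariates: pd.DataFrame | None = None,
    cpgs: list[str] | None = None,
) -> pd.DataFrame:
    """Traditional EWAS: per-CpG OLS of beta values on asthma status.

    The methylation proportion is the dependent variable; the coefficient
    is the mean beta difference (asthma vs not) conditional on covariates,
    with p from the t-statistic.  Complete-case per CpG.
    """
    cpgs = list(cpgs) if cpgs is not None else beta.cpg_ids
    y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        _check_full_rank(pd.concat([y.rename("y"), covariates], axis=1))
    design = _design_frame(y.rename("x"), covariates)
    rows = []
    vals = beta.frame[cpgs].to_numpy()
    design_ok = design.notna().all(axis=1).to_numpy()
    D = design.to_numpy(dtype=float)
    for j, cpg in enumerate(cpgs):
        b = vals[:, j]
        keep = design_ok & ~np.isnan(b)
        n_used = int(keep.sum())
        X = sm.add_constant(D[keep], has_constant="add")
        res = sm.OLS(b[keep], X).fit()
        rows.append(
            {
                "cpg_id": cpg,
                "model_kind": "linear_adjusted" if covariates is not None else "linear_crude",
                "coefficient": float(res.params[1]),
                "or_value": np.nan,
                "ci_low": float(res.conf_int()[1][0]),
                "ci_high": float(res.conf_int()[1][1]),
                "p_value": float(res.pvalues[1]),
                "n_used": n_used,
                "converged": True,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


@dataclass
class QValueSet:
    feature_ids: list[str]
    p_values: np.ndarray
    q_values: np.ndarray
    pi0: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cpg_id": self.feature_ids, "p_value": self.p_values, "q_value": self.q_values}
        )


def _cubic_smoothing_spline_fit(x: np.ndarray, y: np.ndarray, df: float = 3.0) -> np.ndarray:
    """Natural cubic smoothing spline fitted values with a target effective df.

    Solves min sum (y - f(x))^2 + alpha * integral f''^2 over natural cubic
    splines with knots at the x values (Reinsch form); alpha is found by
    bisection so that trace of the smoother matrix equals ``df``.
    """
    n = x.size
    h = np.diff(x)
    # second-difference matrix D ((n-2) x n) and weight matrix W ((n-2) x (n-2))
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    K = D.T @ np.linalg.solve(W, D)

    def trace_df(log_alpha: float) -> float:
        S = np.linalg.inv(np.eye(n) + np.exp(log_alpha) * K)
        return float(np.trace(S))

    lo, hi = -20.0, 20.0  # df(lo) ~ n, df(hi) ~ 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if trace_df(mid) > df:
            lo = mid
        else:
            hi = mid
    alpha = np.exp(0.5 * (lo + hi))
    return np.linalg.solve(np.eye(n) + alpha * K, y)


def estimate_pi0(p: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #(p > lambda) / (m (1 - lambda)) is evaluated on the grid
    lambda = 0.05, 0.10, ..., 0.95; a cubic smoothing spline with 3
    effective degrees of freedom is fitted and read off at the right end
    of the grid; the result is clamped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    fitted = _cubic_smoothing_spline_fit(lambdas, pi0_lambda, df=3.0)
    return float(np.clip(fitted[-1], 1.0 / m, 1.0))


def storey_qvalues(p_values, feature_ids=None, pi0: float | None = None) -> QValueSet:
    """Storey q-values; with pi0 = 1 these equal BH step-up adjusted p.

    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over the sorted p-values.
    For fewer than 100 features pi0 estimation is unstable, so pi0 is fixed
    at 1 (Benjamini-Hochberg fallback, logged).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if feature_ids is None:
        feature_ids = [f"p{i}" for i in range(p.size)]
    m = p.size
    if pi0 is None:
        if m < 100:
            logger.info("m=%d < 100: pi0 fixed at 1 (BH fallback)", m)
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    # evaluated as p / (i/m): the BH step-up factor in its canonical form
    ranked = pi0 * (p[order] / (np.arange(1, m + 1) / m))
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return QValueSet(feature_ids=list(feature_ids), p_values=p, q_values=q, pi0=float(pi0))


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------


def assess_replication(
    discovery: pd.DataFrame, replication: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Compare discovery and replication models CpG by CpG.

    Joins on (cpg_id, model_kind); a replication is direction-consistent
    when the log-OR signs agree (only computable when both fits converged)
    and significant when its p-value is strictly below ``alpha``.
    """
    merged = discovery.merge(
        replication, on=["cpg_id", "model_kind"], suffixes=("_disc", "_rep")
    )
    if merged.empty:
        raise ValueError("no overlapping CpG/model pairs between discovery and replication")
    both_ok = merged["converged_disc"] & merged["converged_rep"]
    direction = np.sign(np.log(merged["or_value_disc"])) == np.sign(
        np.log(merged["or_value_rep"])
    )
    out = pd.DataFrame(
        {
            "cpg_id": merged["cpg_id"],
            "model_kind": merged["model_kind"],
            "discovery_or": merged["or_value_disc"],
            "replication_or": merged["or_value_rep"],
            "replication_p": merged["p_value_rep"],
            "direction_consistent": direction.where(both_ok),
            "replication_significant": (merged["p_value_rep"] < alpha).where(both_ok),
            "alpha": alpha,
        }
    )
    return out


def replication_summary(assessment: pd.DataFrame) -> dict:
    return {
        "n_pairs": int(len(assessment)),
        "n_direction_consistent": int(assessment["direction_consistent"].fillna(False).sum()),
        "n_replicated": int(
            (
                assessment["direction_consistent"].fillna(False)
                & assessment["replication_significant"].fillna(False)
            ).sum()
        ),
    }


# ---------------------------------------------------------------------------
# Phenotype correlations
# ---------------------------------------------------------------------------


def phenotype_correlations(
    m: pd.Series,
    phenotypes: PhenotypeTable,
    cell_props: CellProportions | None = None,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Cross-sectional report for one CpG's M-values.

    Spearman correlations of M with log(FeNO), FEV1/FVC, FEF25-75 and each
    estimated cell fraction, plus a Welch t-test of M by atopy.  FeNO is
    log-transformed before correlating.  Contrasts with fewer than
    ``min_pairs`` paired observations or zero variance are flagged and
    their statistic omitted.
    """
    m = pd.Series(m).astype(float)
    pf = phenotypes.frame
    rows = []

    def spearman_row(name: str, other: pd.Series):
        paired = pd.concat([m, other.astype(float)], axis=1, join="inner").dropna()
        n = len(paired)
        if n < min_pairs or paired.iloc[:, 0].nunique() < 2 or paired.iloc[:, 1].nunique() < 2:
            rows.append({"variable": name, "kind": "spearman", "estimate": np.nan,
                         "p_value": np.nan, "n": n, "flag": "insufficient_or_constant"})
            return
        rho, p = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
        rows.append({"variable": name, "kind": "spearman", "estimate": float(rho),
                     "p_value": float(p), "n": n, "flag": ""})

    if "feno" in pf.columns:
        spearman_row("log_feno", np.log(pf["feno"].where(pf["feno"] > 0)))
    for col in ("fev1_fvc", "fef2575"):
        if col in pf.columns:
            spearman_row(col, pf[col])
    if cell_props is not None:
        for cell in cell_props.cell_types:
            spearman_row(f"cell_{cell}", cell_props.frame[cell])

    if "atopy" in pf.columns:
        paired = pd.concat([m, pf["atopy"]], axis=1, join="inner").dropna()
        g1 = paired[paired.iloc[:, 1] == 1].iloc[:, 0]
        g0 = paired[paired.iloc[:, 1] == 0].iloc[:, 0]
        if min(len(g1), len(g0)) < max(2, min_pairs // 2) or paired.iloc[:, 0].nunique() < 2:
            rows.append({"variable": "atopy", "kind": "welch_t", "estimate": np.nan,
                         "p_value": np.nan, "n": len(paired), "flag": "insufficient_or_constant"})
        else:
            t, p = stats.ttest_ind(g1, g0, equal_var=False)
            rows.append({"variable": "atopy", "kind": "welch_t", "estimate": float(t),
                         "p_value": float(p), "n": len(paired), "flag": ""})
    return pd.DataFrame(rows)
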