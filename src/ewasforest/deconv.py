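"""Reference-based cell-type deconvolution from bulk methylation.

Bulk blood methylation is modelled as a convex combination of cell-type
mean-methylation profiles measured at a set of discriminating CpGs.  Each
sample's cell fractions are the solution of a least-squares projection onto
the probability simplex:

    min_w || beta_sample - P^T w ||^2   s.t.  w >= 0,  sum(w) = 1

with P the (cell type x CpG) reference profile.  The sum-to-one equality
constraint (rather than <= 1) is used because downstream regression models
treat the fractions as compositional covariates.

The solver enumerates active sets: for every support S of cell types it
solves the equality-constrained normal equations (a small KKT system,
factorized once and applied to all samples at once) and keeps, per sample,
the feasible candidate with the smallest residual.  With at most 8 cell
types this is exact — the global optimum's support is always one of the
enumerated subsets — and recovers noiseless mixtures to machine precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data import BetaMatrix, CellProportions

logger = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """Cell-type mean-beta profiles at discriminating CpGs.

    ``profile`` is a DataFrame with cell types as rows and CpGs as columns,
    values strictly in (0, 1).
    """

    panel_name: str
    profile: pd.DataFrame

    def __post_init__(self):
        if len(self.profile.index) < 2:
            raise ValueError("reference panel needs at least 2 cell types")
        vals = self.profile.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals <= 0).any() or (vals >= 1).any():
            raise ValueError("reference profile values must lie strictly in (0, 1)")

    @property
    def cell_types(self) -> list[str]:
        return self.profile.index.tolist()

    @property
    def cpg_ids(self) -> list[str]:
        return self.profile.columns.tolist()


def read_panel(path, panel_name: str = "adult7") -> ReferencePanel:
    """Read a panel TSV: rows = cell types, columns = CpGs."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ReferencePanel(panel_name=panel_name, profile=frame)


def write_panel(panel: ReferencePanel, path) -> None:
    panel.profile.to_csv(path, sep="\t", index_label="cell_type")


def select_discriminating_cpgs(
    profile_library: pd.DataFrame, k_per_type: int, panel_name: str = "adult7"
) -> ReferencePanel:
    """Pick, per cell type, the CpGs that best separate it from the rest.

    For each cell type the one-vs-rest F-statistic
    ``(x_t - mean_rest)^2 / var_rest`` is computed across the type profiles
    and the top ``k_per_type`` CpGs are taken, split evenly between
    hypermethylated (x_t above the rest) and hypomethylated directions when
    both directions offer enough candidates.  The union over types forms
    the panel.
    """
    if len(profile_library.index) < 2:
        raise ValueError("need at least 2 cell types")
    if k_per_type > profile_library.shape[1]:
        raise ValueError(
            f"k_per_type={k_per_type} exceeds available CpGs ({profile_library.shape[1]})"
        )
    lib = profile_library.to_numpy(dtype=float)
    n_types = lib.shape[0]
    if np.ptp(lib, axis=0).max() < 1e-8:
        raise ValueError("no discriminating CpGs: all cell-type profiles are identical")
    selected: list[str] = []
    seen: set[str] = set()
    for t in range(n_types):
        rest = np.delete(lib, t, axis=0)
        mu = rest.mean(axis=0)
        var = rest.var(axis=0, ddof=1) if n_types > 2 else np.zeros(lib.shape[1])
        diff = lib[t] - mu
        score = diff**2 / (var + 1e-12)
        order = np.argsort(-score, kind="stable")
        hyper = [j for j in order if diff[j] > 0]
        hypo = [j for j in order if diff[j] <= 0]
        k_hi = min(len(hyper), k_per_type - min(len(hypo), k_per_type // 2))
        k_lo = k_per_type - k_hi
        chosen = hyper[:k_hi] + hypo[:k_lo]
        if len(chosen) < k_per_type:
            raise ValueError(
                f"k_per_type={k_per_type} exceeds available CpGs for type "
                f"{profile_library.index[t]!r}"
            )
        for j in sorted(chosen):
            cpg = profile_library.columns[j]
            if cpg not in seen:
                seen.add(cpg)
                selected.append(cpg)
    return ReferencePanel(panel_name=panel_name, profile=profile_library[selected].copy())


def _simplex_lstsq_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A w - b||^2 s.t. w >= 0, sum w = 1 for each column b of B.

    Active-set enumeration: every support is a candidate; feasible candidates
    are compared by objective.  Exact for small numbers of cell types.
    """
    n_obs, T = A.shape
    n_samples = B.shape[1]
    G = A.T @ A
    ATB = A.T @ B  # T x n_samples
    best_obj = np.full(n_samples, np.inf)
    best_w = np.zeros((T, n_samples))
    ones = np.ones(1)
    for size in range(1, T + 1):
        for S in combinations(range(T), size):
            S = list(S)
            k = len(S)
            K = np.zeros((k + 1, k + 1))
            K[:k, :k] = 2.0 * G[np.ix_(S, S)]
            K[:k, k] = 1.0
            K[k, :k] = 1.0
            rhs = np.empty((k + 1, n_samples))
            rhs[:k] = 2.0 * ATB[S, :]
            rhs[k] = ones
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            W = sol[:k]
            feasible = (W >= -1e-9).all(axis=0)
            if not feasible.any():
                continue
            # objective ||Aw - b||^2 = b'b - 2 w'A'b + w'Gw ; b'b common, drop it
            obj = -2.0 * np.einsum("ts,ts->s", W, ATB[S, :]) + np.einsum(
                "ts,tu,us->s", W, G[np.ix_(S, S)], W
            )
            improve = feasible & (obj < best_obj - 1e-12)
            if improve.any():
                best_obj[improve] = obj[improve]
                best_w[:, improve] = 0.0
                Wi = np.clip(W[:, improve], 0.0, None)
                best_w[np.ix_(S, np.flatnonzero(improve))] = Wi
    # renormalize away the <=1e-9 feasibility slack
    best_w /= best_w.sum(axis=0, keepdims=True)
    return best_w


def estimate_proportions(
    beta: BetaMatrix, panel: ReferencePanel, min_coverage: float = 0.8
) -> CellProportions:
    """Estimate per-sample cell fractions by constrained projection.

    Panel CpGs absent from ``beta`` are dropped with a warning; below
    ``min_coverage`` (fraction of panel CpGs observed, overall or within a
    sample) estimation refuses.  Samples with missing values at some panel
    CpGs are solved over their observed subset.
    """
    panel_cpgs = panel.cpg_ids
    present = [c for c in panel_cpgs if c in set(beta.cpg_ids)]
    if len(present) < min_coverage * len(panel_cpgs):
        raise ValueError(
            f"only {len(present)}/{len(panel_cpgs)} panel CpGs present in beta matrix "
            f"(< {min_coverage:.0%} coverage)"
        )
    if len(present) < len(panel_cpgs):
        warnings.warn(
            f"{len(panel_cpgs) - len(present)} panel CpGs missing from beta matrix; dropped",
            stacklevel=2,
        )
    A = panel.profile[present].to_numpy(dtype=float).T  # cpgs x types
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("singular profile matrix: cell-type profiles are collinear")
    X = beta.frame[present].to_numpy(dtype=float).T  # cpgs x samples
    obs = ~np.isnan(X)
    complete = obs.all(axis=0)
    W = np.zeros((A.shape[1], X.shape[1]))
    if complete.any():
        W[:, complete] = _simplex_lstsq_batch(A, X[:, complete])
    for s in np.flatnonzero(~complete):
        keep = obs[:, s]
        if keep.sum() < min_coverage * len(panel_cpgs):
            raise ValueError(
                f"sample {beta.sample_ids[s]!r} observes {int(keep.sum())}/"
                f"{len(panel_cpgs)} panel CpGs (< {min_coverage:.0%} coverage)"
            )
        W[:, [s]] = _simplex_lstsq_batch(A[keep], X[keep][:, [s]])
    frame = pd.DataFrame(W.T, index=beta.frame.index, columns=panel.cell_types)
    return CellProportions(frame, panel_name=panel.panel_name)
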