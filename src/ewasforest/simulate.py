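"""Seeded synthetic methylation cohorts with recoverable ground truth.

The generator emulates the data structure the analysis assumes: a
sample x CpG beta matrix arising as a cell-composition-weighted mixture of
cell-type methylation profiles, phenotypes with realistic case/control
contrasts, a shifted eosinophil (or, for cord blood, nucleated-red-blood-
cell) fraction among cases, a handful of planted asthma-associated CpGs
whose case effect acts on the M scale, and one expression probe coupled
(negatively, by default) to the first planted CpG.

Mechanics, per sample:

1. cell composition ~ Dirichlet whose shifted-cell component is re-centred
   so the empirical case/control means hit their targets exactly;
2. bulk mean beta = composition-weighted mixture of cell-type profiles;
3. on the M scale, non-reference CpGs receive per-sample biological noise
   (sd ``bio_m_sd``) and planted CpGs an additional case shift
   (``planted_effect``; negative values = cases hypomethylated);
4. the measured beta is Beta-distributed around the mixed mean with
   concentration ``beta_precision`` (moment-matched measurement noise that
   keeps values inside (0, 1) with realistic heteroscedasticity).

All randomness flows from seeded generators (one for cohort structure,
one for sample-level draws), so identical seeds give byte-identical
outputs, and two cohorts built with the same ``structure_seed`` but
different ``rng_seed`` share planted truth and profiles — the setting for
replication experiments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .data import (
    EPS,
    PANELS,
    SEASONS,
    SHIFTED_CELL,
    BetaMatrix,
    CellProportions,
    ExpressionMatrix,
    PhenotypeTable,
    write_matrix,
    write_phenotypes,
    write_proportions,
)
from .deconv import ReferencePanel, select_discriminating_cpgs, write_panel

#: Default Dirichlet mean fractions (sum to one) per panel; the adult means
#: follow typical whole-blood leukocyte differentials among non-asthmatic
#: adolescents, the cord means a typical cord-blood composition with nRBCs.
_DEFAULT_MEANS = {
    "adult7": {"CD8T": 0.098, "CD4T": 0.110, "NK": 0.070, "B": 0.039,
               "Mono": 0.074, "Eos": 0.021, "Gran": 0.588},
    "cord7": {"CD8T": 0.05, "CD4T": 0.15, "NK": 0.04, "B": 0.05,
              "Mono": 0.07, "Gran": 0.54, "nRBC": 0.10},
}

#: Dirichlet total concentration; 30 reproduces the observed dispersion of
#: estimated fractions (e.g. granulocyte sd ~0.11, control eosinophil sd ~0.026).
_DIRICHLET_TOTAL = 30.0


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the adolescent discovery cohort: 370 samples, 13.9%
    asthma prevalence, 66.2% female, case/control eosinophil means
    0.045/0.021.  ``planted_effect`` (case shift on the M scale) and
    ``bio_m_sd`` (per-sample biological M noise) are calibrated so crude
    per-unit-M odds ratios at planted CpGs fall in the 0.1-0.4 range;
    ``beta_precision`` sets the Beta measurement noise (sd ~0.02 at
    beta = 0.5).
    """

    n_samples: int = 370
    n_cpgs: int = 5000
    prevalence: float = 0.139
    prop_female: float = 0.662
    panel_name: str = "adult7"
    dirichlet_base: dict[str, float] | None = None
    eos_mean_case: float = 0.045
    eos_mean_control: float = 0.021
    n_discriminating_cpgs_per_type: int = 50
    n_planted_cpgs: int = 10
    planted_effect: float = -1.5
    bio_m_sd: float = 1.0
    beta_precision: float = 600.0
    n_expression_probes: int = 50
    expr_dnam_rho: float = -0.22
    wheeze_expr_log_or: float = 1.1
    wheeze_base_rate: float = 0.30
    any_wheeze_extra_rate: float = 0.20
    rng_seed: int = 0
    structure_seed: int | None = None
    label: str = "synthetic"

    def __post_init__(self):
        for name in ("prevalence", "prop_female"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.panel_name not in PANELS:
            raise ValueError(f"unknown panel {self.panel_name!r}")
        for name in ("n_samples", "n_cpgs", "n_discriminating_cpgs_per_type",
                     "n_expression_probes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_cpgs < 0:
            raise ValueError("n_planted_cpgs must be >= 0")
        n_types = len(PANELS[self.panel_name])
        n_disc = n_types * self.n_discriminating_cpgs_per_type
        if self.n_cpgs < n_disc + self.n_planted_cpgs + 1:
            raise ValueError("n_cpgs too small for the requested reference and planted CpGs")

    def null(self) -> "SimulationConfig":
        """A copy with no planted effect and no composition shift (global null)."""
        return replace(self, planted_effect=0.0, eos_mean_case=self.eos_mean_control)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticCohort:
    """A generated cohort plus its retained ground truth."""

    beta: BetaMatrix
    phenotypes: PhenotypeTable
    true_proportions: CellProportions
    reference_panel: ReferencePanel
    expression: ExpressionMatrix
    truth: pd.DataFrame  # columns: cpg_id, effect
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self):
        ids = self.beta.sample_ids
        for other in (self.phenotypes.sample_ids, self.true_proportions.sample_ids,
                      self.expression.sample_ids):
            if other != ids:
                raise ValueError("cohort components must share sample_ids in order")
        missing = set(self.truth["cpg_id"]) - set(self.beta.cpg_ids)
        if missing:
            raise ValueError(f"planted truth CpGs not in beta matrix: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.beta.sample_ids

    def subset(self, sample_ids) -> "SyntheticCohort":
        ids = list(sample_ids)
        return SyntheticCohort(
            beta=self.beta.subset(ids),
            phenotypes=self.phenotypes.subset(ids),
            true_proportions=self.true_proportions.subset(ids),
            reference_panel=self.reference_panel,
            expression=self.expression.subset(ids),
            truth=self.truth,
            config=self.config,
        )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _group_targets(cfg: SimulationConfig, base_mean: np.ndarray, i_shift: int):
    """Per-group Dirichlet mean vectors with the shifted cell at its target."""
    targets = {}
    for group, m_shift in (("case", cfg.eos_mean_case), ("control", cfg.eos_mean_control)):
        if not (0 < m_shift < 1):
            raise ValueError("infeasible composition targets: shifted mean outside (0, 1)")
        mean = base_mean.copy()
        scale = (1.0 - m_shift) / (1.0 - base_mean[i_shift])
        mean *= scale
        mean[i_shift] = m_shift
        if (mean <= 0).any() or (mean >= 1).any():
            raise ValueError("infeasible composition targets: means outside the simplex")
        targets[group] = mean
    return targets


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort; see the module docstring."""
    cfg = config
    types = list(PANELS[cfg.panel_name])
    n_types = len(types)
    k = cfg.n_discriminating_cpgs_per_type
    n, n_cpgs = cfg.n_samples, cfg.n_cpgs
    n_disc = n_types * k

    struct_seed = cfg.structure_seed if cfg.structure_seed is not None else cfg.rng_seed
    rs = np.random.default_rng([1, struct_seed])
    rng = np.random.default_rng([2, cfg.rng_seed])

    cpg_ids = np.array([f"cg{i:08d}" for i in range(n_cpgs)])
    sample_ids = [f"s{i:04d}" for i in range(n)]
    disc_idx = np.arange(n_disc)
    background_idx = np.arange(n_disc, n_cpgs)

    # --- cell-type profiles (structure RNG) -----------------------------
    profiles = np.empty((n_types, n_cpgs))
    base_beta = rs.uniform(0.10, 0.90, size=background_idx.size)
    profiles[:, background_idx] = base_beta  # identical across types
    for j in disc_idx:
        t = j // k
        low_in_type = (j % k) % 2 == 0
        target, others = (0.05, 0.95) if low_in_type else (0.95, 0.05)
        row = np.full(n_types, others)
        row[t] = target
        profiles[:, j] = np.clip(row + rs.uniform(-0.02, 0.02, size=n_types), 0.02, 0.98)
    planted_idx = np.sort(
        rs.choice(background_idx, size=cfg.n_planted_cpgs, replace=False)
    ) if cfg.n_planted_cpgs else np.array([], dtype=int)
    profiles[:, planted_idx] = rs.uniform(0.85, 0.93, size=planted_idx.size)

    # --- phenotypes (sample RNG) ----------------------------------------
    asthma = (rng.random(n) < cfg.prevalence).astype(int)
    sex = (rng.random(n) < cfg.prop_female).astype(int)
    atopy = (rng.random(n) < np.where(asthma == 1, 0.66, 0.295)).astype(int)
    feno = np.exp(np.log(np.where(asthma == 1, 21.0, 14.0)) + 0.7 * rng.normal(size=n))
    fev1_fvc = np.clip(rng.normal(np.where(asthma == 1, 0.83, 0.88), 0.07), 0.35, 1.0)
    fef2575 = np.clip(rng.normal(np.where(asthma == 1, 3.5, 3.9), 0.9), 0.5, None)
    season = np.array(SEASONS)[rng.integers(0, 4, size=n)]

    # --- cell composition -----------------------------------------------
    base = cfg.dirichlet_base or _DEFAULT_MEANS[cfg.panel_name]
    base_alpha = np.array([base[t] for t in types], dtype=float)
    alpha0 = base_alpha.sum()
    if abs(alpha0 - 1.0) < 1e-9:  # means given; use the default total concentration
        alpha0 = _DIRICHLET_TOTAL
    base_mean = base_alpha / base_alpha.sum()
    i_shift = types.index(SHIFTED_CELL[cfg.panel_name])
    targets = _group_targets(cfg, base_mean, i_shift)
    W = np.empty((n, n_types))
    for group, target in (("case", targets["case"]), ("control", targets["control"])):
        rows = np.flatnonzero(asthma == (1 if group == "case" else 0))
        if rows.size == 0:
            continue
        draws = rng.dirichlet(target * alpha0, size=rows.size)
        actual = draws[:, i_shift].mean()
        if actual > 0:
            shifted = draws[:, i_shift] * (target[i_shift] / actual)
            if shifted.max() >= 1.0:
                raise ValueError("infeasible composition targets: re-centring leaves the simplex")
            draws *= ((1.0 - shifted) / (1.0 - draws[:, i_shift]))[:, None]
            draws[:, i_shift] = shifted
        W[rows] = draws
    W /= W.sum(axis=1, keepdims=True)

    # --- bulk methylation ------------------------------------------------
    mu = np.clip(W @ profiles, EPS, 1.0 - EPS)
    M = np.log2(mu / (1.0 - mu))
    if cfg.bio_m_sd > 0:
        M[:, background_idx] += rng.normal(0.0, cfg.bio_m_sd, size=(n, background_idx.size))
    if planted_idx.size and cfg.planted_effect != 0.0:
        M[np.ix_(asthma == 1, planted_idx)] += cfg.planted_effect
    mu_noised = 1.0 / (1.0 + np.exp2(-M))
    if np.isfinite(cfg.beta_precision):
        nu = cfg.beta_precision
        observed = rng.beta(mu_noised * nu, (1.0 - mu_noised) * nu)
    else:
        observed = mu_noised
    observed = np.clip(observed, EPS, 1.0 - EPS)

    beta = BetaMatrix(pd.DataFrame(observed, index=sample_ids, columns=cpg_ids), copy=False)

    # --- expression -------------------------------------------------------
    probe_ids = [f"xp{i:05d}" for i in range(cfg.n_expression_probes)]
    expr_vals = 8.0 + rng.normal(size=(n, cfg.n_expression_probes))
    if planted_idx.size and cfg.expr_dnam_rho != 0.0:
        m_obs = np.log2(observed[:, planted_idx[0]] / (1.0 - observed[:, planted_idx[0]]))
        z = stats.norm.ppf((stats.rankdata(m_obs) - 0.5) / n)
        r = 2.0 * np.sin(np.pi * cfg.expr_dnam_rho / 6.0)  # Spearman -> Pearson on the copula
        expr_vals[:, 0] = 8.0 + r * z + np.sqrt(1.0 - r**2) * rng.normal(size=n)
    expression = ExpressionMatrix(
        pd.DataFrame(expr_vals, index=sample_ids, columns=probe_ids), copy=False
    )

    # --- infant wheeze (driven by the coupled expression probe) ----------
    expr0_centered = expr_vals[:, 0] - 8.0
    eta = _logit(cfg.wheeze_base_rate) + cfg.wheeze_expr_log_or * expr0_centered
    wheeze_no_cold = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    eta2 = _logit(cfg.any_wheeze_extra_rate) + 0.7 * cfg.wheeze_expr_log_or * expr0_centered
    any_wheeze = np.maximum(
        wheeze_no_cold, (rng.random(n) < 1.0 / (1.0 + np.exp(-eta2))).astype(int)
    )

    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {
                "asthma": asthma,
                "sex": sex,
                "atopy": atopy,
                "feno": feno,
                "fev1_fvc": fev1_fvc,
                "fef2575": fef2575,
                "wheeze_no_cold": wheeze_no_cold,
                "any_wheeze": any_wheeze,
                "season_of_birth": season,
                "cohort_label": cfg.label,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        copy=False,
    )
    true_props = CellProportions(
        pd.DataFrame(W, index=sample_ids, columns=types), panel_name=cfg.panel_name
    )
    panel = select_discriminating_cpgs(
        pd.DataFrame(profiles, index=types, columns=cpg_ids), k, panel_name=cfg.panel_name
    )
    truth = pd.DataFrame(
        {
            "cpg_id": cpg_ids[planted_idx],
            "effect": np.full(planted_idx.size, cfg.planted_effect),
        }
    )
    return SyntheticCohort(
        beta=beta,
        phenotypes=phenotypes,
        true_proportions=true_props,
        reference_panel=panel,
        expression=expression,
        truth=truth,
        config=cfg,
    )


def stratified_split_ids(
    phenotypes: PhenotypeTable, stage1_fraction: float, seed: int, stratify: str = "asthma"
) -> tuple[list[str], list[str]]:
    """Exhaustive, disjoint two-way split stratified by case status.

    Largest-remainder apportionment keeps each half's prevalence within one
    sample of the full cohort; the split is seeded and deterministic.
    """
    if not (0 < stage1_fraction < 1):
        raise ValueError("stage1_fraction must be in (0, 1)")
    frame = phenotypes.frame
    n = len(frame)
    total_target = int(round(n * stage1_fraction))
    strata = [np.asarray(ids) for _, ids in frame.groupby(stratify).groups.items()]
    if any(len(s) < 2 for s in strata):
        raise ValueError("each case/control stratum needs at least 2 samples to split")
    rng = np.random.default_rng(seed)
    exact = np.array([len(s) * stage1_fraction for s in strata])
    counts = np.floor(exact).astype(int)
    remainders = exact - counts
    short = total_target - counts.sum()
    for i in np.argsort(-remainders, kind="stable")[: max(short, 0)]:
        counts[i] += 1
    stage1: set = set()
    for s, c in zip(strata, counts):
        perm = rng.permutation(len(s))
        stage1.update(s[perm[:c]])
    all_ids = frame.index.tolist()
    ids1 = [i for i in all_ids if i in stage1]
    ids2 = [i for i in all_ids if i not in stage1]
    return ids1, ids2


def split_cohort(
    cohort: SyntheticCohort, stage1_fraction: float, seed: int
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Random stratified split into stage-1 and stage-2 sub-cohorts."""
    ids1, ids2 = stratified_split_ids(cohort.phenotypes, stage1_fraction, seed)
    return cohort.subset(ids1), cohort.subset(ids2)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write all cohort components as TSV (plus the config as YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "true_proportions": out / "true_proportions.tsv",
        "panel": out / "panel.tsv",
        "expression": out / "expression.tsv",
        "truth": out / "truth.tsv",
    }
    write_matrix(cohort.beta, paths["beta"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    write_proportions(cohort.true_proportions, paths["true_proportions"])
    write_panel(cohort.reference_panel, paths["panel"])
    write_matrix(cohort.expression, paths["expression"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    if cohort.config is not None:
        cohort.config.to_yaml(out / "simulation_config.yaml")
        paths["config"] = out / "simulation_config.yaml"
    return paths
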