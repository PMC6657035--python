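"""Orchestration of the discovery -> replication -> follow-up workflow.

Discovery: split the cohort into a feature-selection half and a larger
testing half (stratified by case status); run the recursive balanced
random forest on stage-1 M-values; trim outliers and fit crude and
cell/sex-adjusted logistic models per selected CpG on stage 2; control the
FDR with Storey q-values on the crude p-values; CpGs with q < threshold
form the discovery list.  Replication refits both models on an independent
cohort at the discovered CpGs and checks direction consistency and
significance against the full discovery cohort.  The follow-up cohort
(cord blood) adds the DNAm-expression correlation and nested wheeze
models.

Every run can write its intermediate artifacts plus a manifest (config
hash, seed, versions) sufficient to reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    assess_replication,
    logistic_ewas,
    replication_summary,
    storey_qvalues,
)
from .data import CellProportions, PhenotypeTable, summarize_phenotypes
from .deconv import estimate_proportions
from .expression import dnam_expression_correlation, fit_wheeze_models
from .preprocess import beta_to_m, trim_outliers, trim_report_frame
from .selection import RFConfig, SelectionTrace, recursive_select
from .simulate import SimulationConfig, SyntheticCohort, generate_cohort, split_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, split fraction and seeding for one pipeline run."""

    stage1_fraction: float = 91.0 / 370.0
    rf: RFConfig = field(default_factory=RFConfig)
    alpha: float = 0.05
    q_threshold: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def reproducible_dict(self) -> dict:
        """Config as a dict without the output location (not a computation input)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        return payload

    def config_hash(self) -> str:
        payload = json.dumps(self.reproducible_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    trace: SelectionTrace
    selected_cpgs: list[str]
    stage1_ids: list[str]
    stage2_ids: list[str]
    stage2_results: pd.DataFrame  # crude + adjusted AssociationResults
    qvalues: pd.DataFrame
    pi0: float
    discovered: list[str]
    proportions: CellProportions
    trim_reports: pd.DataFrame


def _manifest(config: PipelineConfig, extra: dict | None = None) -> dict:
    manifest = {
        "package_version": __version__,
        "config": config.reproducible_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    return manifest


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_discovery(cohort: SyntheticCohort, config: PipelineConfig) -> DiscoveryResult:
    """Split -> stage-1 recursive RF -> trim -> stage-2 logistic -> q < threshold.

    The discovery rule is crude-model q below ``q_threshold``: the adjusted
    (sex + cell fractions) models are fitted and reported for every
    selected CpG but do not gate discovery.
    """
    stage1, stage2 = split_cohort(cohort, config.stage1_fraction, seed=config.seed)
    logger.info("split: stage-1 n=%d, stage-2 n=%d", len(stage1.sample_ids), len(stage2.sample_ids))

    m1 = beta_to_m(stage1.beta)
    rf = dataclasses.replace(config.rf, rng_seed=config.seed)
    trace, selected = recursive_select(m1, stage1.phenotypes.frame["asthma"].to_numpy(), rf)
    logger.info("stage-1 selected %d CpGs at iteration %s", len(selected), trace.selected_iteration)

    m2 = beta_to_m(stage2.beta.subset(feature_ids=selected))
    m2_trimmed, reports = trim_outliers(m2)
    props2 = estimate_proportions(stage2.beta, stage2.reference_panel)
    crude = logistic_ewas(m2_trimmed, stage2.phenotypes, selected)
    adjusted = logistic_ewas(
        m2_trimmed, stage2.phenotypes, selected, cell_props=props2, adjusted=True
    )
    stage2_results = pd.concat([crude, adjusted], ignore_index=True)

    usable = crude[crude["converged"]]
    qset = storey_qvalues(usable["p_value"].to_numpy(), usable["cpg_id"].tolist())
    qframe = qset.to_frame()
    discovered = qframe.loc[qframe["q_value"] < config.q_threshold, "cpg_id"].tolist()

    result = DiscoveryResult(
        trace=trace,
        selected_cpgs=selected,
        stage1_ids=stage1.sample_ids,
        stage2_ids=stage2.sample_ids,
        stage2_results=stage2_results,
        qvalues=qframe,
        pi0=qset.pi0,
        discovered=discovered,
        proportions=props2,
        trim_reports=trim_report_frame(reports),
    )
    if config.out_dir is not None:
        _write_discovery(result, cohort, config)
    return result


def _write_discovery(result: DiscoveryResult, cohort: SyntheticCohort, config: PipelineConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.trace.to_frame().to_csv(out / "selection_trace.tsv", sep="\t")
    (out / "selected_cpgs.txt").write_text("\n".join(result.selected_cpgs) + "\n")
    result.stage2_results.to_csv(out / "stage2_results.tsv", sep="\t", index=False)
    result.qvalues.to_csv(out / "qvalues.tsv", sep="\t", index=False)
    (out / "discovered_cpgs.txt").write_text(
        ("\n".join(result.discovered) + "\n") if result.discovered else ""
    )
    result.trim_reports.to_csv(out / "trim_report.tsv", sep="\t")
    result.proportions.frame.to_csv(out / "stage2_cell_proportions.tsv", sep="\t")
    pd.Series(result.stage1_ids, name="sample_id").to_csv(
        out / "stage1_samples.txt", index=False
    )
    pd.Series(result.stage2_ids, name="sample_id").to_csv(
        out / "stage2_samples.txt", index=False
    )
    _write_json(_manifest(config, {"pi0": result.pi0}), out / "manifest.json")


@dataclass
class FullReport:
    discovery: DiscoveryResult
    discovery_full_results: pd.DataFrame
    replication_results: pd.DataFrame | None
    replication_assessment: pd.DataFrame | None
    replication_counts: dict | None
    followup: dict | None
    summary_text: str


def _fit_both_models(cohort: SyntheticCohort, cpgs: list[str]) -> pd.DataFrame:
    """Crude + adjusted logistic models on a full cohort at given CpGs."""
    m = beta_to_m(cohort.beta.subset(feature_ids=cpgs))
    m_trimmed, _ = trim_outliers(m)
    props = estimate_proportions(cohort.beta, cohort.reference_panel)
    crude = logistic_ewas(m_trimmed, cohort.phenotypes, cpgs)
    adjusted = logistic_ewas(m_trimmed, cohort.phenotypes, cpgs, cell_props=props, adjusted=True)
    return pd.concat([crude, adjusted], ignore_index=True)


def run_full(
    discovery_cohort: SyntheticCohort,
    config: PipelineConfig,
    replication_cohort: SyntheticCohort | None = None,
    followup_cohort: SyntheticCohort | None = None,
) -> FullReport:
    """Discovery, cross-cohort replication and the cord-blood follow-up.

    Missing replication or follow-up cohorts are tolerated: the report
    marks the corresponding section as skipped.
    """
    disco = run_discovery(discovery_cohort, config)
    discovery_full = (
        _fit_both_models(discovery_cohort, disco.discovered) if disco.discovered else pd.DataFrame()
    )

    replication_results = assessment = counts = None
    if replication_cohort is not None and disco.discovered:
        replication_results = _fit_both_models(replication_cohort, disco.discovered)
        assessment = assess_replication(discovery_full, replication_results, alpha=config.alpha)
        counts = replication_summary(assessment)

    followup = None
    if followup_cohort is not None and disco.discovered:
        followup = _run_followup(followup_cohort, disco.discovered, config)

    text = _render_report(disco, discovery_full, assessment, counts, followup, config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if replication_results is not None:
            replication_results.to_csv(out / "replication_results.tsv", sep="\t", index=False)
            assessment.to_csv(out / "replication_assessment.tsv", sep="\t", index=False)
        if followup is not None:
            followup["wheeze_models"].to_csv(out / "followup_wheeze.tsv", sep="\t", index=False)
        (out / "report.md").write_text(text)
    return FullReport(
        discovery=disco,
        discovery_full_results=discovery_full,
        replication_results=replication_results,
        replication_assessment=assessment,
        replication_counts=counts,
        followup=followup,
        summary_text=text,
    )


def _run_followup(cohort: SyntheticCohort, discovered: list[str], config: PipelineConfig) -> dict:
    """Cord-blood DNAm-expression-wheeze models at the top discovered CpG."""
    present = [c for c in discovered if c in set(cohort.beta.cpg_ids)]
    if not present:
        return {"skipped": "no discovered CpGs present in follow-up cohort"}
    top_cpg = present[0]
    m = beta_to_m(cohort.beta.subset(feature_ids=[top_cpg]))
    m_series = m.frame[top_cpg]
    probe = cohort.expression.probe_ids[0]
    expr_series = cohort.expression.frame[probe]
    rho, p = dnam_expression_correlation(m_series, expr_series)
    props = estimate_proportions(cohort.beta, cohort.reference_panel)
    dnam_models = fit_wheeze_models(
        m_series, cohort.phenotypes, props, predictor_id=top_cpg
    )
    expr_models = fit_wheeze_models(
        expr_series, cohort.phenotypes, props, predictor_id=probe
    )
    return {
        "top_cpg": top_cpg,
        "probe": probe,
        "dnam_expression_rho": rho,
        "dnam_expression_p": p,
        "wheeze_models": pd.concat([dnam_models, expr_models], ignore_index=True),
    }


def _render_report(disco, discovery_full, assessment, counts, followup, config) -> str:
    lines = ["# EWAS pipeline report", ""]
    lines.append(f"- stage-1 n = {len(disco.stage1_ids)}; stage-2 n = {len(disco.stage2_ids)}")
    lines.append(
        f"- recursive RF: {len(disco.trace.iterations)} iterations; selected iteration "
        f"{disco.trace.selected_iteration} with {len(disco.selected_cpgs)} CpGs"
    )
    lines.append(f"- Storey pi0 = {disco.pi0:.3f}")
    lines.append(
        f"- discovered (crude q < {config.q_threshold:g}): {len(disco.discovered)} CpGs"
    )
    if disco.discovered:
        lines.append("")
        lines.append("## Discovered CpGs (full discovery cohort)")
        lines.append("")
        lines.append(discovery_full.to_string(index=False))
    if assessment is not None:
        lines.append("")
        lines.append("## Replication")
        lines.append("")
        lines.append(
            f"- {counts['n_direction_consistent']}/{counts['n_pairs']} direction-consistent; "
            f"{counts['n_replicated']} replicated at alpha = {config.alpha:g}"
        )
        lines.append("")
        lines.append(assessment.to_string(index=False))
    else:
        lines.append("")
        lines.append("## Replication: skipped")
    if followup is not None and "skipped" not in followup:
        lines.append("")
        lines.append("## Cord-blood follow-up")
        lines.append("")
        lines.append(
            f"- DNAm at {followup['top_cpg']} vs expression of {followup['probe']}: "
            f"rho = {followup['dnam_expression_rho']:.3f} (p = {followup['dnam_expression_p']:.3g})"
        )
        lines.append("")
        lines.append(followup["wheeze_models"].to_string(index=False))
    else:
        lines.append("")
        lines.append("## Cord-blood follow-up: skipped")
    lines.append("")
    return "\n".join(lines)


def simulate_and_discover(
    sim: SimulationConfig, config: PipelineConfig
) -> tuple[SyntheticCohort, DiscoveryResult]:
    """Convenience wrapper: generate a cohort, then run discovery on it."""
    cohort = generate_cohort(sim)
    return cohort, run_discovery(cohort, config)


def cohort_summary(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Cohort characteristics table (delegates to data.summarize_phenotypes)."""
    return summarize_phenotypes(phenotypes)
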