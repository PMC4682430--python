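"""End-to-end runner: simulate -> design -> expr -> medip -> integrate -> mito -> pheno.

The runner chains the library stages on a synthetic dataset and produces a
machine-readable run report. The report's counts table mirrors the study's
probe-accounting layout (designed, filtered, called per platform), so a
synthetic run can be read side by side with the published accounting, and a
recovery confusion table against the planted ground truth is included
whenever truth is available. The report is validated by a pydantic model; the
matching JSON Schema is shipped under ``boltchip/schemas/``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import array_design, expression, fixtures, integration, methylation, phenotype, synthetic

logger = logging.getLogger(__name__)


class Thresholds(BaseModel):
    fc: float = 2.0
    alpha_deg: float = 0.05
    alpha_dmr_primary: float = 0.01
    alpha_dmr_screen: float = 0.05
    k_background: float = expression.BACKGROUND_K
    rank_tolerance: float = methylation.RANK_TOLERANCE
    locus_max_gap: int = 5000
    locus_min_probes: int = 3

    @field_validator(
        "fc", "alpha_deg", "alpha_dmr_primary", "alpha_dmr_screen",
        "k_background", "rank_tolerance",
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("thresholds must be strictly positive")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: Path = Path("boltchip_run")
    full_scale: bool = False
    n_expr_probes: int = 5000
    n_meth_probes: int = 20000
    mito_length: int = fixtures.MITO_GENOME_BP
    thresholds: Thresholds = Field(default_factory=Thresholds)
    write_tables: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


class StageCounts(BaseModel):
    designed: int
    filtered: int
    called: int


class Recovery(BaseModel):
    planted: int
    called: int
    true_positive: int
    false_positive: int
    false_negative: int
    recall: float
    precision: float
    direction_errors: int


class RunReport(BaseModel):
    seed: int
    parameters: Thresholds
    stages: list[str]
    counts: dict[str, StageCounts]
    n_dems: int
    dems_recovery_exact: bool | None = None
    expression_recovery: Recovery | None = None
    methylation_recovery: Recovery | None = None
    meth_expr_pearson_r: float | None = None
    meth_expr_spearman_rho: float | None = None
    mito_r_vs_s_p: float | None = None
    mito_coding_vs_noncoding_p: float | None = None
    mito_loci_spans_bp: list[int] = Field(default_factory=list)
    phenotype_classes: dict[str, str] = Field(default_factory=dict)
    snp_pc_variance_fraction: float | None = None
    runtime_s: float


def _recovery(calls, truth_directions: dict[str, str]) -> Recovery:
    called = set(calls.index[calls["significant"].astype(bool)])
    planted = set(truth_directions)
    tp = called & planted
    direction_errors = sum(
        1 for i in tp if calls.loc[i, "direction"] != truth_directions[i]
    )
    return Recovery(
        planted=len(planted),
        called=len(called),
        true_positive=len(tp),
        false_positive=len(called - planted),
        false_negative=len(planted - called),
        recall=len(tp) / len(planted) if planted else 1.0,
        precision=len(tp) / len(called) if called else 1.0,
        direction_errors=direction_errors,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic-analysis chain and return the run report.

    A stage failure raises with the failing stage named; the report (and, if
    ``write_tables``, all intermediate tables) land in ``config.output_dir``.
    Identical config and seed give an identical report.
    """
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    sim = synthetic.SimulationConfig(
        seed=config.seed,
        n_expr_probes=config.n_expr_probes,
        n_meth_probes=config.n_meth_probes,
        mito_length=config.mito_length,
    )
    if config.full_scale:
        sim = sim.full_scale()

    stages: list[str] = []
    counts: dict[str, StageCounts] = {}

    def stage(name: str):
        logger.info("stage %s: starting", name)
        stages.append(name)

    try:
        stage("simulate")
        design_sheet, phenotypes = synthetic.generate_panel(sim)
        truth = synthetic.plant_truth(sim)
        expr_signals, _ = synthetic.generate_expression_signals(sim, truth)
        medip_signals, _ = synthetic.generate_medip_signals(sim, truth)
        genome, annotation, mito_signals, mito_coords, mito_truth = (
            synthetic.generate_mito_dataset(sim)
        )
        snps, snp_truth = synthetic.generate_snp_matrix(sim)

        stage("design")
        mito_design = array_design.build_design(
            [
                array_design.SourceRecord(
                    source_id="MITO", length=sim.mito_length, design_class="mito_genome"
                )
            ],
            mode="methylation",
        )

        stage("expr")
        deg_calls, expr_matrix, expr_retained = expression.run_expression_pipeline(
            expr_signals,
            design_sheet,
            fc_threshold=thresholds.fc,
            alpha=thresholds.alpha_deg,
            k_background=thresholds.k_background,
        )
        counts["transcriptomic"] = StageCounts(
            designed=sim.n_expr_probes,
            filtered=len(expr_retained),
            called=int(deg_calls["significant"].sum()),
        )

        stage("medip")
        # Nuclear and organelle probes share the physical array (and its
        # per-sample dye bias), so the linear normalization runs on the
        # pooled table and calls are split by probe namespace afterwards.
        pooled = pd.concat([medip_signals, mito_signals], ignore_index=True)
        all_calls, all_matrix, all_retained = methylation.run_methylation_pipeline(
            pooled,
            design_sheet,
            fc_threshold=thresholds.fc,
            alpha_primary=thresholds.alpha_dmr_primary,
            alpha_screen=thresholds.alpha_dmr_screen,
            rank_tolerance=thresholds.rank_tolerance,
        )
        is_mito = all_calls.index.isin(mito_coords.index)
        dmr_calls = all_calls.loc[~is_mito]
        mito_calls = all_calls.loc[is_mito]
        meth_matrix = methylation.MethylationRatioMatrix(
            values=all_matrix.values.loc[~all_matrix.values.index.isin(mito_coords.index)],
            scale_factor=all_matrix.scale_factor,
            quality_set=all_matrix.quality_set,
        )
        mito_matrix_values = all_matrix.values.loc[
            all_matrix.values.index.isin(mito_coords.index)
        ]
        counts["methylation"] = StageCounts(
            designed=sim.n_meth_probes,
            filtered=len(meth_matrix.values),
            called=int(dmr_calls["significant"].sum()),
        )

        stage("integrate")
        dems = integration.find_dems(
            deg_calls, dmr_calls, expr_matrix.values, meth_matrix.values
        )
        corr = None
        if len(dems) >= 3:
            try:
                corr = integration.meth_expr_correlation(dems, level="per_genotype")
            except integration.IntegrationError:
                corr = None

        stage("mito")
        track = integration.mito_methylome_profile(
            mito_matrix_values, mito_coords, annotation, design_sheet, sim.mito_length
        )
        r_vs_s = integration.compare_track_groups(track, "R_vs_S")
        cod = integration.compare_track_groups(track, "coding_vs_noncoding")
        dmr_positions = mito_coords.loc[
            mito_coords.index.intersection(
                mito_calls.index[mito_calls["significant"]]
            )
        ]
        loci = integration.find_dmr_rich_loci(
            dmr_positions,
            max_gap=thresholds.locus_max_gap,
            min_probes=thresholds.locus_min_probes,
        )
        counts["mitochondrial"] = StageCounts(
            designed=len(mito_design),
            filtered=len(mito_matrix_values),
            called=int(mito_calls["significant"].sum()),
        )

        stage("pheno")
        pheno_summary = phenotype.phenotype_summary(phenotypes)
        snp_clusters = phenotype.cluster_genotypes(snps)
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline failed at stage {stages[-1]!r}: {exc}") from exc

    if config.write_tables:
        deg_calls.to_csv(out / "deg_calls.tsv", sep="\t")
        dmr_calls.to_csv(out / "dmr_calls.tsv", sep="\t")
        dems.to_csv(out / "dems.tsv", sep="\t")
        expr_matrix.values.to_csv(out / "expression_matrix.tsv", sep="\t")
        meth_matrix.values.to_csv(out / "methylation_ratios.tsv", sep="\t")
        pheno_summary.to_csv(out / "phenotype_summary.tsv", sep="\t", index=False)
        integration.track_to_bedgraph(track, "R", out / "mito_track_R.bedgraph")
        integration.track_to_bedgraph(track, "S", out / "mito_track_S.bedgraph")
        synthetic.write_gff3(annotation, out / "mito_annotation.gff3")
        (out / "snp_dendrogram.nwk").write_text(snp_clusters.to_newick() + "\n")

    report = RunReport(
        seed=config.seed,
        parameters=thresholds,
        stages=stages,
        counts=counts,
        n_dems=len(dems),
        dems_recovery_exact=sorted(dems.index) == sorted(truth.dems_ids),
        expression_recovery=_recovery(deg_calls, truth.deg_directions),
        methylation_recovery=_recovery(dmr_calls, truth.dmr_directions),
        meth_expr_pearson_r=None if corr is None else corr.pearson_r,
        meth_expr_spearman_rho=None if corr is None else corr.spearman_rho,
        mito_r_vs_s_p=r_vs_s["p_value"],
        mito_coding_vs_noncoding_p=cod["p_value"],
        mito_loci_spans_bp=[l.span for l in loci],
        phenotype_classes=dict(
            zip(pheno_summary["genotype_id"], pheno_summary["tolerance_class"])
        ),
        snp_pc_variance_fraction=snp_clusters.pc_variance_fraction,
        runtime_s=time.monotonic() - t0,
    )
    (out / "run_report.json").write_text(report.model_dump_json(indent=2) + "\n")
    return report


def report_json_schema() -> dict:
    """JSON Schema of the run report (source of the shipped schema file)."""
    return RunReport.model_json_schema()


def write_report_schema(path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_json_schema(), indent=2) + "\n")
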