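"""End-to-end orchestration: abundance TSV in, modules + survival report out.

Stage order mirrors the analysis: completeness filter -> (optional)
normalization -> top-variance selection -> correlation / soft threshold /
TOM -> dendrogram -> tree cut -> module merging -> eigenproteins & kME ->
module-trait tests -> per-module signature stratification -> log-rank /
Kaplan-Meier -> differential expression between the stratified arms ->
optional gene-set over-representation.  Every stochastic stage draws from a
named stream derived from the single run seed.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from ._rng import stream_seed
from .consensus import stratify_module_signature
from .datatypes import AbundanceMatrix, InputContractError
from .io import (read_abundance, read_clinical, read_gmt, write_abundance,
                 write_clinical, write_matrix_tsv)
from .modules import build_module_set, me_trait_association, sample_clusters
from .network import (build_dendrogram, compute_tom, correlation_matrix,
                      cut_modules, merge_modules, pick_soft_threshold,
                      signed_adjacency, trim_membership)
from .preprocess import filter_complete, normalize, select_top_variable
from .stats import differential_expression, enrich_hypergeometric
from .survival import km_estimate, logrank_test

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline",
           "validate_report", "report_schema"]


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


class RunConfig(BaseModel):
    """Pipeline parameters; defaults follow the study's stated settings."""

    abundance: str
    clinical: str | None = None
    gmt: str | None = None
    out_dir: str = "coexmod_out"
    normalize_input: bool = False  # input already log2/centered by default
    fraction: float = 0.25
    cor_method: str = "bicor"
    beta: int | None = None  # None = choose by scale-free fit
    r2_target: float = 0.8
    min_size: int = 50
    merge_height: float = 0.15
    split_sensitivity: float = 0.05
    kme_stay_min: float = 0.3
    cut_height: float | None = None
    n_top: int = 50
    k: int = 2
    iterations: int = 1000
    item_fraction: float = 0.8
    feature_fraction: float = 0.8
    n_sample_clusters: int = 4
    seed: int = 0
    write_matrices: bool = False
    full_precision: bool = False


class ModuleSurvival(BaseModel):
    module: str
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    median_survival: dict[str, float | None] = Field(default_factory=dict)


class RunReport(BaseModel):
    """Machine-readable run summary written as report.json."""

    version: str
    parameters: dict
    seed_streams: dict[str, int]
    n_proteins_input: int
    n_samples: int
    n_proteins_complete: int
    n_proteins_selected: int
    chosen_beta: int
    scale_free_r2: float
    module_sizes: dict[str, int]
    n_unassigned: int
    sample_cluster_sizes: dict[str, int] | None = None
    trait_association: list[dict] | None = None
    module_survival: list[ModuleSurvival] | None = None
    best_module: str | None = None
    n_de_significant: int | None = None
    top_enriched_sets: list[dict] | None = None


def report_schema() -> dict:
    """The JSON schema the shipped report validates against."""
    return RunReport.model_json_schema()


def validate_report(obj: dict) -> RunReport:
    return RunReport.model_validate(obj)


def shipped_schema() -> dict:
    with resources.files("coexmod").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``; returns the report.

    Artifacts written to ``config.out_dir``: filtered/normalized abundance,
    soft-threshold scan, module assignments, eigenproteins, kME, trait tests,
    per-module signature labels, KM curves and log-rank results, DE table and
    enrichment table (when clinical / GMT inputs are given), plus report.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    current = {"stage": "setup"}

    def _stage(name):
        current["stage"] = name
        log.info("pipeline stage: %s", name)

    try:
        return _run(config, out, _stage)
    except Exception as exc:
        raise PipelineError(
            f"pipeline failed at stage {current['stage']!r}: {exc}") from exc


def _run(config: RunConfig, out: Path, _stage) -> RunReport:

    _stage("load")
    clinical = read_clinical(config.clinical) if config.clinical else None
    matrix = read_abundance(config.abundance, clinical)
    n_input = matrix.shape[0]

    _stage("filter_complete")
    matrix = filter_complete(matrix)
    n_complete = matrix.shape[0]
    if config.normalize_input:
        _stage("normalize")
        matrix = normalize(matrix)

    _stage("select_top_variable")
    selected = select_top_variable(matrix, config.fraction)
    write_abundance(selected, out / "selected_abundance.tsv", config.full_precision)

    _stage("correlation")
    cor = correlation_matrix(selected, method=config.cor_method)
    _stage("soft_threshold")
    scan = pick_soft_threshold(cor, r2_target=config.r2_target)
    write_matrix_tsv(scan.table.set_index("beta"), out / "soft_threshold_scan.tsv", "beta")
    beta = config.beta if config.beta is not None else scan.chosen_beta
    r2_row = scan.table[scan.table.beta == beta]
    r2 = float(r2_row.r_squared.iloc[0]) if len(r2_row) else float("nan")

    _stage("tom")
    adj = signed_adjacency(cor, beta)
    tom = compute_tom(adj)
    if config.write_matrices:
        write_matrix_tsv(tom, out / "tom.tsv", "protein_id", config.full_precision)

    _stage("modules")
    dend = build_dendrogram(tom)
    assignments = cut_modules(dend, min_size=config.min_size,
                              cut_height=config.cut_height,
                              split_sensitivity=config.split_sensitivity)
    assignments = merge_modules(assignments, selected, merge_height=config.merge_height)
    assignments = trim_membership(assignments, selected,
                                  kme_stay_min=config.kme_stay_min,
                                  min_size=config.min_size)
    assignments = merge_modules(assignments, selected, merge_height=config.merge_height)
    pd.DataFrame({"protein_id": assignments.index,
                  "module": [f"M{m}" for m in assignments]}
                 ).to_csv(out / "modules.tsv", sep="\t", index=False)
    sizes = assignments[assignments != 0].value_counts().sort_index()
    module_sizes = {f"M{m}": int(c) for m, c in sizes.items()}
    n_unassigned = int((assignments == 0).sum())
    log.info("modules: %s; unassigned: %d", module_sizes, n_unassigned)

    mset = build_module_set(selected, assignments) if len(sizes) else None
    if mset is not None:
        write_matrix_tsv(mset.eigenproteins, out / "eigenproteins.tsv", "module",
                         config.full_precision)
        write_matrix_tsv(mset.kme, out / "kme.tsv", "protein_id", config.full_precision)

    # sample clustering on the full complete matrix (overview dendrogram cut)
    cluster_sizes = None
    if matrix.shape[1] >= config.n_sample_clusters >= 2:
        _stage("sample_clusters")
        sc = sample_clusters(matrix, k=config.n_sample_clusters)
        sc.rename("cluster").to_frame().assign(
            cluster=lambda d: d.cluster.astype(str)
        ).to_csv(out / "sample_clusters.tsv", sep="\t", index_label="sample_id")
        cluster_sizes = {str(k_): int(v) for k_, v in sc.value_counts().sort_index().items()}

    trait_rows = None
    if clinical is not None and mset is not None and "group" in clinical.columns:
        _stage("trait_association")
        groups = clinical.set_index("sample_id")["group"].reindex(selected.sample_ids)
        if groups.notna().all() and groups.nunique() >= 2 and groups.value_counts().min() >= 2:
            tr = me_trait_association(mset.eigenproteins, groups)
            tr.to_csv(out / "module_trait.tsv", sep="\t", index=False)
            trait_rows = tr.to_dict(orient="records")

    module_survival = None
    best_module = None
    n_de_sig = None
    top_sets = None
    if clinical is not None and mset is not None:
        _stage("signature_survival")
        surv = clinical.set_index("sample_id").reindex(selected.sample_ids)
        module_survival = []
        best_p, best_labels = np.inf, None
        for name in mset.eigenproteins.index:
            m = int(name[1:])
            labels, sig, _ = stratify_module_signature(
                selected, mset, m, n_top=config.n_top, k=config.k,
                iterations=config.iterations, item_fraction=config.item_fraction,
                feature_fraction=config.feature_fraction,
                seed=stream_seed(config.seed, f"signature-{name}"),
            )
            labels.rename("label").to_csv(out / f"signature_labels_{name}.tsv",
                                          sep="\t", index_label="sample_id")
            (out / f"signature_proteins_{name}.txt").write_text("\n".join(sig) + "\n")
            lr = logrank_test(surv["os_months"], surv["os_event"], labels.to_numpy())
            medians = {}
            for arm in pd.unique(labels):
                mask = (labels == arm).to_numpy()
                km = km_estimate(surv["os_months"][mask], surv["os_event"][mask])
                medians[str(arm)] = km.median
                km.table.to_csv(out / f"km_{name}_{arm}.tsv", sep="\t",
                                index_label="time")
            module_survival.append(ModuleSurvival(
                module=name, logrank_statistic=lr.statistic,
                logrank_p=lr.p_value, median_survival=medians))
            if lr.p_value < best_p:
                best_p, best_module, best_labels = lr.p_value, name, labels

        if best_labels is not None and config.k == 2:
            _stage("differential_expression")
            a = list(best_labels.index[best_labels == "high"])
            b = list(best_labels.index[best_labels == "low"])
            if len(a) >= 2 and len(b) >= 2:
                de = differential_expression(matrix, a, b)
                de.to_csv(out / "de_table.tsv", sep="\t")
                n_de_sig = int((de["p_adjusted"] < 0.05).sum())

        if config.gmt and best_module is not None:
            _stage("enrichment")
            coll = read_gmt(config.gmt)
            members = set(mset.members(int(best_module[1:])))
            universe = set(matrix.protein_ids)
            enr = enrich_hypergeometric(members & universe, universe, coll)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            top_sets = enr.head(5)[["set", "overlap", "p", "p_adjusted"]].to_dict("records")

    report = RunReport(
        version=__version__,
        parameters=json.loads(config.model_dump_json()),
        seed_streams={"consensus": stream_seed(config.seed, "consensus"),
                      "signature": stream_seed(config.seed, "signature-M1")},
        n_proteins_input=n_input,
        n_samples=matrix.shape[1],
        n_proteins_complete=n_complete,
        n_proteins_selected=selected.shape[0],
        chosen_beta=int(beta),
        scale_free_r2=r2,
        module_sizes=module_sizes,
        n_unassigned=n_unassigned,
        sample_cluster_sizes=cluster_sizes,
        trait_association=trait_rows,
        module_survival=module_survival,
        best_module=best_module,
        n_de_significant=n_de_sig,
        top_enriched_sets=top_sets,
    )
    (out / "report.json").write_text(report.model_dump_json(indent=2))
    return report
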