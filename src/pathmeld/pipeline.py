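"""End-to-end orchestration of the meta-dimensional pathway analysis.

Stages: genotype QC -> SNP association (+ genomic control) -> gene-level
set test -> four pathway-level GWAS statistics -> Monte-Carlo combination
-> top-K pathway selection -> mutation pre-ranked enrichment -> expression
PDS + paired test -> pathway survival screen -> cross-data-type rank
consistency -> NMF stratification on top-K pathway burden.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import combine as combine_mod
from . import core_io, gsea, gwas_assoc, integrate, pathway_gwas, pds as pds_mod
from . import stratify as stratify_mod
from . import survival as survival_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Per-stage parameters with the pipeline defaults.

    Permutation counts default to desk scale; raise them for production
    runs (the reference scale is 10,000 permutations per stage).
    """

    qc: core_io.QCConfig = field(default_factory=core_io.QCConfig)
    gene_top_n: int = 5
    pathway_top_n: int = 20
    snp_p_threshold: float = 0.05
    ld_r2_threshold: float = 0.5
    window_kb: float = 20.0
    clump_p1: float = 0.01
    clump_p2: float = 0.05
    clump_r2: float = 0.5
    n_perm: int = 500
    n_sim_combine: int = 2000
    n_resample: int = 2000
    gsea_weight: float = 1.0
    top_k: int = 20
    top_max_p: float = 0.05
    set_min_size: int = 1
    set_max_size: int = 500
    nmf_ranks: tuple[int, ...] = (2, 3, 4)
    nmf_runs: int = 30
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """Bundle of per-stage tables from one pipeline run."""

    qc_counts: dict
    snp_assoc: pd.DataFrame
    gene_results: dict[str, float]
    per_method: dict[str, pd.DataFrame]
    combined: combine_mod.CombineResult
    top_pathways: list[str]
    mutation: pd.DataFrame | None
    pds_scores: pd.DataFrame | None
    expression_test: pd.DataFrame | None
    survival_screen: pd.DataFrame | None
    rankings: pd.DataFrame
    consistency: pd.DataFrame
    stratification: stratify_mod.ConsensusResult | None
    subgroup_tests: pd.DataFrame | None
    summary: pd.DataFrame
    config: RunConfig


def gwas_stage(study, genes, sets, cfg: RunConfig):
    """QC, SNP association, gene-level set test, and the four pathway
    statistics; returns everything the combination stage needs."""
    study, qc_counts = core_io.qc_filter(study, cfg.qc)
    assoc = gwas_assoc.genomic_control(gwas_assoc.snp_association(study))

    gene_snp_map = core_io.map_snps_to_genes(study.snp_table, genes, cfg.window_kb)
    sets_f = sets.size_filtered(cfg.set_min_size, cfg.set_max_size)
    pathway_snp_map = core_io.sets_to_snp_map(sets_f, gene_snp_map)

    rng = np.random.default_rng(cfg.seed)
    labels = pathway_gwas.permutation_labels(study.phenotype, cfg.n_perm, rng)

    gene_cfg = pathway_gwas.SetTestConfig(
        top_n_snps=cfg.gene_top_n, snp_p_threshold=cfg.snp_p_threshold,
        ld_r2_threshold=cfg.ld_r2_threshold, window_kb=cfg.window_kb,
        n_perm=cfg.n_perm, seed=cfg.seed,
    )
    gene_tab = pathway_gwas.set_test(study, gene_snp_map, gene_cfg, labels=labels)
    gene_results = dict(zip(gene_tab["set_id"], gene_tab["emp_p"]))

    pw_cfg = pathway_gwas.SetTestConfig(
        top_n_snps=cfg.pathway_top_n, snp_p_threshold=cfg.snp_p_threshold,
        ld_r2_threshold=cfg.ld_r2_threshold, window_kb=cfg.window_kb,
        n_perm=cfg.n_perm, seed=cfg.seed,
    )
    settest = pathway_gwas.set_test(study, pathway_snp_map, pw_cfg, labels=labels)
    gengen = pathway_gwas.gengen_enrich(
        study, gene_snp_map, sets_f, weight=cfg.gsea_weight, labels=labels,
        min_size=cfg.set_min_size, max_size=cfg.set_max_size,
    )
    intervals = pathway_gwas.make_intervals(
        assoc.table, study, p1=cfg.clump_p1, p2=cfg.clump_p2, r2=cfg.clump_r2
    )
    if intervals:
        inrich = pathway_gwas.inrich_test(
            intervals, genes, sets_f, study.snp_table,
            n_perm=cfg.n_perm, seed=cfg.seed, window_kb=cfg.window_kb,
        )
    else:
        logger.warning("no association intervals; INRICH column imputed p = 1")
        inrich = pd.DataFrame(
            {"set_id": sorted(sets_f.sets), "statistic": 0.0, "emp_p": 1.0,
             "contributors": ""}
        )
    try:
        ranked = pathway_gwas.gene_p_to_ranklist(gene_results)
        prerank = gsea.prerank(
            ranked, sets_f, weight=cfg.gsea_weight, n_perm=cfg.n_perm,
            seed=cfg.seed, min_size=cfg.set_min_size, max_size=cfg.set_max_size,
        )
        prerank = prerank.rename(columns={"nom_p": "emp_p"})
    except ValueError:
        logger.warning("empty gene rank list; GSEA column imputed p = 1")
        prerank = pd.DataFrame({"set_id": sorted(sets_f.sets), "emp_p": 1.0})

    per_method = {
        "settest": settest, "gengen": gengen, "inrich": inrich, "prerank": prerank,
    }
    return study, qc_counts, assoc, gene_snp_map, pathway_snp_map, gene_results, per_method


def run_pipeline(
    study,
    genes,
    sets,
    mutation_p: dict[str, float] | None = None,
    expr=None,
    surv: pd.DataFrame | None = None,
    cfg: RunConfig | None = None,
) -> RunResult:
    """Run every stage in memory and collect the per-stage tables.

    ``mutation_p``, ``expr`` and ``surv`` are optional; missing data types
    simply drop out of the integration (degraded mode).
    """
    cfg = cfg or RunConfig()
    (study, qc_counts, assoc, gene_snp_map, pathway_snp_map,
     gene_results, per_method) = gwas_stage(study, genes, sets, cfg)

    pmat = combine_mod.align_pvalue_matrix(
        {m: dict(zip(t["set_id"], t["emp_p"])) for m, t in per_method.items()}
    )
    combined = combine_mod.mc_combine(pmat, n_sim=cfg.n_sim_combine, seed=cfg.seed)
    top = combined.top(cfg.top_k, cfg.top_max_p)

    per_type: dict[str, dict[str, float]] = {
        "gwas": dict(zip(combined.table["set_id"], combined.table["combined_p"]))
    }

    mutation = None
    if mutation_p is not None:
        ranked = gsea.prepare_mutation_ranklist(mutation_p)
        mutation = gsea.prerank(
            ranked, sets, weight=cfg.gsea_weight, n_perm=cfg.n_perm, seed=cfg.seed,
            min_size=cfg.set_min_size, max_size=cfg.set_max_size,
        )
        per_type["mutation"] = dict(zip(mutation["set_id"], mutation["nom_p"]))

    pds_scores = expression_test = None
    pds_result = None
    if expr is not None:
        norm, _ = pds_mod.size_factor_normalize(expr)
        pds_result = pds_mod.compute_pds(norm, sets, expr.normal_ids)
        pds_scores = pds_result.scores
        pairs = expr.pairs()
        if len(pairs) >= 3:
            expression_test = pds_mod.paired_pds_test(
                pds_result, pairs, n_perm=cfg.n_perm, seed=cfg.seed
            )
            per_type["expression"] = dict(
                zip(expression_test["set_id"], expression_test["emp_p"])
            )

    survival_screen = None
    if surv is not None and pds_scores is not None:
        survival_screen = survival_mod.pathway_survival_screen(pds_scores, surv)
        per_type["survival"] = dict(zip(survival_screen["set_id"], survival_screen["p"]))

    rankings = integrate.build_rankings(per_type)
    focus = [s for s in top if s in rankings.index] or list(rankings.index)
    consistency = integrate.consistency_test(
        rankings, focus, n_resample=cfg.n_resample, seed=cfg.seed
    )

    stratification = subgroup_tests = None
    top_snp_map = {s: pathway_snp_map[s] for s in top if s in pathway_snp_map}
    if len(top_snp_map) >= 2:
        burden = stratify_mod.pathway_burden(study, top_snp_map)
        max_rank = min(burden.shape) - 1
        ranks = [r for r in cfg.nmf_ranks if 2 <= r <= max_rank]
        if ranks:
            stratification = stratify_mod.consensus_cluster(
                burden, ranks=ranks, n_runs=cfg.nmf_runs, seed=cfg.seed
            )
            if len(np.unique(stratification.labels)) == 2:
                subgroup_tests = stratify_mod.subgroup_pathway_tests(
                    burden, stratification.labels
                )

    summary = _summary_table(combined, mutation, expression_test, survival_screen, top)
    return RunResult(
        qc_counts=qc_counts, snp_assoc=assoc.table, gene_results=gene_results,
        per_method=per_method, combined=combined, top_pathways=top,
        mutation=mutation, pds_scores=pds_scores, expression_test=expression_test,
        survival_screen=survival_screen, rankings=rankings, consistency=consistency,
        stratification=stratification, subgroup_tests=subgroup_tests,
        summary=summary, config=cfg,
    )


def _summary_table(combined, mutation, expression_test, survival_screen, top):
    """Per-pathway summary across data types for the top pathways."""
    out = combined.table.set_index("set_id").loc[
        [t for t in top], ["mean_rank", "combined_p"]
    ]
    out.columns = ["gwas_mean_rank", "gwas_combined_p"]
    if mutation is not None:
        out["mutation_q"] = mutation.set_index("set_id")["fdr_bh"].reindex(out.index)
    if expression_test is not None:
        out["expression_q"] = expression_test.set_index("set_id")["q"].reindex(out.index)
    if survival_screen is not None:
        out["survival_q"] = survival_screen.set_index("set_id")["q"].reindex(out.index)
    return out.reset_index()


# ---------------------------------------------------------------------------
# File-based run


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# pathmeld stage={stage} config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_run(result: RunResult, out_dir) -> None:
    """Serialize every stage table under ``out_dir/{stage}/``."""
    out = Path(out_dir)
    cfg = result.config
    _write_tsv(result.snp_assoc, out / "snp" / "assoc.tsv", cfg, "snp_assoc")
    gene_tab = pd.DataFrame(
        sorted(result.gene_results.items()), columns=["gene", "emp_p"]
    )
    _write_tsv(gene_tab, out / "gene" / "set_test.tsv", cfg, "gene_set_test")
    for method, tab in result.per_method.items():
        _write_tsv(tab, out / "pathway" / f"{method}.tsv", cfg, f"pathway_{method}")
    _write_tsv(result.combined.table, out / "combine" / "combined.tsv", cfg, "combine")
    sidecar = {
        "A": result.combined.correlation.tolist(),
        "L": result.combined.cholesky.tolist(),
        "n_sim": result.combined.n_sim,
        "seed": cfg.seed,
        "top_pathways": result.top_pathways,
    }
    (out / "combine").mkdir(parents=True, exist_ok=True)
    (out / "combine" / "combined.json").write_text(json.dumps(sidecar, indent=1))
    if result.mutation is not None:
        _write_tsv(result.mutation, out / "mutation" / "prerank.tsv", cfg, "mutation")
    if result.pds_scores is not None:
        _write_tsv(result.pds_scores.reset_index(names="set_id"),
                   out / "expression" / "pds.tsv", cfg, "pds")
    if result.expression_test is not None:
        _write_tsv(result.expression_test, out / "expression" / "paired_test.tsv",
                   cfg, "paired_test")
    if result.survival_screen is not None:
        _write_tsv(result.survival_screen, out / "survival" / "screen.tsv", cfg, "survival")
    _write_tsv(result.rankings.reset_index(names="set_id"),
               out / "integrate" / "rankings.tsv", cfg, "rankings")
    _write_tsv(result.consistency, out / "integrate" / "consistency.tsv", cfg, "consistency")
    if result.stratification is not None:
        labels = result.stratification.labels_series().reset_index()
        labels.columns = ["sample_id", "cluster"]
        _write_tsv(labels, out / "stratify" / "labels.tsv", cfg, "stratify_labels")
        cons = pd.DataFrame(result.stratification.consensus[result.stratification.chosen_rank])
        _write_tsv(cons, out / "stratify" / "consensus.tsv", cfg, "stratify_consensus")
    if result.subgroup_tests is not None:
        _write_tsv(result.subgroup_tests, out / "stratify" / "subgroup_tests.tsv",
                   cfg, "stratify_tests")
    _write_tsv(result.summary, out / "summary.tsv", cfg, "summary")
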