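"""Synthetic multi-omics generators with planted pathway effects.

Every stage of the pipeline is exercised on data whose ground truth is
known: case/control genotypes with LD blocks and risk alleles concentrated
in chosen pathways, gene-level mutation p-values enriched in chosen
pathways, paired tumor/normal expression drifting along a latent direction
in deregulated pathways, and relapse times whose hazard grows with the
per-patient deregulation severity.  Each generator is a pure function of
(design, seed).

The default design is desk-scale — 300 cases / 300 controls, 5,000 SNPs in
LD blocks of 10, 500 genes tiled along the genome, 40 pathways of
contiguous genes, 23 tumor/normal pairs — so all stages finish in minutes
while preserving the structure the pipeline relies on (LD for
pruning/clumping, gene windows, pathway-concentrated effects).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import GeneSetCollection, GenotypeStudy
from .pds import ExpressionStudy


@dataclass
class SimulationDesign:
    """Parameters of the synthetic study; defaults are desk-scale."""

    n_cases: int = 300
    n_controls: int = 300
    n_snps: int = 5000
    n_genes: int = 500
    n_pathways: int = 40
    ld_block_size: int = 10
    ld_copy_prob: float = 0.8
    causal_pathways: tuple[str, ...] = ("PW01",)
    causal_snp_or: float = 1.5
    n_causal_snps: int = 10
    mutation_enriched_pathways: tuple[str, ...] = ("PW01",)
    mutation_beta_a: float = 0.1
    mutation_p1_fraction: float = 0.1
    deregulated_pathways: tuple[str, ...] = ("PW01",)
    expression_shift_sd: float = 2.0
    n_pairs: int = 23
    n_survival: int = 100
    hazard_beta: float = 1.0
    censoring_target: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_snps", "n_genes", "n_pathways",
                     "ld_block_size", "n_pairs", "n_survival"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.causal_snp_or <= 0:
            raise ValueError("causal_snp_or must be positive")
        valid = set(self.pathway_ids())
        for group in (self.causal_pathways, self.mutation_enriched_pathways,
                      self.deregulated_pathways):
            unknown = set(group) - valid
            if unknown:
                raise ValueError(f"unknown pathway ids: {sorted(unknown)}")

    def pathway_ids(self) -> list[str]:
        width = max(2, len(str(self.n_pathways)))
        return [f"PW{i + 1:0{width}d}" for i in range(self.n_pathways)]

    def gene_symbols(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def _gene_table(design: SimulationDesign, snp_pos: np.ndarray) -> pd.DataFrame:
    """Genes tiled over consecutive SNP runs on the synthetic genome."""
    snps_per_gene = max(1, design.n_snps // design.n_genes)
    rows = []
    for g, sym in enumerate(design.gene_symbols()):
        lo = g * snps_per_gene
        hi = min(lo + snps_per_gene, design.n_snps) - 1
        if lo >= design.n_snps:
            lo = hi = design.n_snps - 1
        rows.append((sym, "1", int(snp_pos[lo]), int(snp_pos[hi])))
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end"])


def _gene_sets(design: SimulationDesign) -> GeneSetCollection:
    """Pathways as contiguous tiles of genes."""
    symbols = design.gene_symbols()
    per_pw = max(1, design.n_genes // design.n_pathways)
    sets = {}
    for k, name in enumerate(design.pathway_ids()):
        lo = k * per_pw
        hi = min(lo + per_pw, design.n_genes)
        if lo >= design.n_genes:
            lo, hi = design.n_genes - per_pw, design.n_genes
        sets[name] = frozenset(symbols[lo:hi])
    return GeneSetCollection(sets, {name: "KEGG" for name in sets})


def simulate_genotypes(design: SimulationDesign):
    """Case/control genotypes with LD blocks and pathway-planted risk SNPs.

    Haplotypes are built per LD block by first-order allele copying (each
    SNP copies its left neighbour's allele with ``ld_copy_prob``, else
    draws fresh from its frequency).  Disease status follows a logistic
    model with log-odds ``ln(causal_snp_or)`` per causal minor allele,
    causal SNPs lying inside the causal pathways' genes; individuals are
    drawn until the case and control quotas fill.

    Returns (GenotypeStudy, GeneTable, GeneSetCollection, truth dict).
    """
    rng = np.random.default_rng(design.seed)
    m = design.n_snps
    snp_pos = 1000 * np.arange(1, m + 1, dtype=np.int64)
    snp_ids = [f"rs{j + 1:06d}" for j in range(m)]
    freq = rng.uniform(0.1, 0.5, size=m)

    genes = _gene_table(design, snp_pos)
    sets = _gene_sets(design)

    # causal SNPs: uniformly inside the causal pathways' gene bodies
    causal_cols: list[int] = []
    if design.causal_snp_or != 1.0 and design.causal_pathways:
        gene_rows = genes.set_index("symbol")
        candidates = []
        for pw in design.causal_pathways:
            for g in sorted(sets[pw]):
                lo, hi = gene_rows.loc[g, "start"], gene_rows.loc[g, "end"]
                cols = np.where((snp_pos >= lo) & (snp_pos <= hi))[0]
                candidates.extend(cols.tolist())
        candidates = sorted(set(candidates))
        k = min(design.n_causal_snps, len(candidates))
        causal_cols = sorted(rng.choice(candidates, size=k, replace=False).tolist())
    beta = np.zeros(m)
    beta[causal_cols] = np.log(design.causal_snp_or)
    # intercept centers the genetic score at ~50% prevalence
    intercept = -float(beta @ (2 * freq))

    def draw_batch(n: int) -> np.ndarray:
        """n individuals' dosages via blockwise haplotype copying."""
        hap = np.empty((2 * n, m), dtype=np.int8)
        u = rng.random((2 * n, m))
        copy = rng.random((2 * n, m)) < design.ld_copy_prob
        for start in range(0, m, design.ld_block_size):
            stop = min(start + design.ld_block_size, m)
            hap[:, start] = u[:, start] < freq[start]
            for j in range(start + 1, stop):
                fresh = u[:, j] < freq[j]
                hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh)
        return (hap[0::2] + hap[1::2]).astype(np.int8)

    need_cases, need_controls = design.n_cases, design.n_controls
    case_rows, control_rows = [], []
    while need_cases > 0 or need_controls > 0:
        batch = draw_batch(max(need_cases + need_controls, 64))
        score = intercept + batch @ beta
        is_case = rng.random(len(batch)) < 1.0 / (1.0 + np.exp(-score))
        for row, c in zip(batch, is_case):
            if c and need_cases > 0:
                case_rows.append(row)
                need_cases -= 1
            elif not c and need_controls > 0:
                control_rows.append(row)
                need_controls -= 1

    dosage = np.vstack(case_rows + control_rows)
    phenotype = np.concatenate(
        [np.ones(design.n_cases, dtype=int), np.zeros(design.n_controls, dtype=int)]
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(len(phenotype))]
    snp_table = pd.DataFrame(
        {"id": snp_ids, "chrom": "1", "pos": snp_pos, "a1": "A", "a2": "G"}
    )
    study = GenotypeStudy(dosage, phenotype, sample_ids, snp_table)
    truth = {
        "causal_snps": [snp_ids[j] for j in causal_cols],
        "causal_pathways": list(design.causal_pathways),
        "allele_freq": freq,
    }
    return study, genes, sets, truth


def simulate_mutation_pvalues(design: SimulationDesign, sets: GeneSetCollection | None = None):
    """Gene-level mutation-significance p-values with planted enrichment.

    Background genes draw p ~ Uniform(0, 1]; genes of the enriched
    pathways draw p ~ Beta(a, 1) with a < 1 (smaller a = stronger signal);
    a fraction of background genes is set to exactly p = 1 to exercise the
    removal rule upstream of the pre-ranked test.
    """
    rng = np.random.default_rng(design.seed + 1)
    sets = sets or _gene_sets(design)
    enriched_genes: set[str] = set()
    for pw in design.mutation_enriched_pathways:
        enriched_genes |= set(sets[pw])
    gene_p: dict[str, float] = {}
    for g in design.gene_symbols():
        if g in enriched_genes:
            gene_p[g] = max(float(rng.beta(design.mutation_beta_a, 1.0)), 1e-300)
        else:
            p = float(rng.uniform(0.0, 1.0))
            if rng.random() < design.mutation_p1_fraction:
                p = 1.0
            gene_p[g] = max(p, 1e-300)
    truth = {"enriched_pathways": list(design.mutation_enriched_pathways),
             "beta_a": design.mutation_beta_a}
    return gene_p, truth


def simulate_paired_expression(design: SimulationDesign, sets: GeneSetCollection | None = None):
    """Paired tumor/normal counts with a planted deregulation trajectory.

    Normal samples draw log-normal baseline counts around per-gene means;
    each tumor shares its partner's patient effect but member genes of the
    deregulated pathways are shifted along a fixed latent direction by
    ``expression_shift_sd`` x a per-patient severity ~ Uniform(0.5, 1.5)
    (in units of the within-gene noise SD).  Per-sample library-size
    multipliers exercise the normalization.  ``n_survival`` extra unpaired
    tumors carry their own severities for the survival stage.

    Returns (ExpressionStudy, truth) with per-tumor severities in truth.
    """
    rng = np.random.default_rng(design.seed + 2)
    sets = sets or _gene_sets(design)
    genes = design.gene_symbols()
    n_genes = len(genes)
    mu = rng.normal(np.log(100.0), 1.0, size=n_genes)
    noise_sd = 0.3
    dereg_genes = set()
    for pw in design.deregulated_pathways:
        dereg_genes |= set(sets[pw])
    direction = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    member = np.array([g in dereg_genes for g in genes])

    cols, meta_rows = [], []

    def sample_counts(patient_eff, severity, lib):
        logx = mu + patient_eff + rng.normal(0.0, noise_sd, size=n_genes)
        if severity > 0:
            logx = logx + member * direction * design.expression_shift_sd * noise_sd * severity
        return np.round(np.exp(logx) * lib).astype(int)

    severities = {}
    for i in range(design.n_pairs):
        pid = f"PA{i + 1:03d}"
        eff = rng.normal(0.0, 0.2, size=n_genes)
        sev = float(rng.uniform(0.5, 1.5))
        for cond, sv in (("normal", 0.0), ("tumor", sev)):
            sid = f"{pid}_{cond[0].upper()}"
            cols.append(sample_counts(eff, sv, float(rng.uniform(0.5, 2.0))))
            meta_rows.append((sid, cond, pid))
            if cond == "tumor":
                severities[sid] = sev
    for i in range(design.n_survival):
        sid = f"SV{i + 1:04d}_T"
        eff = rng.normal(0.0, 0.2, size=n_genes)
        sev = float(rng.uniform(0.0, 2.0))
        cols.append(sample_counts(eff, sev, float(rng.uniform(0.5, 2.0))))
        meta_rows.append((sid, "tumor", None))
        severities[sid] = sev

    meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition", "pair_id"])
    counts = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=meta["sample_id"]
    )
    expr = ExpressionStudy(counts=counts, meta=meta)
    truth = {
        "deregulated_pathways": list(design.deregulated_pathways),
        "severity": severities,
        "shift_sd": design.expression_shift_sd,
    }
    return expr, truth


def simulate_survival(severity: dict[str, float] | pd.Series,
                      design: SimulationDesign) -> pd.DataFrame:
    """Relapse-free survival times driven by deregulation severity.

    Event times are exponential with hazard proportional to
    exp(hazard_beta x standardized severity); censoring times are uniform
    on [0, c], with c tuned by bisection so the realized censoring rate
    approximates ``censoring_target``.
    """
    sev = pd.Series(severity, dtype=float)
    rng = np.random.default_rng(design.seed + 3)
    z = (sev - sev.mean()) / (sev.std() if sev.std() > 0 else 1.0)
    hazard = 0.01 * np.exp(design.hazard_beta * z.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    u = rng.random(len(sev))

    def censored_frac(c: float) -> float:
        return float(np.mean(u * c < t_event))

    lo, hi = 1e-6, float(t_event.max()) * 10
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        # censored fraction decreases as the censoring horizon grows
        if censored_frac(mid) > design.censoring_target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    t_cens = u * c
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"sample_id": sev.index, "time": observed, "event": event}
    ).reset_index(drop=True)


def simulate_burden_subpopulations(
    n_patients: int = 200,
    n_pathways: int = 20,
    n_shifted: int = 4,
    shift_sd: float = 1.5,
    frac_group1: float = 0.5,
    seed: int = 0,
):
    """Pathway-burden matrix with a planted two-subpopulation structure.

    One patient subgroup carries a ``shift_sd``-SD mean shift in the first
    ``n_shifted`` pathway rows; rows are z-scored and the global minimum is
    subtracted, matching the stratification preprocessing.  Returns
    (burden DataFrame pathways x patients, true labels, shifted pathway ids).
    """
    rng = np.random.default_rng(seed)
    n1 = int(round(frac_group1 * n_patients))
    labels = np.array([1] * n1 + [2] * (n_patients - n1))
    X = rng.normal(0.0, 1.0, size=(n_pathways, n_patients))
    X[:n_shifted, labels == 1] += shift_sd
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    X = X - X.min()
    width = max(2, len(str(n_pathways)))
    pw = [f"PW{i + 1:0{width}d}" for i in range(n_pathways)]
    patients = [f"S{i + 1:05d}" for i in range(n_patients)]
    M = pd.DataFrame(X, index=pw, columns=patients)
    return M, labels, pw[:n_shifted]


def null_design(design: SimulationDesign | None = None, seed: int = 0) -> SimulationDesign:
    """A copy of the design with every planted effect switched off."""
    design = design or SimulationDesign()
    return replace(
        design,
        causal_snp_or=1.0,
        mutation_beta_a=1.0,
        expression_shift_sd=0.0,
        hazard_beta=0.0,
        seed=seed,
    )
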