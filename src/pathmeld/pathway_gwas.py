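"""Pathway-level GWAS set statistics.

Three permutation-based set statistics over case/control genotypes:

* :func:`set_test` — PLINK-style set-based test: mean trend chi-square of
  the top LD-independent SNPs passing a p threshold, phenotype-permutation
  null (top 5 SNPs for gene-level runs, top 20 for pathway-level runs).
* :func:`gengen_enrich` — per-gene statistic = max SNP chi-square, genes
  ranked, weighted KS enrichment per pathway, phenotype-permutation null.
* :func:`inrich_test` — LD-clumped association intervals scored by how many
  overlap a pathway gene, against matched random relocations.

plus :func:`gene_p_to_ranklist`, the adaptor feeding gene-level empirical
p-values to the pre-ranked GSEA engine.

All permutation p-values use the (1 + b)/(1 + n) estimator, and the
phenotype permutation stream is shared across sets within a run so
p-values are comparable between sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GeneSetCollection, GenotypeStudy
from .gsea import RankedList

logger = logging.getLogger(__name__)


@dataclass
class SetTestConfig:
    """Selection and permutation parameters for the set-based test."""

    top_n_snps: int = 20
    snp_p_threshold: float = 0.05
    ld_r2_threshold: float = 0.5
    window_kb: float = 20.0
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_n_snps < 1:
            raise ValueError("top_n_snps must be >= 1")
        for name in ("snp_p_threshold", "ld_r2_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Shared permutation machinery


def _imputed_dosage(study: GenotypeStudy) -> np.ndarray:
    """Float dosage matrix with missing entries replaced by the SNP mean."""
    d = study.dosage.astype(float)
    miss = study.dosage == MISSING
    if miss.any():
        obs = np.where(miss, np.nan, d)
        means = np.nanmean(obs, axis=0)
        means = np.nan_to_num(means)
        d = np.where(miss, means[None, :], d)
    return d


def perm_chi2_matrix(study: GenotypeStudy, labels: np.ndarray) -> np.ndarray:
    """Trend chi-squares for many phenotype labelings at once.

    ``labels`` is (n_perm, n_samples) of 0/1; returns (n_perm, n_snps).
    Genotype column totals are label-independent, so only the per-genotype
    case counts are recomputed per permutation (three matrix products).
    """
    labels = np.asarray(labels, dtype=float)
    masks = [(study.dosage == g).astype(float) for g in (0, 1, 2)]
    n_col = np.stack([m.sum(axis=0) for m in masks])          # (3, n_snps)
    case_counts = np.stack([labels @ m for m in masks])       # (3, n_perm, n_snps)
    w = np.array([0.0, 1.0, 2.0])
    N = n_col.sum(axis=0)                                     # (n_snps,)
    R = case_counts.sum(axis=0)                               # (n_perm, n_snps)
    sw_r = np.tensordot(w, case_counts, axes=(0, 0))
    sw_n = w @ n_col
    sw2_n = (w**2) @ n_col
    num = N[None, :] * sw_r - R * sw_n[None, :]
    den = R * (N[None, :] - R) * (N * sw2_n - sw_n**2)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, N[None, :] * num**2 / np.where(den > 0, den, 1.0), 0.0)


def permutation_labels(
    phenotype: np.ndarray, n_perm: int, seed: int | np.random.Generator
) -> np.ndarray:
    """(n_perm, n) matrix of permuted phenotype labels (shared stream)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.stack([rng.permutation(phenotype) for _ in range(n_perm)])


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    study: GenotypeStudy, snp_ids, r2_threshold: float, p_order: np.ndarray | None = None
) -> list[str]:
    """Greedy LD pruning in ascending-p order.

    A SNP is kept iff its dosage r-squared with every already-kept SNP is
    strictly below ``r2_threshold``.  ``p_order`` gives the scan priority
    (ascending p-values aligned with ``snp_ids``); by default the input
    order is used.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        return []
    cols = study.snp_index(snp_ids)
    dosage = _imputed_dosage(study)[:, cols]
    order = np.argsort(p_order, kind="stable") if p_order is not None else np.arange(len(snp_ids))
    sd = dosage.std(axis=0)
    centered = dosage - dosage.mean(axis=0)
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = (centered[:, i] @ centered[:, j]) / (len(centered) * sd[i] * sd[j])
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    kept_set = set(kept)
    return [snp_ids[i] for i in range(len(snp_ids)) if i in kept_set]


# ---------------------------------------------------------------------------
# PLINK-style set-based test


def _select_stat(chi2_vec: np.ndarray, crit: float, top_n: int) -> tuple[float, np.ndarray]:
    """Mean chi-square of the (up to) top_n statistics at or above crit."""
    qual = np.where(chi2_vec >= crit)[0]
    if len(qual) == 0:
        return 0.0, qual
    order = qual[np.argsort(-chi2_vec[qual], kind="stable")][:top_n]
    return float(chi2_vec[order].mean()), order


def set_test(
    study: GenotypeStudy,
    set_snp_map: dict[str, list[str]],
    cfg: SetTestConfig,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """PLINK-style set-based permutation test.

    Per set: LD-prune members, select up to ``top_n_snps`` SNPs with trend
    p at or below ``snp_p_threshold`` (ascending p), observed statistic =
    mean chi-square of the selected SNPs.  The null re-draws phenotype
    labels, recomputes every SNP's chi-square and redoes the selection.
    Sets with no qualifying SNP get p = 1 and no contributors.

    ``labels``: optional pre-drawn (n_perm, n_samples) permutation stream,
    shared across methods for comparability.
    """
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    crit = stats.chi2.isf(cfg.snp_p_threshold, df=1)
    obs_chi2_all = perm_chi2_matrix(study, study.phenotype[None, :])[0]
    if labels is None:
        labels = permutation_labels(study.phenotype, cfg.n_perm, cfg.seed)
    perm_chi2 = perm_chi2_matrix(study, labels)
    n_perm = labels.shape[0]

    records = []
    for name in sorted(set_snp_map):
        snps = set_snp_map[name]
        cols = study.snp_index(snps)
        pruned = ld_prune(study, snps, cfg.ld_r2_threshold, p_order=-obs_chi2_all[cols])
        pcols = study.snp_index(pruned)
        obs_stat, sel = _select_stat(obs_chi2_all[pcols], crit, cfg.top_n_snps)
        if len(sel) == 0:
            records.append((name, 0.0, 1.0, "", ""))
            continue
        contributors = [pruned[i] for i in sel]
        perm_sub = perm_chi2[:, pcols]
        exceed = 0
        for b in range(n_perm):
            stat_b, _ = _select_stat(perm_sub[b], crit, cfg.top_n_snps)
            if stat_b >= obs_stat:
                exceed += 1
        emp_p = (1 + exceed) / (1 + n_perm)
        records.append((name, obs_stat, emp_p, ",".join(contributors), ""))

    out = pd.DataFrame(
        records, columns=["set_id", "statistic", "emp_p", "contributors", "genes"]
    )
    return out.drop(columns="genes")


# ---------------------------------------------------------------------------
# GenGen-style enrichment


def gene_max_chi2(chi2_vec: np.ndarray, gene_cols: dict[str, np.ndarray]) -> dict[str, float]:
    """Per-gene statistic: maximum SNP chi-square among the gene's SNPs."""
    return {g: float(chi2_vec[cols].max()) for g, cols in gene_cols.items()}


def _es_for_ranked_scores(genes: np.ndarray, scores: np.ndarray, member_mask: np.ndarray,
                          weight: float) -> float:
    """ES of a member mask against (genes, scores) already rank-ordered.

    A set covering no gene — or every gene — carries no enrichment
    information and scores 0 (the running sum has nothing to deviate from).
    """
    n = len(genes)
    n_hits = int(member_mask.sum())
    if n_hits == 0 or n_hits == n:
        return 0.0
    w = np.abs(scores[member_mask]) ** weight
    delta = np.full(n, -1.0 / (n - n_hits))
    delta[member_mask] = w / w.sum()
    running = np.cumsum(delta)
    hi, lo = running.max(), running.min()
    return float(hi if hi >= -lo else lo)


def gengen_enrich(
    study: GenotypeStudy,
    gene_snp_map: dict[str, list[str]],
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    labels: np.ndarray | None = None,
    min_size: int = 1,
    max_size: int = 500,
) -> pd.DataFrame:
    """GenGen-style pathway enrichment.

    Each gene is represented by its most significant SNP (max trend
    chi-square); genes are ranked by that statistic and each pathway is
    scored by the weighted KS enrichment score.  The null recomputes gene
    statistics under phenotype permutations; the empirical p per set is
    one-sided against its own permutation ES distribution.
    """
    sets = sets.size_filtered(min_size, max_size)
    gene_names = sorted(g for g in gene_snp_map if gene_snp_map[g])
    gene_cols = {g: study.snp_index(gene_snp_map[g]) for g in gene_names}
    if labels is None:
        labels = permutation_labels(study.phenotype, n_perm, seed)
    n_perm = labels.shape[0]

    obs_chi2 = perm_chi2_matrix(study, study.phenotype[None, :])[0]
    perm_chi2 = perm_chi2_matrix(study, labels)

    genes_arr = np.array(gene_names, dtype=object)
    member_masks = {}
    for name in sorted(sets.sets):
        mask = np.isin(genes_arr, sorted(sets[name]))
        if not mask.any():
            logger.warning("gene set %r has no genes with SNPs; dropped", name)
            continue
        member_masks[name] = mask

    def ranked_view(chi2_vec: np.ndarray):
        scores = np.array([chi2_vec[gene_cols[g]].max() for g in gene_names])
        order = np.lexsort((genes_arr, -scores))
        return order, scores[order]

    obs_order, obs_scores = ranked_view(obs_chi2)
    obs_es = {
        name: _es_for_ranked_scores(
            genes_arr[obs_order], obs_scores, mask[obs_order], weight
        )
        for name, mask in member_masks.items()
    }

    exceed = {name: 0 for name in member_masks}
    for b in range(n_perm):
        order, scores = ranked_view(perm_chi2[b])
        for name, mask in member_masks.items():
            es_b = _es_for_ranked_scores(genes_arr[order], scores, mask[order], weight)
            if es_b >= obs_es[name]:
                exceed[name] += 1

    records = [
        (name, obs_es[name], (1 + exceed[name]) / (1 + n_perm),
         ",".join(sorted(genes_arr[member_masks[name]])))
        for name in sorted(member_masks)
    ]
    return pd.DataFrame(records, columns=["set_id", "statistic", "emp_p", "contributors"])


# ---------------------------------------------------------------------------
# INRICH-style interval enrichment


@dataclass
class Interval:
    """LD-clump association interval."""

    chrom: str
    start: int
    end: int
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def span_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0

    @property
    def density(self) -> float:
        return self.n_snps / self.span_kb


def make_intervals(
    assoc: pd.DataFrame,
    study: GenotypeStudy,
    p1: float = 0.01,
    p2: float = 0.05,
    r2: float = 0.5,
) -> list[Interval]:
    """Greedy LD clumping of association results into intervals.

    Index SNPs (p <= p1) are processed in ascending-p order; each absorbs
    every not-yet-assigned same-chromosome SNP with p <= p2 and dosage
    r-squared >= r2 with the index.  The clump's interval spans the min and
    max positions of its SNPs.  Output intervals are disjoint in SNPs.
    """
    tab = assoc.set_index("id")
    p = tab["p"].reindex(study.snp_table["id"]).to_numpy()
    chrom = study.snp_table["chrom"].to_numpy()
    pos = study.snp_table["pos"].to_numpy()
    ids = study.snp_table["id"].to_numpy()
    dosage = _imputed_dosage(study)
    sd = dosage.std(axis=0)
    centered = dosage - dosage.mean(axis=0)
    n = len(centered)

    assigned = np.zeros(len(ids), dtype=bool)
    intervals: list[Interval] = []
    for i in np.argsort(p, kind="stable"):
        if p[i] > p1:
            break
        if assigned[i]:
            continue
        members = [i]
        assigned[i] = True
        cand = np.where((~assigned) & (chrom == chrom[i]) & (p <= p2))[0]
        for j in cand:
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = (centered[:, i] @ centered[:, j]) / (n * sd[i] * sd[j])
            if r * r >= r2:
                members.append(j)
                assigned[j] = True
        members = sorted(members, key=lambda k: pos[k])
        intervals.append(
            Interval(
                chrom=str(chrom[members[0]]),
                start=int(min(pos[k] for k in members)),
                end=int(max(pos[k] for k in members)),
                snp_ids=[ids[k] for k in members],
            )
        )
    return intervals


class _GeneIndex:
    """Vectorized windowed interval-vs-gene overlap queries."""

    def __init__(self, genes: pd.DataFrame, window: int):
        self.symbols = genes["symbol"].to_numpy()
        self.chrom = genes["chrom"].to_numpy().astype(str)
        self.lo = genes["start"].to_numpy(dtype=np.int64) - window
        self.hi = genes["end"].to_numpy(dtype=np.int64) + window

    def overlap_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        return (self.chrom == chrom) & (self.lo <= end) & (self.hi >= start)

    def overlap_counts(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Number of overlapping genes for many same-chromosome windows."""
        on = self.chrom == chrom
        lo, hi = self.lo[on], self.hi[on]
        # genes x windows boolean overlap
        hit = (lo[:, None] <= ends[None, :]) & (hi[:, None] >= starts[None, :])
        return hit.sum(axis=0)


def _candidate_placements(
    interval: Interval, snp_table: pd.DataFrame, gene_index: _GeneIndex,
    snp_tol: float, density_tol: float, gene_exact: bool,
) -> list[tuple[str, int, int]]:
    """All windows of consecutive SNPs matching the interval's SNP count
    (within tolerance), overlapping-gene count, and SNP density per kb."""
    out = []
    n_genes_orig = int(
        gene_index.overlap_mask(interval.chrom, interval.start, interval.end).sum()
    )
    s = interval.n_snps
    lo_s = max(1, int(np.floor(s * (1 - snp_tol))))
    hi_s = int(np.ceil(s * (1 + snp_tol)))
    for chrom, grp in snp_table.groupby("chrom"):
        chrom = str(chrom)
        pos = np.sort(grp["pos"].to_numpy())
        for s2 in range(lo_s, hi_s + 1):
            if s2 > len(pos):
                continue
            starts = pos[: len(pos) - s2 + 1].astype(np.int64)
            ends = pos[s2 - 1:].astype(np.int64)
            dens = s2 / ((ends - starts + 1) / 1000.0)
            ok = np.ones(len(starts), dtype=bool)
            if interval.density > 0:
                ok &= (dens >= (1 - density_tol) * interval.density) & (
                    dens <= (1 + density_tol) * interval.density
                )
            if gene_exact and ok.any():
                counts = gene_index.overlap_counts(chrom, starts[ok], ends[ok])
                sub = np.where(ok)[0]
                ok[sub] = counts == n_genes_orig
            out.extend((chrom, int(a), int(b)) for a, b in zip(starts[ok], ends[ok]))
    return out


def inrich_test(
    intervals: list[Interval],
    genes: pd.DataFrame,
    sets: GeneSetCollection,
    snp_table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    window_kb: float = 20.0,
    snp_tol: float = 0.2,
    density_tol: float = 0.5,
    max_attempts: int = 1000,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """INRICH-style interval enrichment test.

    Observed statistic per set = number of intervals overlapping at least
    one set gene (gene windows extended by ``window_kb``).  Null intervals
    are windows of consecutive SNPs relocated uniformly over the SNP map,
    constrained to approximately match the original interval's SNP count
    (within ``snp_tol``), overlapping-gene count (exact), and SNP density
    per kb (within ``density_tol``); tolerances are relaxed stepwise when
    no placement qualifies.  ``exhaustive=True`` enumerates all placement
    combinations instead of sampling (small toys only).
    """
    if not intervals:
        raise ValueError("no intervals to test")
    window = int(round(window_kb * 1000))
    rng = np.random.default_rng(seed)
    gene_index = _GeneIndex(genes, window)

    candidates: list[list[tuple[str, int, int]]] = []
    for iv in intervals:
        tol_s, tol_d, exact = snp_tol, density_tol, True
        cand = _candidate_placements(iv, snp_table, gene_index, tol_s, tol_d, exact)
        attempts = 0
        while not cand and attempts < 4:
            attempts += 1
            if exact:
                exact = False
            else:
                tol_s *= 2
                tol_d *= 2
            logger.warning(
                "interval %s:%d-%d: relaxing relocation matching (snp_tol=%.2f, "
                "density_tol=%.2f, gene_exact=%s)", iv.chrom, iv.start, iv.end,
                tol_s, tol_d, exact,
            )
            cand = _candidate_placements(iv, snp_table, gene_index, tol_s, tol_d, exact)
        if not cand:
            cand = [(iv.chrom, iv.start, iv.end)]
            logger.warning("interval %s:%d-%d: no relocation found; frozen in place",
                           iv.chrom, iv.start, iv.end)
        candidates.append(cand)

    set_names = sorted(sets.sets)
    # gene x set membership matrix
    member_mat = np.column_stack(
        [np.isin(gene_index.symbols, sorted(sets[name])) for name in set_names]
    )

    def window_set_hits(chrom, start, end) -> np.ndarray:
        """Boolean per set: does this window overlap >= 1 set gene."""
        mask = gene_index.overlap_mask(chrom, start, end)
        return member_mat[mask].any(axis=0) if mask.any() else np.zeros(
            len(set_names), dtype=bool
        )

    observed = np.sum(
        [window_set_hits(iv.chrom, iv.start, iv.end) for iv in intervals], axis=0
    )
    # per interval, per candidate placement, per set: overlap indicator
    cand_hits = [
        np.stack([window_set_hits(c, s, e) for c, s, e in cand]) for cand in candidates
    ]

    if exhaustive:
        import itertools

        combos = list(itertools.product(*[range(len(c)) for c in candidates]))
        null_counts = np.stack(
            [sum(cand_hits[i][j] for i, j in enumerate(combo)) for combo in combos]
        )
    else:
        null_counts = np.zeros((n_perm, len(set_names)), dtype=np.int64)
        for i, hits in enumerate(cand_hits):
            idx = rng.integers(len(hits), size=n_perm)
            null_counts += hits[idx]
    exceed = (null_counts >= observed[None, :]).sum(axis=0)
    emp_p = (1 + exceed) / (1 + null_counts.shape[0])

    return pd.DataFrame(
        {"set_id": set_names, "statistic": observed, "emp_p": emp_p, "contributors": ""}
    )


# ---------------------------------------------------------------------------
# Adaptor: gene-level empirical p -> pre-ranked gene list


def gene_p_to_ranklist(gene_results: dict[str, float]) -> RankedList:
    """Ranked list from gene-level empirical p-values.

    Genes with p = 1 (no significant SNP) are removed; the score is the
    log base 0.05 of the p-value, sorted descending with lexicographic
    tie-breaking.
    """
    scores = {g: float(np.log(p) / np.log(0.05)) for g, p in gene_results.items() if p < 1.0}
    if not scores:
        raise ValueError("no genes remain after removing p = 1")
    if any(p <= 0 for p in gene_results.values()):
        raise ValueError("p-values must lie in (0, 1]")
    return RankedList.from_dict(scores)
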