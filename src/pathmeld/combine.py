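"""Combination of correlated per-method pathway p-values.

The four pathway-level GWAS statistics are correlated (they share the
genotype data), so naive Fisher/Stouffer combination is anticonservative.
Instead, pathways are ranked within each method, the observed average rank
is compared with average ranks of simulated null matrices whose columns
are uniform on [0, 1] with the methods' empirical Pearson correlation,
realized through a Gaussian copula built from the Cholesky factor of the
correlation matrix.  Multiplying uniforms directly by the Cholesky factor
would destroy marginal uniformity; the normal-score route preserves it
while inducing the target correlation (in the Gaussian-copula sense).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def align_pvalue_matrix(per_method: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Merge per-method {pathway: p} maps into a pathways x methods frame.

    Pathways missing from a method (e.g. dropped for lack of intervals)
    are imputed p = 1, logged via warning.
    """
    universe = sorted(set().union(*[set(d) for d in per_method.values()]))
    out = pd.DataFrame(index=universe, dtype=float)
    for method, d in per_method.items():
        missing = [pw for pw in universe if pw not in d]
        if missing:
            warnings.warn(
                f"method {method!r}: {len(missing)} pathways missing; imputed p = 1"
            )
        out[method] = [d.get(pw, 1.0) for pw in universe]
    _check_pmat(out)
    return out


def _check_pmat(pmat: pd.DataFrame) -> None:
    vals = pmat.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("p-value matrix contains missing values")
    if (vals <= 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")


def method_correlation(pmat: pd.DataFrame) -> np.ndarray:
    """Pearson correlation matrix of the methods' p-value columns."""
    _check_pmat(pmat)
    if pmat.shape[0] < 3:
        raise ValueError("need at least 3 pathways to estimate correlations")
    if pmat.shape[1] < 2:
        raise ValueError("need at least 2 methods")
    vals = pmat.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        bad = list(pmat.columns[sd == 0])
        raise ValueError(f"zero-variance method column(s): {bad}")
    A = np.corrcoef(vals, rowvar=False)
    np.fill_diagonal(A, 1.0)
    return A


def nearest_psd_cholesky(A: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Upper-triangular factor L with A = L.T @ L, after eigenvalue
    clipping when the sample correlation matrix is not PSD."""
    try:
        return np.linalg.cholesky(A).T
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(A)
        w = np.clip(w, clip, None)
        A_fix = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(A_fix))
        A_fix = A_fix / np.outer(d, d)
        return np.linalg.cholesky(A_fix).T


def correlated_uniforms(
    L: np.ndarray, n_rows: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Rows of uniforms on [0, 1] with Gaussian-copula correlation L.T @ L.

    Independent uniforms are mapped to normal scores, mixed by L, and
    mapped back through the normal CDF, so each column stays marginally
    uniform while pairwise correlation approximates the target.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = L.shape[0]
    z = stats.norm.ppf(rng.random((n_rows, m)).clip(1e-12, 1 - 1e-12))
    corr_z = z @ L  # rows z_i -> z_i @ L so cov = L.T L = A
    return stats.norm.cdf(corr_z)


@dataclass
class CombineResult:
    """Observed average rankings and pooled-null combined p-values."""

    table: pd.DataFrame          # set_id, mean_rank, combined_p
    correlation: np.ndarray      # A
    cholesky: np.ndarray         # upper-triangular L, A = L.T @ L
    n_sim: int
    seed: int
    metadata: dict

    def top(self, k: int = 20, max_p: float = 0.05) -> list[str]:
        """Top-k pathways by combined p, restricted to combined p < max_p."""
        tab = self.table.sort_values(["combined_p", "mean_rank", "set_id"])
        tab = tab[tab["combined_p"] < max_p]
        if len(tab) < k:
            warnings.warn(f"only {len(tab)} pathways with combined p < {max_p}")
        return list(tab["set_id"].head(k))


def mc_combine(
    pmat: pd.DataFrame,
    n_sim: int = 10_000,
    seed: int = 0,
    correlation: np.ndarray | None = None,
) -> CombineResult:
    """Monte-Carlo combination of correlated per-method p-values.

    Pathways are ranked ascending by p within each method (average ranks on
    ties); each simulation draws a correlated-uniform matrix of the same
    shape, ranks within columns, and averages per row.  The combined p of a
    pathway is the pooled-null fraction of simulated average ranks at or
    below its observed average rank, with the (1+b)/(1+n) correction.

    ``correlation`` overrides the Pearson matrix estimated from ``pmat``
    (e.g. a known correlation structure, or identity for independence).
    """
    _check_pmat(pmat)
    if n_sim < 100:
        warnings.warn(f"n_sim = {n_sim} is small; combined p resolution is coarse")
    n_path, n_meth = pmat.shape
    ranks = pmat.rank(axis=0, method="average")
    obs_mean = ranks.mean(axis=1).to_numpy()

    if correlation is not None:
        A = np.asarray(correlation, dtype=float)
    elif n_meth == 1:
        A = np.eye(1)
    else:
        A = method_correlation(pmat)
    L = nearest_psd_cholesky(A)
    rng = np.random.default_rng(seed)
    null_means = np.empty((n_sim, n_path))
    for s in range(n_sim):
        u = correlated_uniforms(L, n_path, rng)
        null_ranks = stats.rankdata(u, axis=0, method="average")
        null_means[s] = null_ranks.mean(axis=1)
    pooled = np.sort(null_means.ravel())
    below = np.searchsorted(pooled, obs_mean, side="right")
    combined_p = (1 + below) / (1 + pooled.size)

    table = pd.DataFrame(
        {"set_id": pmat.index, "mean_rank": obs_mean, "combined_p": combined_p}
    ).reset_index(drop=True)
    return CombineResult(
        table=table,
        correlation=A,
        cholesky=L,
        n_sim=n_sim,
        seed=seed if isinstance(seed, int) else -1,
        metadata={"null": "pooled", "ties": "average", "estimator": "(1+b)/(1+n)"},
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-stable)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# Confounder diagnostics


def snp_frequency_per_kb(gene_snp_map: dict[str, list], genes: pd.DataFrame) -> pd.Series:
    """SNP count per kilobase of gene length, per gene."""
    lengths = (genes.set_index("symbol")["end"] - genes.set_index("symbol")["start"] + 1) / 1000.0
    out = {}
    for g, snps in gene_snp_map.items():
        if g in lengths.index:
            out[g] = len(snps) / lengths[g]
    return pd.Series(out, dtype=float)


def _safe_pearson(x, y) -> float:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def confounder_diagnostics(
    combined: pd.DataFrame,
    sets,
    gene_snp_map: dict[str, list],
    genes: pd.DataFrame,
    gene_p: dict[str, float] | None = None,
) -> dict[str, float]:
    """Correlations probing whether pathway significance tracks annotation
    artifacts (pathway size, per-gene SNP density, annotation degree).

    ``combined`` needs columns set_id and combined_p.  Undefined
    correlations (constant inputs) are reported as NaN.
    """
    sizes = np.array([len(sets[s]) for s in combined["set_id"]])
    report = {
        "pathway_size_vs_combined_p": _safe_pearson(sizes, combined["combined_p"]),
    }
    freq = snp_frequency_per_kb(gene_snp_map, genes)
    degree = pd.Series(
        {g: sum(1 for _, gs in sets.items() if g in gs) for g in freq.index}, dtype=float
    )
    common = freq.index.intersection(degree.index)
    report["snp_freq_vs_annotation_degree"] = _safe_pearson(freq[common], degree[common])
    with np.errstate(divide="ignore"):
        report["log_snp_freq_vs_annotation_degree"] = _safe_pearson(
            np.log(freq[common].clip(lower=1e-12)), degree[common]
        )
    if gene_p is not None:
        common = freq.index.intersection(pd.Index(gene_p))
        pv = np.array([gene_p[g] for g in common])
        report["snp_freq_vs_gene_p"] = _safe_pearson(freq[common], pv)
        report["log_snp_freq_vs_gene_p"] = _safe_pearson(
            np.log(freq[common].clip(lower=1e-12)), pv
        )
    return report


def bootstrap_snp_freq(
    top_sets,
    all_sets,
    gene_freq: pd.Series | dict[str, float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical p of the top pathways' mean per-gene SNP frequency against
    equally sized random pathway draws (with replacement) from the
    collection."""
    gene_freq = pd.Series(gene_freq, dtype=float)
    top_sets = list(top_sets)
    names = sorted(all_sets.sets)
    if len(top_sets) > len(names):
        raise ValueError("more top sets than pathways in the collection")

    def mean_freq(set_names) -> float:
        vals = []
        for s in set_names:
            vals.extend(gene_freq[g] for g in all_sets[s] if g in gene_freq.index)
        return float(np.mean(vals)) if vals else float("nan")

    observed = mean_freq(top_sets)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        draw = rng.choice(names, size=len(top_sets), replace=True)
        if mean_freq(draw) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_boot)
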