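"""Patient stratification by NMF consensus clustering of pathway SNP burden.

Per-patient SNP dosages are summed within each top pathway, z-scored per
pathway, and shifted by the global matrix minimum so the matrix is
nonnegative.  Repeated NMF runs from random initializations give a
consensus co-clustering matrix per candidate rank; the rank whose
consensus matrix is most dendrogram-like (highest cophenetic correlation)
is chosen, and pathways driving the split are found by t-tests between
the resulting subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from .core_io import MISSING, GenotypeStudy

logger = logging.getLogger(__name__)


def pathway_burden(study: GenotypeStudy, set_snp_map: dict[str, list[str]]) -> pd.DataFrame:
    """Pathways x patients normalized SNP burden matrix.

    Burden = sum of minor-allele dosages over the pathway's SNPs (missing
    dosages mean-imputed per SNP); each pathway row is z-scored, then the
    global matrix minimum is subtracted so every entry is nonnegative.
    Constant-burden pathways (undefined z-score) are dropped with a log.
    """
    dosage = study.dosage.astype(float)
    miss = study.dosage == MISSING
    if miss.any():
        obs = np.where(miss, np.nan, dosage)
        means = np.nan_to_num(np.nanmean(obs, axis=0))
        dosage = np.where(miss, means[None, :], dosage)
    rows = {}
    for name in sorted(set_snp_map):
        snps = set_snp_map[name]
        if not snps:
            logger.warning("pathway %r has no SNPs; dropped", name)
            continue
        cols = study.snp_index(snps)
        burden = dosage[:, cols].sum(axis=1)
        sd = burden.std()
        if sd == 0:
            logger.warning("pathway %r has constant burden; dropped", name)
            continue
        rows[name] = (burden - burden.mean()) / sd
    if not rows:
        raise ValueError("no pathway with variable burden")
    M = pd.DataFrame(rows, index=study.sample_ids).T
    return M - M.to_numpy().min()


def nmf_factorize(
    M: np.ndarray,
    rank: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative-update NMF minimizing Frobenius error.

    Returns the best (W, H, relative reconstruction error) over
    ``n_restarts`` random initializations.  The multiplicative updates
    guarantee a nonincreasing objective.
    """
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise ValueError("matrix must be nonnegative")
    if rank >= min(M.shape):
        raise ValueError(f"rank {rank} must be < min(dims) = {min(M.shape)}")
    rng = np.random.default_rng(seed)
    norm_M = np.linalg.norm(M)
    best = None
    eps = 1e-12
    for _ in range(n_restarts):
        W = rng.random((M.shape[0], rank)) + 0.1
        H = rng.random((rank, M.shape[1])) + 0.1
        prev = np.inf
        for _ in range(max_iter):
            H *= (W.T @ M) / (W.T @ W @ H + eps)
            W *= (M @ H.T) / (W @ H @ H.T + eps)
            err = np.linalg.norm(M - W @ H) / max(norm_M, eps)
            if prev - err < tol:
                break
            prev = err
        if best is None or err < best[2]:
            best = (W, H, float(err))
    return best


@dataclass
class ConsensusResult:
    """NMF consensus clustering output."""

    consensus: dict[int, np.ndarray]     # rank -> patients x patients matrix
    cophenetic: dict[int, float]         # rank -> cophenetic coefficient
    chosen_rank: int
    labels: np.ndarray                   # hard cluster labels at chosen rank
    sample_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


def _cophenetic_coefficient(consensus: np.ndarray) -> tuple[float, np.ndarray]:
    """Cophenetic correlation of a consensus matrix and its linkage."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    link = average(condensed)
    if np.allclose(condensed, condensed[0]):
        return 1.0, link  # perfectly stable (all-equal distances)
    coef, _ = cophenet(link, condensed)
    return float(coef), link


def consensus_cluster(
    M: pd.DataFrame,
    ranks=(2, 3, 4),
    n_runs: int = 50,
    seed: int = 0,
    nmf_max_iter: int = 500,
) -> ConsensusResult:
    """Consensus clustering over NMF restarts with cophenetic rank choice.

    For each candidate rank, ``n_runs`` NMF fits each assign every patient
    to the argmax row of H; consensus(i, j) = fraction of runs co-clustering
    i and j.  The chosen rank maximizes the cophenetic correlation between
    (1 - consensus) distances and their average-linkage dendrogram; hard
    labels come from cutting that dendrogram at the chosen rank.
    """
    X = M.to_numpy(dtype=float)
    n_pat = X.shape[1]
    ranks = [r for r in ranks]
    if any(r < 2 or r > n_pat - 1 for r in ranks):
        raise ValueError("ranks must lie in [2, patients - 1]")
    rng = np.random.default_rng(seed)
    consensus = {}
    cophenetic = {}
    links = {}
    for r in ranks:
        co = np.zeros((n_pat, n_pat))
        for _ in range(n_runs):
            _, H, _ = nmf_factorize(
                X, r, n_restarts=1, seed=int(rng.integers(2**31 - 1)),
                max_iter=nmf_max_iter,
            )
            lab = H.argmax(axis=0)
            co += (lab[:, None] == lab[None, :]).astype(float)
        co /= n_runs
        np.fill_diagonal(co, 1.0)
        consensus[r] = co
        cophenetic[r], links[r] = _cophenetic_coefficient(co)
    chosen = max(ranks, key=lambda r: (cophenetic[r], -r))
    labels = fcluster(links[chosen], t=chosen, criterion="maxclust")
    return ConsensusResult(
        consensus=consensus,
        cophenetic=cophenetic,
        chosen_rank=chosen,
        labels=labels,
        sample_ids=list(M.columns),
        metadata={"n_runs": n_runs, "seed": seed, "objective": "frobenius"},
    )


def subgroup_pathway_tests(
    M: pd.DataFrame, labels, welch: bool = True
) -> pd.DataFrame:
    """Two-sample t-test per pathway row between the two subgroups.

    Welch's unequal-variance t by default (subgroup sizes are typically
    unbalanced); the pooled-variance test via ``welch=False``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 subgroups, got {len(classes)}")
    g1, g2 = labels == classes[0], labels == classes[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each subgroup needs at least 2 patients")
    X = M.to_numpy(dtype=float)
    t, p = stats.ttest_ind(X[:, g1], X[:, g2], axis=1, equal_var=not welch)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"set_id": M.index, "t": t, "p": p}).reset_index(drop=True)
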