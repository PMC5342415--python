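"""Self-contained GSEA pre-ranked engine.

Computes weighted Kolmogorov-Smirnov enrichment scores over a ranked gene
list, with a gene-identity permutation null, normalized enrichment scores,
and an FDR q estimated from the pooled normalized null (BH q on nominal
p-values is emitted alongside for comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combine import bh_fdr
from .core_io import GeneSetCollection, log005


@dataclass
class RankedList:
    """Gene symbols with real-valued scores, strictly ordered descending.

    Ties in score are broken by symbol (ascending) so runs are reproducible.
    """

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        if len(genes) != len(scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols in ranked list")
        order = np.lexsort((genes, -scores))
        self.genes = genes[order]
        self.scores = scores[order]

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_dict(cls, scores: dict[str, float]) -> "RankedList":
        return cls(np.array(list(scores), dtype=object), np.array(list(scores.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
):
    """Weighted KS enrichment score of ``gene_set`` in the ranked list.

    Walking the list, genes in the set increment the running sum by
    |score|^weight (normalized over set hits) and the rest decrement it by
    1/(n_total - n_hits).  Returns ``(ES, running, leading_edge)`` where
    ES is the signed extremum of the running sum.
    """
    hit = np.isin(ranked.genes, list(gene_set))
    if not hit.any():
        raise ValueError("set not represented in the ranked list")
    n = len(ranked)
    n_hits = int(hit.sum())
    if n_hits == n:
        delta = np.abs(ranked.scores) ** weight
        delta = delta / delta.sum()
    else:
        weights = np.abs(ranked.scores[hit]) ** weight
        delta = np.full(n, -1.0 / (n - n_hits))
        delta[hit] = weights / weights.sum()
    running = np.cumsum(delta)
    i_max, i_min = int(running.argmax()), int(running.argmin())
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = ranked.genes[: i_max + 1][hit[: i_max + 1]]
    else:
        es = float(running[i_min])
        leading = ranked.genes[i_min:][hit[i_min:]]
    return es, running, list(leading)


def _null_es(scores: np.ndarray, k: int, weight: float, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random k-subsets of the list (gene-ID permutation).

    Vectorized over permutations using the fact that the running sum's
    extrema occur at hit positions (just after a hit for the maximum,
    just before for the minimum).
    """
    n = len(scores)
    if k == n:
        return np.ones(n_perm)
    u = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1)
    w = np.abs(scores[pos]) ** weight
    hit_cum = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
    miss_before = (pos - np.arange(k)) / (n - k)
    at_hit = hit_cum - miss_before
    before_hit = np.concatenate(
        [np.zeros((n_perm, 1)), hit_cum[:, :-1]], axis=1
    ) - miss_before
    hi = at_hit.max(axis=1)
    lo = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def prerank(
    ranked: RankedList,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 1,
    max_size: int = 500,
) -> pd.DataFrame:
    """GSEA pre-ranked test for every gene set.

    Null built by permuting gene identities (random equal-size subsets of
    the list); nominal p is one-sided on the observed sign; NES divides ES
    by the mean |null ES| of the same sign; FDR q is the GSEA-style ratio
    of null to observed tail fractions over pooled NES, clipped to [0, 1].
    Sets with no gene in the list are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    sets = sets.size_filtered(min_size, max_size)
    gene_pool = set(ranked.genes)

    records = []
    null_nes_pool: list[np.ndarray] = []
    for name in sorted(sets.sets):
        members = sets[name] & gene_pool
        if not members:
            warnings.warn(f"gene set {name!r} not represented in ranked list; dropped")
            continue
        es, _, leading = enrichment_score(ranked, members, weight)
        null = _null_es(ranked.scores, len(members), weight, n_perm, rng)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) < 10:
            warnings.warn(f"gene set {name!r}: fewer than 10 same-sign null values")
            nom_p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
            nes = np.nan
            records.append((name, es, nes, nom_p, leading))
            null_nes_pool.append(np.array([]))
            continue
        nom_p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
        mean_same = np.abs(same_sign).mean()
        nes = es / mean_same
        # normalize the whole null of this set for the pooled FDR null
        pos, neg = null[null >= 0], null[null < 0]
        norm_null = np.concatenate(
            [
                pos / pos.mean() if len(pos) else pos,
                neg / np.abs(neg).mean() if len(neg) else neg,
            ]
        )
        records.append((name, es, nes, nom_p, leading))
        null_nes_pool.append(norm_null)

    if not records:
        raise ValueError("no gene set overlaps the ranked list")

    pooled = np.concatenate([a for a in null_nes_pool if len(a)]) if null_nes_pool else np.array([])
    obs_nes = np.array([r[2] for r in records])
    qs = np.full(len(records), np.nan)
    for i, (_, es, nes, _, _) in enumerate(records):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_tail = np.mean(pooled >= nes) if len(pooled) else np.nan
            obs_tail = np.mean(obs_nes[np.isfinite(obs_nes)] >= nes)
        else:
            null_tail = np.mean(pooled <= nes) if len(pooled) else np.nan
            obs_tail = np.mean(obs_nes[np.isfinite(obs_nes)] <= nes)
        qs[i] = np.clip(null_tail / max(obs_tail, 1e-12), 0.0, 1.0)

    nom_ps = np.array([r[3] for r in records])
    return pd.DataFrame(
        {
            "set_id": [r[0] for r in records],
            "es": [r[1] for r in records],
            "nes": obs_nes,
            "nom_p": nom_ps,
            "fdr_q": qs,
            "fdr_bh": bh_fdr(nom_ps),
            "leading_edge": [",".join(r[4]) for r in records],
        }
    )


def prepare_mutation_ranklist(gene_p: dict[str, float]) -> RankedList:
    """Ranked list from gene-level mutation p-values.

    Scores are log base 0.05 of p; genes with p = 1 (score 0, carrying no
    mutation signal) are removed before ranking.
    """
    if not gene_p:
        raise ValueError("empty gene p-value table")
    scores = {g: float(log005(p)) for g, p in gene_p.items() if p < 1.0}
    if not scores:
        raise ValueError("all genes have p = 1; empty ranked list")
    return RankedList.from_dict(scores)
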