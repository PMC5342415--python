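"""Single-SNP association: Cochran-Armitage trend test, genomic control,
and multifactor dimensionality reduction (MDR) interaction search.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeStudy

CHI2_MEDIAN_1DF = 0.45493642311957283  # median of chi-square(1)

_WEIGHTS = np.array([0.0, 1.0, 2.0])


def genotype_counts(dosage: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Per-SNP 2 x 3 genotype count tables.

    Returns an (n_snps, 2, 3) array: axis 1 is phenotype (0 = control,
    1 = case), axis 2 the genotype dosage.  Missing genotypes are excluded.
    """
    counts = np.empty((dosage.shape[1], 2, 3), dtype=np.int64)
    for ph in (0, 1):
        rows = dosage[phenotype == ph]
        for g in (0, 1, 2):
            counts[:, ph, g] = (rows == g).sum(axis=0)
    return counts


def trend_chi2(counts: np.ndarray) -> np.ndarray:
    """Vectorized Cochran-Armitage trend chi-square (additive weights 0,1,2).

    ``counts`` is (..., 2, 3) with controls in row 0, cases in row 1.
    Monomorphic tables (trend variance zero) yield statistic 0.
    """
    counts = np.asarray(counts, dtype=float)
    n_col = counts.sum(axis=-2)          # genotype totals
    cases = counts[..., 1, :]
    R = cases.sum(axis=-1)               # case total
    N = n_col.sum(axis=-1)
    sw_r = (cases * _WEIGHTS).sum(axis=-1)
    sw_n = (n_col * _WEIGHTS).sum(axis=-1)
    sw2_n = (n_col * _WEIGHTS**2).sum(axis=-1)
    num = N * sw_r - R * sw_n
    den = R * (N - R) * (N * sw2_n - sw_n**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, N * num**2 / np.where(den > 0, den, 1.0), 0.0)
    return chi2


def trend_test(counts: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test on a single 2 x 3 table.

    Returns (chi-square statistic, p-value from chi-square with 1 df).
    A monomorphic table returns (0.0, 1.0).
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 3):
        raise ValueError("counts must be a 2 x 3 table (phenotype x genotype)")
    chi2 = float(trend_chi2(counts))
    if chi2 == 0.0:
        return 0.0, 1.0
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class SnpAssocResult:
    """Per-SNP trend-test results with genomic-control correction."""

    table: pd.DataFrame  # columns: id, chrom, pos, chisq, p, gcp
    counts: np.ndarray   # (n_snps, 2, 3)
    lambda_gc: float | None = None

    def __getitem__(self, snp_id: str) -> pd.Series:
        return self.table.set_index("id").loc[snp_id]


def snp_association(study: GenotypeStudy) -> SnpAssocResult:
    """Trend test for every SNP in the study (no GC correction yet)."""
    counts = genotype_counts(study.dosage, study.phenotype)
    chi2 = trend_chi2(counts)
    p = np.where(chi2 > 0, stats.chi2.sf(chi2, df=1), 1.0)
    table = pd.DataFrame(
        {
            "id": study.snp_table["id"],
            "chrom": study.snp_table["chrom"],
            "pos": study.snp_table["pos"],
            "chisq": chi2,
            "p": p,
            "gcp": p,
        }
    )
    return SnpAssocResult(table=table, counts=counts)


def genomic_control(result: SnpAssocResult) -> SnpAssocResult:
    """Genomic-control correction: divide chi-squares by the inflation
    factor lambda = median(chi2)/0.4549 when lambda > 1."""
    table = result.table.copy()
    if len(table) < 100:
        warnings.warn(
            f"genomic control on {len(table)} SNPs; lambda is unstable below ~100"
        )
    lam = float(np.median(table["chisq"])) / CHI2_MEDIAN_1DF
    if lam > 1.0:
        corrected = table["chisq"].to_numpy() / lam
        table["gcp"] = np.where(corrected > 0, stats.chi2.sf(corrected, df=1), 1.0)
    else:
        table["gcp"] = table["p"]
    return SnpAssocResult(table=table, counts=result.counts, lambda_gc=lam)


# ---------------------------------------------------------------------------
# MDR


@dataclass
class MdrResult:
    """Best multilocus models per interaction order.

    ``per_order`` maps order -> dict with keys ``combination`` (tuple of
    SNP ids), ``consistency`` (folds in which selected), ``test_bal_acc``.
    ``perm_p`` is the phenotype-permutation p of the overall best model's
    mean testing balanced accuracy.
    """

    per_order: dict[int, dict]
    best: dict
    perm_p: float | None
    n_folds: int
    metadata: dict = field(default_factory=dict)


def _stratified_folds(phenotype: np.ndarray, n_folds: int, rng: np.random.Generator):
    folds = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.where(phenotype == cls)[0]
        if len(idx) < n_folds:
            raise ValueError(
                f"cannot build {n_folds} stratified folds: class {cls} has {len(idx)} samples"
            )
        idx = rng.permutation(idx)
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(chunk.tolist())
    return [np.array(sorted(f)) for f in folds]


def _mdr_eval(cells_train, cells_test, y_train, y_test):
    """Label multilocus cells high/low risk on training data, score test.

    High risk iff the cell's case:control ratio is at least the overall
    training ratio; empty cells are low risk.  Returns (train balanced
    accuracy, test balanced accuracy).
    """
    ratio_all = y_train.sum() / max((1 - y_train).sum(), 1)
    high: set = set()
    cases: dict = {}
    ctrls: dict = {}
    for c, y in zip(cells_train, y_train):
        if y:
            cases[c] = cases.get(c, 0) + 1
        else:
            ctrls[c] = ctrls.get(c, 0) + 1
    for c in set(cases) | set(ctrls):
        nca, nco = cases.get(c, 0), ctrls.get(c, 0)
        if nco == 0 or nca / nco >= ratio_all:
            if nca > 0:
                high.add(c)

    def bal_acc(cells, y):
        pred = np.fromiter((c in high for c in cells), dtype=bool, count=len(y))
        pos, neg = y == 1, y == 0
        sens = pred[pos].mean() if pos.any() else 0.0
        spec = (~pred[neg]).mean() if neg.any() else 0.0
        return 0.5 * (sens + spec)

    return bal_acc(cells_train, y_train), bal_acc(cells_test, y_test)


def _mdr_cv(dosage, y, combos, folds):
    """Cross-validate every combination; return per-combo mean test accuracy
    and per-fold winning combination (by training balanced accuracy)."""
    n_c = len(combos)
    test_acc = np.zeros((n_c, len(folds)))
    train_acc = np.zeros((n_c, len(folds)))
    all_idx = np.arange(len(y))
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        for ci, combo in enumerate(combos):
            cells_train = list(map(tuple, dosage[np.ix_(train_idx, combo)]))
            cells_test = list(map(tuple, dosage[np.ix_(test_idx, combo)]))
            train_acc[ci, k], test_acc[ci, k] = _mdr_eval(
                cells_train, cells_test, y[train_idx], y[test_idx]
            )
    fold_winner = train_acc.argmax(axis=0)
    return test_acc.mean(axis=1), fold_winner


def mdr_search(
    study: GenotypeStudy,
    snp_subset,
    max_order: int = 2,
    n_folds: int = 10,
    n_perm: int = 0,
    seed: int = 0,
) -> MdrResult:
    """Exhaustive MDR over combinations of the given SNPs.

    Within each cross-validation fold the best combination is chosen by
    training balanced accuracy; the reported best model per order is the
    one with highest mean testing balanced accuracy, with cross-validation
    consistency = number of folds in which it won.  The permutation p
    compares the best model's mean testing accuracy to phenotype-permuted
    re-runs of the full search.
    """
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")
    snp_subset = list(snp_subset)
    cols = study.snp_index(snp_subset)
    dosage = study.dosage[:, cols]
    y = study.phenotype
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)

    per_order: dict[int, dict] = {}
    for order in range(1, max_order + 1):
        combos = list(itertools.combinations(range(len(snp_subset)), order))
        mean_test, fold_winner = _mdr_cv(dosage, y, combos, folds)
        # consistency counted for the highest-mean-test-accuracy model;
        # ties on consistency break to higher mean testing accuracy
        best_ci = int(mean_test.argmax())
        consistency = int((fold_winner == best_ci).sum())
        per_order[order] = {
            "combination": tuple(snp_subset[i] for i in combos[best_ci]),
            "consistency": consistency,
            "test_bal_acc": float(mean_test[best_ci]),
        }

    best_order = max(per_order, key=lambda o: per_order[o]["test_bal_acc"])
    best = dict(per_order[best_order], order=best_order)

    perm_p = None
    if n_perm > 0:
        combos = list(itertools.combinations(range(len(snp_subset)), best_order))
        observed = best["test_bal_acc"]
        exceed = 0
        for _ in range(n_perm):
            y_perm = rng.permutation(y)
            folds_p = _stratified_folds(y_perm, n_folds, rng)
            mean_test, _ = _mdr_cv(dosage, y_perm, combos, folds_p)
            if mean_test.max() >= observed:
                exceed += 1
        perm_p = (1 + exceed) / (1 + n_perm)

    return MdrResult(
        per_order=per_order,
        best=best,
        perm_p=perm_p,
        n_folds=n_folds,
        metadata={
            "scoring": "balanced_accuracy",
            "empty_cells": "low_risk",
            "folds": "stratified",
            "seed": seed,
        },
    )
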