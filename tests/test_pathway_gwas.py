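import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathmeld.core_io import GeneSetCollection
from pathmeld.gwas_assoc import snp_association, trend_chi2, genotype_counts
from pathmeld.pathway_gwas import (
    Interval,
    SetTestConfig,
    gene_p_to_ranklist,
    gengen_enrich,
    inrich_test,
    ld_prune,
    make_intervals,
    perm_chi2_matrix,
    permutation_labels,
    set_test,
)

from .conftest import make_study


def _r2(a, b):
    return np.corrcoef(a, b)[0, 1] ** 2


def _ld_chain_study(seed=0, n=4000):
    """Three SNPs with Markov LD: r2(1,2) and r2(2,3) high, r2(1,3) lower."""
    rng = np.random.default_rng(seed)
    h1 = rng.random((2 * n,)) < 0.5
    copy12 = rng.random(2 * n) < 0.78
    h2 = np.where(copy12, h1, rng.random(2 * n) < 0.5)
    copy23 = rng.random(2 * n) < 0.78
    h3 = np.where(copy23, h2, rng.random(2 * n) < 0.5)
    dosage = np.column_stack(
        [h[0::2].astype(int) + h[1::2].astype(int) for h in (h1, h2, h3)]
    ).astype(np.int8)
    return make_study(dosage, [0, 1] * (n // 2))


class TestLdPrune:
    def test_perfectly_correlated_keeps_one(self):
        dosage = np.array([[0, 0], [1, 1], [2, 2], [1, 1]] * 3, dtype=np.int8)
        study = make_study(dosage, [0, 1] * 6)
        kept = ld_prune(study, ["rs1", "rs2"], r2_threshold=0.5)
        assert len(kept) == 1

    def test_independent_all_kept(self, null_study):
        ids = list(null_study.snp_ids[:10])
        kept = ld_prune(null_study, ids, r2_threshold=0.5)
        assert kept == ids

    def test_chain_greedy_hand_trace(self):
        """A~B and B~C above threshold, A~C below; priority order A<B<C
        keeps exactly {A, C} under the greedy rule."""
        study = _ld_chain_study()
        d = study.dosage.astype(float)
        assert _r2(d[:, 0], d[:, 1]) >= 0.5
        assert _r2(d[:, 1], d[:, 2]) >= 0.5
        assert _r2(d[:, 0], d[:, 2]) < 0.5
        kept = ld_prune(
            study, ["rs1", "rs2", "rs3"], r2_threshold=0.5,
            p_order=np.array([0.001, 0.01, 0.02]),
        )
        assert kept == ["rs1", "rs3"]


class TestSetTest:
    def test_selection_rule_and_statistic(self, rng):
        n, m = 200, 3
        dosage = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        # make SNP 1 and 3 associated, SNP 2 null
        y = np.zeros(n, dtype=int)
        score = dosage[:, 0] + dosage[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-(score - score.mean()) * 1.5))).astype(int)
        study = make_study(dosage, y)
        assoc = snp_association(study)
        qual = assoc.table[assoc.table["p"] <= 0.05]
        if len(qual) < 2:
            pytest.skip("construction did not reach significance")
        cfg = SetTestConfig(top_n_snps=5, snp_p_threshold=0.05, ld_r2_threshold=1.0,
                            n_perm=10, seed=0)
        out = set_test(study, {"S": ["rs1", "rs2", "rs3"]}, cfg)
        contributors = out.loc[0, "contributors"].split(",")
        assert set(contributors) == set(qual["id"])
        expected = assoc.table.set_index("id").loc[contributors, "chisq"].mean()
        assert out.loc[0, "statistic"] == pytest.approx(expected, rel=1e-10)

    def test_no_qualifying_snp_p_one(self, null_study):
        cfg = SetTestConfig(top_n_snps=5, snp_p_threshold=1e-12, n_perm=20, seed=0)
        out = set_test(null_study, {"S": list(null_study.snp_ids[:5])}, cfg)
        assert out.loc[0, "emp_p"] == 1.0
        assert out.loc[0, "contributors"] == ""

    def test_exhaustive_enumeration_oracle(self):
        """On 6 samples, passing every distinct phenotype relabeling as the
        permutation stream reproduces the exact enumeration p-value."""
        dosage = np.array(
            [[2, 0], [2, 1], [1, 0], [0, 2], [0, 1], [1, 2]], dtype=np.int8
        )
        y = np.array([1, 1, 1, 0, 0, 0])
        study = make_study(dosage, y)
        perms = np.array(sorted(set(itertools.permutations(y))))
        cfg = SetTestConfig(top_n_snps=2, snp_p_threshold=1.0, ld_r2_threshold=1.0,
                            n_perm=len(perms), seed=0)
        out = set_test(study, {"S": ["rs1", "rs2"]}, cfg, labels=perms)

        # independent oracle: mean trend chi2 over both SNPs per relabeling
        def mean_chi2(labels):
            return trend_chi2(genotype_counts(study.dosage, labels)).mean()

        obs = mean_chi2(y)
        exceed = sum(mean_chi2(np.array(p)) >= obs for p in perms)
        assert out.loc[0, "emp_p"] == pytest.approx((1 + exceed) / (1 + len(perms)))

    def test_equals_plain_mean_chi2_test_when_unrestricted(self, null_study):
        """top_n = inf and threshold 1 reduce the statistic to the plain
        mean chi-square permutation test (independent oracle)."""
        ids = list(null_study.snp_ids[:8])
        labels = permutation_labels(null_study.phenotype, 150, 3)
        cfg = SetTestConfig(top_n_snps=10**6, snp_p_threshold=1.0,
                            ld_r2_threshold=1.0, n_perm=150, seed=3)
        out = set_test(null_study, {"S": ids}, cfg, labels=labels)
        cols = null_study.snp_index(ids)
        obs = trend_chi2(genotype_counts(null_study.dosage, null_study.phenotype))[cols].mean()
        perm_stats = perm_chi2_matrix(null_study, labels)[:, cols].mean(axis=1)
        expected = (1 + (perm_stats >= obs).sum()) / (1 + 150)
        assert out.loc[0, "statistic"] == pytest.approx(obs)
        assert out.loc[0, "emp_p"] == pytest.approx(expected)


class TestGenGen:
    def test_gene_statistic_is_max_chi2(self, null_study):
        from pathmeld.pathway_gwas import gene_max_chi2

        chi2 = np.array([1.2, 7.1, 0.5])
        assert gene_max_chi2(chi2, {"G": np.array([0, 1])})["G"] == pytest.approx(7.1)

    def test_all_gene_set_scores_zero(self, null_study):
        gene_snp_map = {f"G{i}": [null_study.snp_ids[i]] for i in range(10)}
        sets = GeneSetCollection({"ALL": frozenset(gene_snp_map)})
        out = gengen_enrich(null_study, gene_snp_map, sets, n_perm=20, seed=0)
        assert out.loc[0, "statistic"] == pytest.approx(0.0)

    def test_planted_pathway_small_p(self, rng):
        n, m = 300, 40
        dosage = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        score = dosage[:, :8].sum(axis=1)
        y = (rng.random(n) < 1 / (1 + np.exp(-(score - score.mean()) * 0.8))).astype(int)
        study = make_study(dosage, y)
        gene_snp_map = {f"G{i}": [study.snp_ids[2 * i], study.snp_ids[2 * i + 1]]
                        for i in range(m // 2)}
        sets = GeneSetCollection(
            {"CAUSAL": frozenset(f"G{i}" for i in range(4)),
             "NULL": frozenset(f"G{i}" for i in range(10, 14))}
        )
        out = gengen_enrich(study, gene_snp_map, sets, n_perm=99, seed=0).set_index("set_id")
        assert out.loc["CAUSAL", "emp_p"] < out.loc["NULL", "emp_p"]
        assert out.loc["CAUSAL", "emp_p"] <= 0.05


class TestMakeIntervals:
    def _study_with_corr(self, r2_high=True):
        rng = np.random.default_rng(4)
        n = 2000
        base = rng.binomial(2, 0.4, n)
        if r2_high:
            other = base.copy()
            flip = rng.random(n) < 0.05
            other[flip] = rng.binomial(2, 0.4, flip.sum())
        else:
            other = rng.binomial(2, 0.4, n)
        third = rng.binomial(2, 0.4, n)
        dosage = np.column_stack([base, other, third]).astype(np.int8)
        return make_study(dosage, [0, 1] * (n // 2))

    def test_single_index_no_neighbors(self):
        study = self._study_with_corr(r2_high=False)
        assoc = pd.DataFrame(
            {"id": ["rs1", "rs2", "rs3"], "p": [0.001, 0.5, 0.9]}
        )
        ivs = make_intervals(assoc, study, p1=0.01, p2=0.05, r2=0.5)
        assert len(ivs) == 1
        assert ivs[0].n_snps == 1
        assert ivs[0].start == ivs[0].end

    def test_index_absorbs_correlated_neighbors(self):
        study = self._study_with_corr(r2_high=True)
        assoc = pd.DataFrame(
            {"id": ["rs1", "rs2", "rs3"], "p": [0.001, 0.02, 0.9]}
        )
        ivs = make_intervals(assoc, study, p1=0.01, p2=0.05, r2=0.5)
        assert len(ivs) == 1
        assert set(ivs[0].snp_ids) == {"rs1", "rs2"}
        assert (ivs[0].start, ivs[0].end) == (1000, 2000)

    def test_two_index_snps_in_ld_merge(self):
        study = self._study_with_corr(r2_high=True)
        assoc = pd.DataFrame(
            {"id": ["rs1", "rs2", "rs3"], "p": [0.001, 0.005, 0.9]}
        )
        ivs = make_intervals(assoc, study, p1=0.01, p2=0.05, r2=0.5)
        assert len(ivs) == 1
        assert set(ivs[0].snp_ids) == {"rs1", "rs2"}

    def test_snp_membership_disjoint(self, rng):
        n, m = 400, 30
        dosage = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        study = make_study(dosage, [0, 1] * (n // 2))
        assoc = snp_association(study).table
        ivs = make_intervals(assoc, study, p1=0.3, p2=0.6, r2=0.05)
        all_snps = [s for iv in ivs for s in iv.snp_ids]
        assert len(all_snps) == len(set(all_snps))


class TestInrich:
    def _toy(self):
        """3-slot genome: one gene per SNP position, window 0."""
        snp_table = pd.DataFrame(
            {"id": ["rs1", "rs2", "rs3"], "chrom": "1", "pos": [1000, 2000, 3000]}
        )
        genes = pd.DataFrame(
            {"symbol": ["g1", "g2", "g3"], "chrom": "1",
             "start": [1000, 2000, 3000], "end": [1000, 2000, 3000]}
        )
        sets = GeneSetCollection({"S1": frozenset({"g1"}), "S13": frozenset({"g1", "g3"})})
        return snp_table, genes, sets

    def test_exhaustive_matches_enumeration_oracle(self):
        snp_table, genes, sets = self._toy()
        intervals = [
            Interval("1", 1000, 1000, ["rs1"]),
            Interval("1", 2000, 2000, ["rs2"]),
        ]
        out = inrich_test(
            intervals, genes, sets, snp_table, window_kb=0, exhaustive=True
        ).set_index("set_id")
        # enumeration: each interval relocates to any of the 3 slots
        for name, members in [("S1", {1}), ("S13", {1, 3})]:
            obs = sum(iv.start // 1000 in members for iv in intervals)
            exceed = sum(
                (int(a in members) + int(b in members)) >= obs
                for a, b in itertools.product([1, 2, 3], repeat=2)
            )
            assert out.loc[name, "emp_p"] == pytest.approx((1 + exceed) / (1 + 9)), name

    def test_unreachable_set_p_one(self):
        snp_table, genes, _ = self._toy()
        sets = GeneSetCollection({"FAR": frozenset({"nowhere"})})
        intervals = [Interval("1", 1000, 1000, ["rs1"])]
        out = inrich_test(intervals, genes, sets, snp_table, n_perm=50,
                          seed=0, window_kb=0)
        assert out.loc[0, "statistic"] == 0
        assert out.loc[0, "emp_p"] == 1.0

    def test_unique_region_extreme_p(self):
        """All intervals overlap set genes that the null can only hit by
        landing on the same slots."""
        snp_table = pd.DataFrame(
            {"id": [f"rs{i}" for i in range(10)], "chrom": "1",
             "pos": 1000 * np.arange(1, 11)}
        )
        genes = pd.DataFrame(
            {"symbol": [f"g{i}" for i in range(10)], "chrom": "1",
             "start": 1000 * np.arange(1, 11), "end": 1000 * np.arange(1, 11)}
        )
        sets = GeneSetCollection({"HIT": frozenset({"g0"})})
        intervals = [Interval("1", 1000, 1000, ["rs0"])]
        out = inrich_test(intervals, genes, sets, snp_table, n_perm=200,
                          seed=1, window_kb=0)
        # null hits g0 with prob 1/10 per draw
        assert out.loc[0, "statistic"] == 1
        assert out.loc[0, "emp_p"] < 0.3


class TestGenePToRanklist:
    def test_filter_and_order(self):
        ranked = gene_p_to_ranklist({"A": 1.0, "B": 0.05, "C": 0.01})
        assert list(ranked.genes) == ["C", "B"]

    def test_log005_scores(self):
        ranked = gene_p_to_ranklist({"B": 0.05, "C": 0.0025})
        assert dict(zip(ranked.genes, ranked.scores))["B"] == pytest.approx(1.0)
        assert dict(zip(ranked.genes, ranked.scores))["C"] == pytest.approx(2.0)

    def test_empty_after_filter_errors(self):
        with pytest.raises(ValueError):
            gene_p_to_ranklist({"A": 1.0})


class TestNullCalibration:
    def test_set_test_p_uniform_under_null(self):
        """Shared-permutation empirical p's across many independent sets are
        uniform when phenotype is independent of genotype."""
        rng = np.random.default_rng(21)
        n, m = 120, 600
        dosage = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(np.int8)
        study = make_study(dosage, [0, 1] * (n // 2))
        set_map = {f"S{k}": [f"rs{j + 1}" for j in range(10 * k, 10 * k + 10)]
                   for k in range(m // 10)}
        cfg = SetTestConfig(top_n_snps=10**6, snp_p_threshold=1.0,
                            ld_r2_threshold=1.0, n_perm=199, seed=5)
        out = set_test(study, set_map, cfg)
        assert stats.kstest(out["emp_p"], "uniform").pvalue > 0.01
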