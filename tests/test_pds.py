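import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathmeld.core_io import GeneSetCollection
from pathmeld.pds import (
    ExpressionStudy,
    PDSConfig,
    compute_pds,
    fit_principal_curve,
    paired_pds_test,
    size_factor_normalize,
)


def _expr_study(counts, conditions, pair_ids=None):
    meta = pd.DataFrame(
        {
            "sample_id": list(counts.columns),
            "condition": conditions,
            "pair_id": pair_ids if pair_ids is not None else [None] * len(conditions),
        }
    )
    return ExpressionStudy(counts=counts, meta=meta)


class TestSizeFactorNormalize:
    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame(
            {"s1": [10.0, 20.0, 30.0], "s2": [20.0, 40.0, 60.0]},
            index=["g1", "g2", "g3"],
        )
        expr = _expr_study(counts, ["normal", "tumor"])
        _, sf = size_factor_normalize(expr, log2=False)
        # geometric means: sqrt(200), sqrt(800), sqrt(1800)
        # ratios s1: 10/14.14, 20/28.28, 30/42.43 -> all 1/sqrt(2)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)
        assert sf["s2"] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_library_scaling_removed(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 100, size=12).astype(float)
        counts = pd.DataFrame({"a": base, "b": 2 * base}, index=[f"g{i}" for i in range(12)])
        expr = _expr_study(counts, ["normal", "tumor"])
        norm, sf = size_factor_normalize(expr, log2=False)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-9)
        assert np.allclose(norm["a"], norm["b"])

    def test_balanced_matrix_identity(self):
        counts = pd.DataFrame(
            {"a": [10.0, 20.0], "b": [20.0, 10.0]}, index=["g1", "g2"]
        )
        expr = _expr_study(counts, ["normal", "tumor"])
        norm, sf = size_factor_normalize(expr, log2=False)
        assert np.allclose(sf, 1.0)
        assert np.allclose(norm, counts)

    def test_no_universally_expressed_gene_errors(self):
        counts = pd.DataFrame({"a": [0.0, 5.0], "b": [5.0, 0.0]}, index=["g1", "g2"])
        expr = _expr_study(counts, ["normal", "tumor"])
        with pytest.raises(ValueError, match="pseudocount"):
            size_factor_normalize(expr)


class TestPrincipalCurve:
    def test_points_on_line_recovered(self, rng):
        t = np.sort(rng.uniform(-2, 2, 40))
        direction = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        points = np.outer(t, direction)
        curve = fit_principal_curve(points)
        lam = curve.lambdas
        # arc-length order equals PC1 order and spacing is affine in t
        assert stats.pearsonr(lam, t).statistic > 0.999999
        resid = points - np.outer((lam - lam.mean()), direction) * np.sign(
            np.dot(direction, np.polyfit(lam, points, 1)[0])
        )
        _, dists = curve.project(points)
        assert np.abs(dists).max() < 1e-8

    def test_quarter_circle_approximated(self, rng):
        theta = np.sort(rng.uniform(0, np.pi / 2, 150))
        points = np.column_stack([np.cos(theta), np.sin(theta)])
        curve = fit_principal_curve(points, span=0.15)
        _, dists = curve.project(points)
        assert np.sqrt((dists**2).mean()) < 0.05

    def test_duplicate_points_no_crash(self, rng):
        pts = np.repeat(rng.normal(size=(5, 2)), 3, axis=0)
        curve = fit_principal_curve(pts)
        lam, d = curve.project(pts)
        assert np.isfinite(lam).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_principal_curve(np.zeros((3, 2)))


def _pathway_expr(shift=3.0, n_pairs=10, n_genes=6, seed=0):
    """Normals at a baseline, tumors displaced along one direction in the
    pathway's genes."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    cols, conds, pairs = {}, [], []
    direction = rng.choice([-1.0, 1.0], n_genes)
    for i in range(n_pairs):
        base = rng.normal(8.0, 0.5, n_genes)
        cols[f"p{i}_N"] = base + rng.normal(0, 0.3, n_genes)
        sev = rng.uniform(0.5, 1.5)
        cols[f"p{i}_T"] = base + direction * shift * 0.3 * sev + rng.normal(0, 0.3, n_genes)
        conds += ["normal", "tumor"]
        pairs += [f"p{i}", f"p{i}"]
    mat = pd.DataFrame(cols, index=genes)
    return mat, conds, pairs, genes


class TestComputePds:
    def test_line_data_equals_rescaled_pc1(self, rng):
        """Samples exactly on a line: PDS is the |PC1 - normal median|
        rescaled by the range (oracle comparison)."""
        t = rng.uniform(0, 4, 30)
        t[:10] = rng.uniform(0, 0.5, 10)  # normals at the low end
        genes = [f"g{i}" for i in range(4)]
        direction = np.array([1.0, -0.5, 2.0, 0.3])
        mat = pd.DataFrame(
            8.0 + np.outer(direction, t), index=genes,
            columns=[f"s{i}" for i in range(30)],
        )
        normal_ids = [f"s{i}" for i in range(10)]
        sets = GeneSetCollection({"PW": frozenset(genes)})
        pds = compute_pds(mat, sets, normal_ids, PDSConfig(min_genes=3))
        scores = pds.scores.loc["PW"].to_numpy()
        # oracle: z-scored line still parameterized by t; curve = line
        anchor = np.median(t[:10])
        expected = np.abs(t - anchor)
        expected = expected / (t.max() - t.min())
        assert np.allclose(scores, expected, atol=1e-6)

    def test_planted_shift_tumor_exceeds_normal(self):
        mat, conds, pairs, genes = _pathway_expr(shift=4.0)
        sets = GeneSetCollection({"PW": frozenset(genes)})
        normal_ids = [c for c, cond in zip(mat.columns, conds) if cond == "normal"]
        pds = compute_pds(mat, sets, normal_ids, PDSConfig(min_genes=3))
        row = pds.scores.loc["PW"]
        tum = row[[c for c in mat.columns if c.endswith("_T")]].to_numpy()
        nor = row[[c for c in mat.columns if c.endswith("_N")]].to_numpy()
        assert (tum > nor).all()

    def test_zero_variance_pathway_nan_row(self, rng):
        genes = ["a", "b", "c", "x", "y", "z"]
        mat = pd.DataFrame(
            np.vstack([np.ones((3, 8)), rng.normal(5, 1, size=(3, 8))]),
            index=genes, columns=[f"s{i}" for i in range(8)],
        )
        sets = GeneSetCollection(
            {"FLAT": frozenset(["a", "b", "c"]), "OK": frozenset(["x", "y", "z"])}
        )
        pds = compute_pds(mat, sets, [f"s{i}" for i in range(4)], PDSConfig(min_genes=3))
        assert pds.scores.loc["FLAT"].isna().all()
        assert pds.scores.loc["OK"].notna().all()

    def test_scores_in_unit_interval_and_normals_near_anchor(self, rng):
        mat, conds, pairs, genes = _pathway_expr(shift=0.0, n_pairs=12)
        sets = GeneSetCollection({"PW": frozenset(genes)})
        pds = compute_pds(mat, sets, list(mat.columns), PDSConfig(min_genes=3))
        row = pds.scores.loc["PW"].to_numpy()
        assert ((row >= 0) & (row <= 1)).all()
        assert np.mean(row) < 0.35  # scores cluster at the normal anchor

    def test_deterministic_and_order_invariant(self, rng):
        mat, conds, pairs, genes = _pathway_expr(shift=2.0)
        sets = GeneSetCollection({"PW": frozenset(genes)})
        normal_ids = [c for c in mat.columns if c.endswith("_N")]
        a = compute_pds(mat, sets, normal_ids).scores
        perm = list(rng.permutation(mat.columns))
        b = compute_pds(mat[perm], sets, normal_ids).scores
        assert np.allclose(a.loc["PW", perm].to_numpy(), b.loc["PW"].to_numpy(), atol=1e-9)


class TestPairedPdsTest:
    def _pds_frame(self, values, n_pairs):
        pathways = [f"PW{k}" for k in range(values.shape[0])]
        cols = []
        for i in range(n_pairs):
            cols += [f"p{i}_T", f"p{i}_N"]
        return pd.DataFrame(values, index=pathways, columns=cols), {
            f"p{i}_T": f"p{i}_N" for i in range(n_pairs)
        }

    def test_enumeration_oracle_two_pathways_three_pairs(self):
        rng = np.random.default_rng(8)
        scores, pairs = self._pds_frame(rng.random((2, 6)), 3)
        out = paired_pds_test(scores, pairs, exhaustive=True).set_index("set_id")

        # independent enumeration over per-patient pathway swaps (2^3 x ...)
        D = np.column_stack(
            [
                scores[f"p{i}_T"].to_numpy() - scores[f"p{i}_N"].to_numpy()
                for i in range(3)
            ]
        )

        def paired_t(d):
            return d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))

        t_obs = np.array([paired_t(D[0]), paired_t(D[1])])
        null = []
        for combo in itertools.product([(0, 1), (1, 0)], repeat=3):
            Dp = np.column_stack([D[list(combo[j]), j] for j in range(3)])
            null.append([paired_t(Dp[0]), paired_t(Dp[1])])
        null = np.abs(np.array(null))
        for k, name in enumerate(["PW0", "PW1"]):
            exceed = (null[:, k] >= abs(t_obs[k])).sum()
            expected = (1 + exceed) / (1 + len(null))
            assert out.loc[name, "emp_p"] == pytest.approx(expected), name

    def test_iid_scores_p_uniform(self):
        """Exchangeable pathways: empirical p's are uniform."""
        rng = np.random.default_rng(9)
        ps = []
        for rep in range(10):
            scores, pairs = self._pds_frame(
                np.random.default_rng(100 + rep).random((20, 16)), 8
            )
            out = paired_pds_test(scores, pairs, n_perm=199, seed=rep)
            ps.extend(out["emp_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tumor_equals_normal_p_one(self):
        vals = np.tile(np.random.default_rng(0).random((3, 4)), 2)
        # build so that tumor == normal per pair
        pathways = ["A", "B", "C"]
        cols, pairs = [], {}
        data = {}
        base = np.random.default_rng(1).random((3, 4))
        for i in range(4):
            data[f"p{i}_T"] = base[:, i]
            data[f"p{i}_N"] = base[:, i]
            pairs[f"p{i}_T"] = f"p{i}_N"
        scores = pd.DataFrame(data, index=pathways)
        out = paired_pds_test(scores, pairs, n_perm=50, seed=0)
        assert (out["emp_p"] == 1.0).all()

    def test_planted_deregulation_smallest_q(self):
        """One of 20 pathways with a consistent tumor-normal shift attains
        the smallest q in most replicates."""
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            vals = rng.normal(0.3, 0.1, size=(20, 46)).clip(0, 1)
            data, pairs = {}, {}
            for i in range(23):
                data[f"p{i}_T"] = vals[:, 2 * i]
                data[f"p{i}_N"] = vals[:, 2 * i + 1]
                pairs[f"p{i}_T"] = f"p{i}_N"
            scores = pd.DataFrame(data, index=[f"PW{k}" for k in range(20)])
            scores.loc["PW0", [f"p{i}_T" for i in range(23)]] += 0.2  # 2 SD shift
            out = paired_pds_test(scores, pairs, n_perm=199, seed=rep).set_index("set_id")
            if out["q"].idxmin() == "PW0":
                hits += 1
        assert hits >= 9

    def test_fewer_than_three_pairs_rejected(self):
        scores, pairs = self._pds_frame(np.random.default_rng(0).random((2, 4)), 2)
        with pytest.raises(ValueError, match="3 complete"):
            paired_pds_test(scores, pairs)
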