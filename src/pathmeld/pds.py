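"""Pathway deregulation scores from paired tumor/normal expression.

The score of a sample for a pathway is its normalized arc-length distance
from the normal-sample anchor along a principal curve fitted to the
pathway-restricted (z-scored, PCA-reduced) expression cloud — a one-number
summary of how far the sample has drifted from the normal state along the
dominant trajectory of variation.  The published Pathifier procedure adds
spanning-tree denoising and stability filtering over sample subsets; here
the curve is fitted directly with the Hastie-Stuetzle iteration after a
variability filter and PCA, which preserves the score's meaning on data
whose deregulation is a drift along a latent direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combine import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class ExpressionStudy:
    """Genes x samples nonnegative counts with tumor/normal pairing.

    ``meta`` columns: sample_id, condition in {tumor, normal}, pair_id
    (nullable).  When present, each pair_id maps exactly one tumor to one
    normal sample.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if list(self.counts.columns) != list(self.meta["sample_id"]):
            raise ValueError("metadata sample order must match count columns")
        bad = ~self.meta["condition"].isin(["tumor", "normal"])
        if bad.any():
            raise ValueError("condition must be 'tumor' or 'normal'")
        paired = self.meta.dropna(subset=["pair_id"]) if "pair_id" in self.meta else None
        if paired is not None and len(paired):
            g = paired.groupby("pair_id")["condition"]
            if not ((g.size() == 2).all() and (g.nunique() == 2).all()):
                raise ValueError("each pair_id must map one tumor to one normal")

    @property
    def normal_ids(self) -> list[str]:
        return list(self.meta.loc[self.meta["condition"] == "normal", "sample_id"])

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.meta.loc[self.meta["condition"] == "tumor", "sample_id"])

    def pairs(self) -> dict[str, str]:
        """Map tumor sample id -> its paired normal sample id."""
        out = {}
        if "pair_id" not in self.meta:
            return out
        for _, grp in self.meta.dropna(subset=["pair_id"]).groupby("pair_id"):
            t = grp.loc[grp["condition"] == "tumor", "sample_id"].iloc[0]
            n = grp.loc[grp["condition"] == "normal", "sample_id"].iloc[0]
            out[t] = n
        return out


def size_factor_normalize(expr: ExpressionStudy, log2: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios (DESeq-style) normalization.

    The size factor of a sample is the median, over genes expressed in all
    samples, of the ratio of its count to the gene's geometric mean across
    samples.  Returns (normalized matrix, size factors); by default the
    matrix is log2(x + 1) transformed for downstream geometry.
    """
    counts = expr.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene expressed in all samples; add a pseudocount before normalizing"
        )
    log_geo = np.log(counts[all_pos]).mean(axis=1)
    ratios = np.log(counts[all_pos]) - log_geo[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    norm = counts / size_factors[None, :]
    if log2:
        norm = np.log2(norm + 1.0)
    return (
        pd.DataFrame(norm, index=expr.counts.index, columns=expr.counts.columns),
        pd.Series(size_factors, index=expr.counts.columns, name="size_factor"),
    )


# ---------------------------------------------------------------------------
# Principal curve (Hastie-Stuetzle)


@dataclass
class PrincipalCurve:
    """Fitted principal curve: ordered nodes with arc-length parameters."""

    nodes: np.ndarray          # (n_nodes, dims), ordered along the curve
    arclength: np.ndarray      # (n_nodes,), 0 at the first node
    lambdas: np.ndarray        # per-input-point arc-length of the projection
    converged: bool = True

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project points onto the polyline; return (arc-lengths, distances)."""
        return _project_polyline(np.atleast_2d(points), self.nodes, self.arclength)


def _project_polyline(points, nodes, arclength):
    if len(nodes) == 1:
        d = np.linalg.norm(points - nodes[0], axis=1)
        return np.zeros(len(points)), d
    seg_vec = nodes[1:] - nodes[:-1]                      # (S, d)
    seg_len2 = (seg_vec**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    diff = points[:, None, :] - nodes[None, :-1, :]       # (n, S, d)
    t = np.clip((diff * seg_vec[None]).sum(axis=2) / seg_len2[None], 0.0, 1.0)
    proj = nodes[None, :-1, :] + t[:, :, None] * seg_vec[None]
    dist2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = dist2.argmin(axis=1)
    rows = np.arange(len(points))
    lam = arclength[best] + t[rows, best] * np.sqrt(seg_len2[best])
    return lam, np.sqrt(dist2[rows, best])


def _local_linear(t: np.ndarray, y: np.ndarray, half_width: int) -> np.ndarray:
    """Moving-window local linear smoother of y against t.

    Fits an ordinary least-squares line over each centered index window
    (shrunk at the edges) and predicts at the window's own t.  Exactly
    reproduces linear input, including at the boundaries.
    """
    n = len(y)
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width + 1, n)

    def csum(v):
        c = np.concatenate([[0.0], np.cumsum(v)])
        return c[hi] - c[lo]

    m = hi - lo
    st, sy = csum(t), csum(y)
    stt, sty = csum(t * t), csum(t * y)
    denom = m * stt - st * st
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom > 1e-300, (m * sty - st * sy) / np.where(denom > 0, denom, 1.0), 0.0)
    intercept = (sy - slope * st) / m
    return intercept + slope * t


def fit_principal_curve(
    points: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-4,
    span: float = 0.3,
) -> PrincipalCurve:
    """Hastie-Stuetzle principal curve through a point cloud.

    Initialized on the first principal component; alternates projecting
    points onto the current polyline and smoothing each coordinate against
    the arc-length parameter (local linear scatterplot smoother over a
    ``span`` fraction of the points) until the mean squared projection
    distance stabilizes.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 4:
        raise ValueError("need a (n >= 4) x dims point matrix")
    n, dims = points.shape
    center = points.mean(axis=0)
    x = points - center
    # PC1 initialization
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    lam = x @ vt[0]
    order = np.argsort(lam, kind="stable")
    nodes = np.outer(lam[order], vt[0]) + center
    arclength = _polyline_arclength(nodes)

    prev_mse = np.inf
    converged = False
    for _ in range(max_iter):
        lam_proj, dist = _project_polyline(points, nodes, arclength)
        mse = float((dist**2).mean())
        if abs(prev_mse - mse) < tol * max(prev_mse, 1.0):
            converged = True
            break
        prev_mse = mse
        order = np.argsort(lam_proj, kind="stable")
        t_sorted = lam_proj[order]
        # collapse duplicate parameters (duplicate points)
        t_unique, inv = np.unique(np.round(t_sorted, 12), return_inverse=True)
        if len(t_unique) < 4:
            break
        half_width = max(2, int(round(span * len(t_unique) / 2)))
        new_nodes = np.empty((len(t_unique), dims))
        for d in range(dims):
            y = np.bincount(inv, weights=points[order, d]) / np.bincount(inv)
            new_nodes[:, d] = _local_linear(t_unique, y, half_width)
        nodes = new_nodes
        arclength = _polyline_arclength(nodes)
    else:
        logger.warning("principal curve did not converge in %d iterations", max_iter)

    lam_final, _ = _project_polyline(points, nodes, arclength)
    return PrincipalCurve(nodes=nodes, arclength=arclength, lambdas=lam_final,
                          converged=converged)


def _polyline_arclength(nodes: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


# ---------------------------------------------------------------------------
# PDS


@dataclass
class PDSConfig:
    var_explained: float = 0.85
    max_pcs: int = 5
    min_genes: int = 3
    min_gene_sd: float = 1e-8


@dataclass
class PDSMatrix:
    """Pathways x samples deregulation scores in [0, 1]."""

    scores: pd.DataFrame
    curve_meta: dict[str, dict] = field(default_factory=dict)
    meta: pd.DataFrame | None = None

    @property
    def pathways(self) -> list[str]:
        return list(self.scores.index)


def compute_pds(
    expr_norm: pd.DataFrame,
    sets,
    normal_ids,
    cfg: PDSConfig | None = None,
) -> PDSMatrix:
    """Pathway deregulation score per pathway and sample.

    Per pathway: restrict to member genes passing a variability filter,
    z-score each gene on the normal samples' mean/sd, reduce by PCA to the
    smallest number of components explaining ``var_explained`` of variance
    (capped at ``max_pcs``), fit a principal curve through all samples, and
    score each sample by its arc-length distance from the normal-median
    anchor point, divided by total curve length.  Pathways with fewer than
    ``min_genes`` usable genes yield a row of NaN.
    """
    cfg = cfg or PDSConfig()
    normal_ids = list(normal_ids)
    if not normal_ids:
        raise ValueError("need at least one normal sample")
    samples = list(expr_norm.columns)
    normal_mask = np.isin(samples, normal_ids)
    scores = {}
    curve_meta = {}
    for name in sorted(sets.sets):
        genes = sorted(set(sets[name]) & set(expr_norm.index))
        sub = expr_norm.loc[genes].to_numpy(dtype=float)
        if len(genes):
            mu = sub[:, normal_mask].mean(axis=1)
            sd = sub[:, normal_mask].std(axis=1)
            usable = (sd > cfg.min_gene_sd) & (sub.std(axis=1) > cfg.min_gene_sd)
        else:
            usable = np.zeros(0, dtype=bool)
        if usable.sum() < cfg.min_genes:
            logger.warning("pathway %r: %d usable genes (< %d); NaN row",
                           name, int(usable.sum()), cfg.min_genes)
            scores[name] = np.full(len(samples), np.nan)
            curve_meta[name] = {"genes": [], "n_pcs": 0, "curve_length": np.nan}
            continue
        z = ((sub[usable] - mu[usable, None]) / sd[usable, None]).T  # samples x genes
        # PCA on the z-scored cloud
        zc = z - z.mean(axis=0)
        u, s, vt = np.linalg.svd(zc, full_matrices=False)
        var = s**2
        frac = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        k = int(np.searchsorted(frac, cfg.var_explained) + 1)
        k = min(max(k, 1), cfg.max_pcs, zc.shape[1])
        coords = u[:, :k] * s[:k]
        curve = fit_principal_curve(coords)
        lam = curve.lambdas
        anchor = float(np.median(lam[normal_mask]))
        length = max(curve.length, 1e-12)
        pds = np.abs(lam - anchor) / length
        scores[name] = np.clip(pds, 0.0, 1.0)
        curve_meta[name] = {
            "genes": [g for g, u_ in zip(genes, usable) if u_],
            "n_pcs": k,
            "curve_length": length,
        }
    out = pd.DataFrame(scores, index=samples).T
    if not np.isfinite(out.to_numpy()).any():
        raise ValueError("no pathway produced finite scores")
    return PDSMatrix(scores=out, curve_meta=curve_meta)


# ---------------------------------------------------------------------------
# Paired permutation test


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Row-wise paired t statistic of a (pathways x patients) difference
    matrix; rows with zero-variance differences yield NaN."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return t


def paired_pds_test(
    pds: PDSMatrix,
    pairs: dict[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
    flip_pairs: bool = False,
) -> pd.DataFrame:
    """Paired t test of tumor-vs-normal PDS with a pathway-permutation null.

    The observed statistic per pathway is the paired t over patients of
    (tumor PDS - normal PDS).  Under the null that a pathway's PDS is
    exchangeable with other pathways', each patient's (tumor, normal) PDS
    pairs are jointly reassigned to random pathways — the tumor/normal
    coupling never breaks.  ``flip_pairs=True`` instead swaps tumor/normal
    labels within pairs (the alternative null).  ``exhaustive=True``
    enumerates all per-patient pathway permutations (tiny instances only).
    Returns set_id, t, emp_p, q (BH over pathways).

    ``pds`` may be a :class:`PDSMatrix` or a bare pathways x samples frame.
    """
    scores = pds if isinstance(pds, pd.DataFrame) else pds.scores
    finite = scores.dropna(how="all")
    pathways = list(finite.index)
    tumors = [t for t in pairs if t in finite.columns and pairs[t] in finite.columns]
    if len(tumors) < 3:
        raise ValueError("need at least 3 complete tumor/normal pairs")
    normals = [pairs[t] for t in tumors]
    D = finite[tumors].to_numpy() - finite[normals].to_numpy()  # pathways x patients
    t_obs = _paired_t(D)

    P, n_pat = D.shape
    rng = np.random.default_rng(seed)

    def perm_ts(perm_cols) -> np.ndarray:
        Dp = np.column_stack([D[perm_cols[j], j] for j in range(n_pat)])
        return _paired_t(Dp)

    if flip_pairs:
        if exhaustive:
            signs_iter = itertools.product((1, -1), repeat=n_pat)
            null_t = np.array([_paired_t(D * np.array(s)[None, :]) for s in signs_iter])
        else:
            signs = rng.choice((1.0, -1.0), size=(n_perm, n_pat))
            null_t = np.array([_paired_t(D * s[None, :]) for s in signs])
    elif exhaustive:
        perms_per_patient = list(itertools.permutations(range(P)))
        null_t = np.array(
            [perm_ts([np.array(c) for c in combo])
             for combo in itertools.product(perms_per_patient, repeat=n_pat)]
        )
    else:
        null_t = np.empty((n_perm, P))
        for b in range(n_perm):
            cols = [rng.permutation(P) for _ in range(n_pat)]
            null_t[b] = perm_ts(cols)

    n_null = null_t.shape[0]
    abs_null = np.abs(null_t)
    emp_p = np.ones(P)
    for k in range(P):
        if not np.isfinite(t_obs[k]):
            emp_p[k] = 1.0
            continue
        comparable = abs_null[:, k]
        exceed = np.nansum(comparable >= abs(t_obs[k]))
        emp_p[k] = (1 + exceed) / (1 + n_null)
    return pd.DataFrame(
        {
            "set_id": pathways,
            "t": t_obs,
            "emp_p": emp_p,
            "q": bh_fdr(emp_p),
        }
    )
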