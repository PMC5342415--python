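"""Pathway-level relapse-free survival analysis.

Patients are split at the median pathway deregulation score (strictly
above the median = higher-risk), survival in the two groups is summarized
by Kaplan-Meier curves, and the difference is tested with a weighted
log-rank statistic.  "Wilcoxon" means the Gehan-Breslow-Wilcoxon weighting
(weight = number at risk), the common reading in survival packages; the
unweighted log-rank is available via ``weighting="logrank"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .combine import bh_fdr

logger = logging.getLogger(__name__)


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Clinical table with columns sample_id, time, event (1 = relapse).

    Rows with missing time or event are dropped with a logged count.
    """
    required = {"sample_id", "time", "event"}
    if not required <= set(table.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    n0 = len(table)
    table = table.dropna(subset=["time", "event"]).copy()
    if len(table) < n0:
        logger.warning("dropped %d samples with missing survival fields", n0 - len(table))
    if (table["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return table


def dichotomize_by_median(pds_row: pd.Series) -> pd.Series:
    """Labels 'high' for scores strictly above the median, else 'low'."""
    finite = pds_row.dropna()
    if len(finite) < 4:
        raise ValueError("need at least 4 finite scores to dichotomize")
    med = float(finite.median())
    if (finite == finite.iloc[0]).all():
        raise ValueError("degenerate dichotomization: all scores equal")
    return pd.Series(np.where(finite > med, "high", "low"), index=finite.index)


def km_curve(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per risk group.

    Returns, per group, a frame with columns time, survival, at_risk and
    the censored times (one row per distinct time, censoring tick-marked
    via the ``censored`` column).
    """
    table = validate_survival_table(table)
    if "group" not in table.columns:
        raise ValueError("table must carry a 'group' column")
    out = {}
    for grp, sub in table.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        surv = kmf.survival_function_.iloc[:, 0]
        censor_times = set(sub.loc[sub["event"] == 0, "time"])
        out[str(grp)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(),
                "survival": surv.to_numpy(),
                "censored": [t in censor_times for t in surv.index],
            }
        )
    return out


def weighted_logrank(table: pd.DataFrame, weighting: str = "wilcoxon") -> tuple[float, float]:
    """Two-group weighted log-rank test.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; contributions
    are weighted by 1 (``logrank``) or by the total number at risk
    (``wilcoxon``, i.e. Gehan-Breslow).  Returns (chi-square, p) with 1 df.
    """
    if weighting not in ("logrank", "wilcoxon"):
        raise ValueError("weighting must be 'logrank' or 'wilcoxon'")
    table = validate_survival_table(table)
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if table["event"].sum() == 0:
        raise ValueError("no events observed")
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    in1 = (table["group"] == groups[0]).to_numpy()

    event_times = np.unique(time[event == 1])
    num = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & in1).sum())
        if n <= 1:
            continue
        w = float(n) if weighting == "wilcoxon" else 1.0
        expected = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        num += w * (d1 - expected)
        var += w * w * v
    if var <= 0:
        return 0.0, 1.0
    chi2 = num * num / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def pathway_survival_screen(
    pds_scores: pd.DataFrame,
    surv: pd.DataFrame,
    weighting: str = "wilcoxon",
) -> pd.DataFrame:
    """Median-PDS dichotomization + weighted log-rank for every pathway.

    ``pds_scores`` is pathways x samples; ``surv`` carries sample_id, time,
    event.  Pathways with a degenerate dichotomization (all scores equal)
    or undefined test get p = 1 and a flag.  Returns set_id, chisq, p, q
    (BH across all pathways in the run).
    """
    surv = validate_survival_table(surv).set_index("sample_id")
    common = [s for s in pds_scores.columns if s in surv.index]
    if not common:
        raise ValueError("no overlapping samples between PDS and survival table")
    records = []
    for name, row in pds_scores.loc[:, common].iterrows():
        try:
            groups = dichotomize_by_median(row)
            tab = surv.loc[groups.index].rename_axis("sample_id").reset_index()
            tab["group"] = groups.to_numpy()
            chi2, p = weighted_logrank(tab, weighting=weighting)
            records.append((name, chi2, p, False))
        except ValueError as exc:
            logger.warning("pathway %r: %s; p = 1", name, exc)
            records.append((name, 0.0, 1.0, True))
    out = pd.DataFrame(records, columns=["set_id", "chisq", "p", "degenerate"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["set_id", "chisq", "p", "q", "degenerate"]]
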