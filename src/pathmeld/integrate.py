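"""Cross-data-type rank aggregation of pathway significance.

Each data type (GWAS combination, mutation enrichment, expression
deregulation, survival) contributes a ranking of pathways by significance.
A pathway that is consistently near the top across data types gets a small
average rank; its empirical p is computed against a null that resamples
one rank independently from each data type's rank column — deliberately
destroying cross-type dependence, so the test asks whether the observed
consistency could arise if the data types were unrelated.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def build_rankings(per_type_results: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Pathways x data-type matrix of ascending significance ranks.

    Within each data type, pathways are ranked ascending by p (1 = most
    significant), with average ranks on ties.  Pathways missing from a
    data type are imputed p = 1 before ranking (logged).
    """
    if not per_type_results:
        raise ValueError("no data types provided")
    for name, d in per_type_results.items():
        if not d:
            raise ValueError(f"data type {name!r} is empty")
    universe = sorted(set().union(*[set(d) for d in per_type_results.values()]))
    cols = {}
    for name, d in per_type_results.items():
        missing = len(universe) - len(set(d) & set(universe))
        if missing:
            logger.warning("data type %r: %d pathways imputed p = 1", name, missing)
        p = pd.Series([d.get(pw, 1.0) for pw in universe], index=universe)
        cols[name] = p.rank(method="average")
    return pd.DataFrame(cols)


def consistency_test(
    ranks: pd.DataFrame,
    focus_sets=None,
    n_resample: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Empirical p of each focus pathway's mean rank across data types.

    The null draws one rank uniformly with replacement from each data
    type's rank column and averages them; ``n_resample`` such draws form
    the null distribution (``exhaustive=True`` enumerates every
    combination instead — small universes only).  Empirical p uses the
    (1 + b)/(1 + n) estimator and is monotone in the observed mean rank.
    """
    if focus_sets is None:
        focus_sets = list(ranks.index)
    focus_sets = list(focus_sets)
    missing = [s for s in focus_sets if s not in ranks.index]
    if missing:
        raise KeyError(f"focus sets not in ranking table: {missing[:5]}")
    obs_mean = ranks.loc[focus_sets].mean(axis=1)

    cols = [ranks[c].to_numpy() for c in ranks.columns]
    if exhaustive:
        null_means = np.array([np.mean(c) for c in itertools.product(*cols)])
    else:
        rng = np.random.default_rng(seed)
        draws = np.column_stack([rng.choice(c, size=n_resample, replace=True) for c in cols])
        null_means = draws.mean(axis=1)
    null_sorted = np.sort(null_means)
    below = np.searchsorted(null_sorted, obs_mean.to_numpy(), side="right")
    if exhaustive:
        # the enumeration is the exact null distribution, no MC correction
        emp_p = below / len(null_sorted)
    else:
        emp_p = (1 + below) / (1 + len(null_sorted))

    out = pd.DataFrame(
        {"set_id": focus_sets, "mean_rank": obs_mean.to_numpy(), "emp_p": emp_p}
    )
    for c in ranks.columns:
        out[f"rank_{c}"] = ranks.loc[focus_sets, c].to_numpy()
    return out.reset_index(drop=True)
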