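"""Subgroup-feature association tests and shared multiple-testing utilities.

Categorical features are tested with Fisher's exact test — by default as
per-subgroup one-vs-rest 2x2 decompositions (the per-subgroup enrichment
style of reporting), with an omnibus exact r x c alternative computed by
complete enumeration of tables with fixed margins.  Continuous features use
Kruskal-Wallis with pairwise rank-sum post hocs.  All adjustment is
Benjamini-Hochberg, within one feature (never across features).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalTable

__all__ = [
    "AssociationResult",
    "bh_adjust",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "categorical_association",
    "kruskal_wallis",
    "pairwise_wilcoxon",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method:
    sum hypergeometric probabilities of all tables with the observed margins
    whose point probability is <= the observed one)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _rxc_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row, remaining_cols, acc):
        if row == r - 1:
            last = tuple(remaining_cols)
            if all(v >= 0 for v in last) and sum(last) == row_sums[row]:
                yield acc + [last]
            return
        target = row_sums[row]

        def fill(j, left, current):
            if j == c - 1:
                v = left
                if 0 <= v <= remaining_cols[j]:
                    yield current + (v,)
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                yield from fill(j + 1, left - v, current + (v,))

        for filled in fill(0, target, ()):
            rem = [remaining_cols[j] - filled[j] for j in range(c)]
            yield from rec(row + 1, rem, acc + [filled])

    yield from rec(0, list(col_sums), [])


def _log_table_prob(table, log_fact) -> float:
    flat = [v for row in table for v in row]
    rows = [sum(row) for row in table]
    cols = [sum(col) for col in zip(*table)]
    n = sum(flat)
    return (
        sum(log_fact[v] for v in rows)
        + sum(log_fact[v] for v in cols)
        - log_fact[n]
        - sum(log_fact[v] for v in flat)
    )


def fisher_exact_rxc(table, rel_tol: float = 1e-7) -> float:
    """Exact r x c Fisher p by complete enumeration of tables with the
    observed margins (feasible for small tables, e.g. 3x2 / 3x3 at n<=100)."""
    t = np.asarray(table, dtype=np.int64)
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    n = int(t.sum())
    if n == 0:
        raise ValueError("table total must be positive")
    row_sums = t.sum(axis=1).tolist()
    col_sums = t.sum(axis=0).tolist()
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])
    obs = _log_table_prob([tuple(r) for r in t.tolist()], log_fact)
    total = 0.0
    for tab in _rxc_tables(row_sums, col_sums):
        lp = _log_table_prob(tab, log_fact)
        if lp <= obs + np.log1p(rel_tol):
            total += np.exp(lp)
    return float(min(total, 1.0))


@dataclass
class AssociationResult:
    """One feature's association with the subgroup labels."""

    feature: str
    test: str
    mode: str
    comparisons: pd.DataFrame  # columns: comparison, statistic, p_raw, p_adj

    @property
    def min_p_adj(self) -> float:
        return float(self.comparisons["p_adj"].min())


def categorical_association(
    clinical: ClinicalTable | pd.Series,
    labels: pd.Series,
    feature: str | None = None,
    mode: str = "one-vs-rest",
) -> AssociationResult:
    """Fisher association between a categorical feature and subgroup labels.

    ``one-vs-rest`` (default): for each subgroup (and, for multi-level
    features, each level) a 2x2 in-subgroup-vs-rest table, with BH across
    the subgroup comparisons.  ``rxc``: one omnibus exact p from complete
    enumeration.  Samples with unknown feature values are dropped.
    """
    if isinstance(clinical, ClinicalTable):
        if feature is None:
            raise ValueError("feature name required with a ClinicalTable")
        values = clinical[feature]
    else:
        values = clinical
        feature = feature or (values.name or "feature")
    shared = values.index.intersection(labels.index)
    values = values.loc[shared]
    labels = labels.loc[shared]
    keep = values.notna()
    values, labels = values[keep], labels[keep]
    levels = sorted(map(str, pd.unique(values.astype(str))))
    groups = sorted(map(str, pd.unique(labels.astype(str))))
    if len(levels) < 2:
        raise ValueError(f"feature {feature!r} has fewer than 2 levels")
    if len(groups) < 2:
        raise ValueError("labels have fewer than 2 subgroups")
    v = values.astype(str).to_numpy()
    g = labels.astype(str).to_numpy()

    if mode == "rxc":
        table = [[int(((g == gr) & (v == lv)).sum()) for lv in levels] for gr in groups]
        p = fisher_exact_rxc(table)
        comp = pd.DataFrame(
            {"comparison": ["omnibus"], "statistic": [np.nan], "p_raw": [p], "p_adj": [p]}
        )
        return AssociationResult(feature, "fisher_exact_rxc", mode, comp)

    if mode != "one-vs-rest":
        raise ValueError(f"unknown mode {mode!r}")

    test_levels = levels[1:] if len(levels) == 2 else levels
    rows = []
    for gr in groups:
        in_g = g == gr
        for lv in test_levels:
            has = v == lv
            table = [
                [int((in_g & has).sum()), int((in_g & ~has).sum())],
                [int((~in_g & has).sum()), int((~in_g & ~has).sum())],
            ]
            odds = stats.contingency.odds_ratio(table, kind="sample").statistic
            name = f"{gr} vs rest" if len(levels) == 2 else f"{gr} vs rest: {lv}"
            rows.append((name, float(odds), fisher_exact_2x2(table)))
    comp = pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw"])
    comp["p_adj"] = bh_adjust(comp["p_raw"].to_numpy())
    return AssociationResult(feature, "fisher_exact_2x2", mode, comp)


def _groups_from_labels(values: pd.Series, labels: pd.Series):
    shared = values.index.intersection(labels.index)
    values, labels = values.loc[shared], labels.loc[shared]
    keep = values.notna()
    values, labels = values[keep], labels[keep]
    names = sorted(map(str, pd.unique(labels.astype(str))))
    groups = [values[labels.astype(str) == name].to_numpy(dtype=float) for name in names]
    return names, groups


def kruskal_wallis(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = groups - 1).

    Degenerate all-identical data returns (0, 1) rather than erroring."""
    names, groups = _groups_from_labels(values, labels)
    if len(names) < 2:
        raise ValueError("need >=2 groups")
    if any(len(grp) == 0 for grp in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def rank_sum_p(x, y, use_continuity: bool = True) -> float:
    """Two-sided rank-sum p: exact by full enumeration when both groups have
    <=10 observations and there are no ties, otherwise the normal
    approximation with tie correction and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 10 and len(y) <= 10 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=use_continuity)
    return float(res.pvalue)


def pairwise_wilcoxon(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Post hoc pairwise rank-sum tests over all subgroup pairs, BH-adjusted
    across the pairs."""
    names, groups = _groups_from_labels(values, labels)
    if len(names) < 2:
        raise ValueError("need >=2 groups")
    by_name = dict(zip(names, groups))
    rows = []
    for a, b in combinations(names, 2):
        rows.append((f"{a}-{b}", rank_sum_p(by_name[a], by_name[b])))
    out = pd.DataFrame(rows, columns=["pair", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out
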