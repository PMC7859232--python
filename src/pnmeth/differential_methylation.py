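"""Pairwise per-probe differential methylation between subgroups.

For every unordered subgroup pair and every probe a two-sample t-test
(Welch by default) is computed on the beta-values; p-values are BH-adjusted
across all probes WITHIN that pair (three separate families at k=3; a
pooled-family option exists) and a site is called significant when
q < 0.05 AND |delta beta| >= 0.20 — the effect-size gate is what keeps
statistically detectable but biologically negligible differences out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BetaMatrix, ProbeAnnotation, PROMOTER_REGIONS
from .group_association import bh_adjust

__all__ = ["DMConfig", "DMSummary", "pairwise_dm", "summarize_dm", "significant_sites"]


@dataclass
class DMConfig:
    q_threshold: float = 0.05
    delta_threshold: float = 0.20
    delta_inclusive: bool = True  # |delta| >= threshold (Results' ">= 0.20")
    equal_var: bool = False  # Welch by default
    bh_family: str = "per-pair"  # or "pooled"


def pairwise_dm(
    beta: BetaMatrix | pd.DataFrame,
    labels: pd.Series,
    config: DMConfig | None = None,
) -> pd.DataFrame:
    """Per-probe differential methylation for every unordered subgroup pair.

    Returns a DataFrame with columns probe_id, group1, group2, pair, mean1,
    mean2, delta_beta (mean1 - mean2, groups in sorted label order), p, q,
    significant.  Every probe must be complete; every subgroup needs >= 2
    samples.  Degenerate probes (zero variance in both groups, equal means)
    get p = 1.
    """
    config = config or DMConfig()
    values = beta.tumour_values() if isinstance(beta, BetaMatrix) else beta
    shared = values.columns.intersection(labels.index)
    values = values[shared]
    labels = labels.loc[shared]
    if values.isna().any().any():
        raise ValueError("beta matrix contains missing values; drop incomplete probes")
    group_names = sorted(map(str, pd.unique(labels.astype(str))))
    arrays = {}
    for name in group_names:
        cols = values.columns[(labels.astype(str) == name).to_numpy()]
        if len(cols) < 2:
            raise ValueError(f"subgroup {name!r} has fewer than 2 samples")
        arrays[name] = values[cols].to_numpy(dtype=float)

    frames = []
    for g1, g2 in combinations(group_names, 2):
        a, b = arrays[g1], arrays[g2]
        mean1 = a.mean(axis=1)
        mean2 = b.mean(axis=1)
        delta = mean1 - mean2
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=config.equal_var)
        p = np.asarray(p, dtype=float)
        nan = np.isnan(p)
        if nan.any():
            # zero variance in both groups: p=1 when means equal, else 0
            p[nan] = np.where(np.isclose(delta[nan], 0.0), 1.0, 0.0)
        frames.append(pd.DataFrame({
            "probe_id": values.index,
            "group1": g1,
            "group2": g2,
            "pair": f"{g1}-{g2}",
            "mean1": mean1,
            "mean2": mean2,
            "delta_beta": delta,
            "p": p,
        }))
    out = pd.concat(frames, ignore_index=True)
    if config.bh_family == "pooled":
        out["q"] = bh_adjust(out["p"].to_numpy())
    elif config.bh_family == "per-pair":
        out["q"] = np.nan
        for pair, idx in out.groupby("pair").groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    else:
        raise ValueError(f"unknown bh_family {config.bh_family!r}")
    gate = (np.abs(out["delta_beta"]) >= config.delta_threshold
            if config.delta_inclusive
            else np.abs(out["delta_beta"]) > config.delta_threshold)
    out["significant"] = (out["q"] < config.q_threshold) & gate
    return out


def significant_sites(dm: pd.DataFrame) -> pd.Index:
    """Union over pairs of significant probe ids."""
    return pd.Index(dm.loc[dm["significant"], "probe_id"].unique())


@dataclass
class DMSummary:
    """Site and gene accounting of a DM result set.

    ``promoter`` membership uses the same region rule as the subtyping
    cascade; gene counts come from the exploded (probe, gene) map, so the
    promoter + elsewhere partition sums to the total per pair and overall.
    """

    total_sites: int
    promoter_sites: int
    elsewhere_sites: int
    genes_any: int
    genes_promoter: int
    per_pair: pd.DataFrame
    per_gene_counts: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "total_sites": self.total_sites,
            "promoter_sites": self.promoter_sites,
            "elsewhere_sites": self.elsewhere_sites,
            "genes_any": self.genes_any,
            "genes_promoter": self.genes_promoter,
            "per_pair": self.per_pair.to_dict(orient="records"),
        }


def _gene_stats(sites: pd.Index, annotation: ProbeAnnotation) -> tuple[int, int, pd.Series]:
    gm = annotation.gene_map
    hit = gm[gm["probe_id"].isin(set(sites))]
    genes_any = hit["gene"].nunique()
    prom = hit[hit["region"].isin(PROMOTER_REGIONS)]
    genes_prom = prom["gene"].nunique()
    per_gene = hit.drop_duplicates(["probe_id", "gene"]).groupby("gene").size()
    return genes_any, genes_prom, per_gene.sort_values(ascending=False)


def summarize_dm(dm: pd.DataFrame, annotation: ProbeAnnotation) -> DMSummary:
    """Summarize significant sites per pair and over the union of pairs."""
    promoter = set(annotation.promoter_probes())
    rows = []
    for pair, grp in dm.groupby("pair", sort=True):
        sites = pd.Index(grp.loc[grp["significant"], "probe_id"].unique())
        n_prom = int(sites.isin(promoter).sum())
        g_any, g_prom, _ = _gene_stats(sites, annotation)
        rows.append({
            "pair": pair,
            "n_significant": len(sites),
            "n_promoter": n_prom,
            "n_elsewhere": len(sites) - n_prom,
            "n_genes": g_any,
            "n_promoter_genes": g_prom,
        })
    union = significant_sites(dm)
    n_prom = int(union.isin(promoter).sum())
    g_any, g_prom, per_gene = _gene_stats(union, annotation)
    return DMSummary(
        total_sites=len(union),
        promoter_sites=n_prom,
        elsewhere_sites=len(union) - n_prom,
        genes_any=g_any,
        genes_promoter=g_prom,
        per_pair=pd.DataFrame(rows),
        per_gene_counts=per_gene,
    )
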