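"""Chromosome-arm copy-number/LOH summaries, the LOH-vs-methylation
negative-control test, and alpha/beta-islet signature scoring.

Arm definitions (centromere boundaries) are supplied as a table; nothing is
looked up from a genome build at run time.  Arm logR summaries use a
length-weighted median with ties broken toward the lower value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ProbeAnnotation, SegmentTable, PROMOTER_REGIONS
from .group_association import bh_adjust, rank_sum_p
from .subtype_discovery import select_variable_probes, ward_cluster

__all__ = [
    "ArmSummaryResult",
    "LOHMethylationResult",
    "IsletSignatureResult",
    "default_arm_table",
    "arm_summaries",
    "cluster_arms",
    "loh_methylation_test",
    "islet_signature",
    "weighted_median",
]

logger = logging.getLogger(__name__)

#: Synthetic autosome lengths (bp) and centromere fractions used by the
#: default arm table; real analyses supply their own arm definitions.
_DEFAULT_CHROM_LENGTH = {str(c): 250_000_000 - 8_000_000 * (c - 1) for c in range(1, 23)}
_CENTROMERE_FRACTION = 0.4


def default_arm_table() -> pd.DataFrame:
    """A synthetic arm-definition table for chromosomes 1..22 (columns arm,
    chrom, start, end; 1-based inclusive).  The p arm spans from 1 to the
    centromere, the q arm from centromere+1 to the chromosome end."""
    rows = []
    for chrom, length in _DEFAULT_CHROM_LENGTH.items():
        cen = int(length * _CENTROMERE_FRACTION)
        rows.append((f"{chrom}p", chrom, 1, cen))
        rows.append((f"{chrom}q", chrom, cen + 1, length))
    return pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])


def _validate_arms(arms: pd.DataFrame) -> None:
    if (arms["end"] <= arms["start"]).any():
        raise ValueError("arm end must exceed start")
    for chrom, grp in arms.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping arms on chromosome {chrom}")


def weighted_median(values, weights) -> float:
    """Weighted median; with an even split the lower value is returned
    (deterministic tie-break)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = w.sum() / 2.0
    return float(v[np.searchsorted(cum, half)])


@dataclass
class ArmSummaryResult:
    """Per (sample, arm) LOH fraction and length-weighted median logR."""

    table: pd.DataFrame  # sample, arm, loh_fraction, median_logr

    def matrix(self, value: str = "loh_fraction") -> pd.DataFrame:
        """Arm x sample matrix of one summary value."""
        return self.table.pivot(index="arm", columns="sample", values=value)


def arm_summaries(segments: SegmentTable, arms: pd.DataFrame) -> ArmSummaryResult:
    """Summarize segments per chromosome arm.

    loh_fraction = sum of overlap lengths of loh=True segments / arm length;
    median_logr = overlap-length-weighted median of segment logR.  Arms with
    no covering segment in a sample are omitted (logged).
    """
    _validate_arms(arms)
    seg = segments.table
    rows = []
    n_missing = 0
    for sample, sgrp in seg.groupby("sample", sort=True):
        for arm_row in arms.itertuples(index=False):
            on = sgrp[sgrp["chrom"].astype(str) == str(arm_row.chrom)]
            if len(on) == 0:
                n_missing += 1
                continue
            ov_start = np.maximum(on["start"].to_numpy(), arm_row.start)
            ov_end = np.minimum(on["end"].to_numpy(), arm_row.end)
            ov_len = np.maximum(0, ov_end - ov_start + 1)
            covered = ov_len > 0
            if not covered.any():
                n_missing += 1
                continue
            arm_len = arm_row.end - arm_row.start + 1
            loh_len = ov_len[covered & on["loh"].to_numpy()].sum()
            med = weighted_median(on["logr"].to_numpy()[covered], ov_len[covered])
            rows.append((sample, arm_row.arm, loh_len / arm_len, med))
    if n_missing:
        logger.info("%d (sample, arm) combinations had no coverage", n_missing)
    return ArmSummaryResult(
        pd.DataFrame(rows, columns=["sample", "arm", "loh_fraction", "median_logr"])
    )


def cluster_arms(arm_matrix: pd.DataFrame, variant: str = "ward.D2"):
    """Ward-cluster chromosome arms (rows) on Euclidean distance over
    samples; returns (leaf order, SubtypeAssignment with the dendrogram).
    Missing entries are imputed as 0 with a warning."""
    m = arm_matrix.copy()
    if m.isna().any().any():
        warnings.warn("missing arm summaries imputed as 0 for clustering")
        m = m.fillna(0.0)
    x = m.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    dist = pd.DataFrame(d, index=m.index, columns=m.index)
    assignment = ward_cluster(dist, k=1, variant=variant)
    return assignment.leaf_order, assignment


@dataclass
class LOHMethylationResult:
    """Outcome of the LOH-vs-methylation contrast.

    ``mean_difference`` is (LOH subgroup mean beta) - (rest mean beta)
    aggregated over selected probes; the bootstrap interval is percentile
    95%.  ``proportion_lower``/``proportion_higher`` count probes where the
    LOH subgroup is significantly lower/higher (BH-adjusted rank-sum
    p < 0.05).
    """

    context: str
    n_probes: int
    mean_difference: float
    ci_low: float
    ci_high: float
    proportion_lower: float
    proportion_higher: float
    per_probe: pd.DataFrame


def loh_methylation_test(
    beta: BetaMatrix,
    labels: pd.Series,
    annotation: ProbeAnnotation,
    loh_chromosomes,
    loh_group: str,
    context: str = "promoter",
    sd_threshold: float = 0.20,
    n_boot: int = 1000,
    seed: int = 0,
) -> LOHMethylationResult:
    """Does the LOH-enriched subgroup have lower methylation on LOH
    chromosomes?  Selects probes on ``loh_chromosomes`` in the requested
    context (promoter or gene_body) with tumour SD >= sd_threshold (the
    boundary is included here), contrasts ``loh_group`` vs the rest per
    probe (rank-sum, BH) and in aggregate (mean beta difference with a
    bootstrap interval)."""
    loh_chromosomes = [str(c) for c in loh_chromosomes]
    if not loh_chromosomes:
        raise ValueError("loh_chromosomes is empty")
    if context == "promoter":
        ctx_probes = annotation.promoter_probes()
    elif context == "gene_body":
        gm = annotation.gene_map
        ctx_probes = pd.Index(gm.loc[gm["region"] == "Body", "probe_id"].unique())
    else:
        raise ValueError(f"unknown context {context!r}")
    on_chrom = annotation.probes["chromosome"].astype(str).isin(loh_chromosomes)
    chrom_probes = annotation.probes.index[on_chrom]
    variable = select_variable_probes(beta, sd_threshold, inclusive=True)
    probes = beta.probe_ids
    probes = probes[probes.isin(ctx_probes) & probes.isin(chrom_probes)
                    & probes.isin(variable)]
    if len(probes) == 0:
        raise ValueError("no probes selected for the LOH-methylation contrast")

    tumours = beta.tumour_values().loc[probes]
    shared = tumours.columns.intersection(labels.index)
    lab = labels.loc[shared].astype(str)
    in_g = shared[(lab == str(loh_group)).to_numpy()]
    rest = shared[(lab != str(loh_group)).to_numpy()]
    if len(in_g) == 0 or len(rest) == 0:
        raise ValueError(f"subgroup {loh_group!r} or its complement is empty")
    a = tumours[in_g].to_numpy(dtype=float)
    b = tumours[rest].to_numpy(dtype=float)

    pvals = np.array([rank_sum_p(a[i], b[i]) for i in range(len(probes))])
    diff = a.mean(axis=1) - b.mean(axis=1)
    padj = bh_adjust(pvals)
    per_probe = pd.DataFrame({
        "probe_id": probes,
        "mean_diff": diff,
        "p_raw": pvals,
        "p_adj": padj,
    })
    sig = padj < 0.05
    prop_lower = float((sig & (diff < 0)).mean())
    prop_higher = float((sig & (diff > 0)).mean())

    # aggregate: per-sample mean beta over selected probes
    agg_g = a.mean(axis=0)
    agg_r = b.mean(axis=0)
    observed = float(agg_g.mean() - agg_r.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = (
            rng.choice(agg_g, size=len(agg_g), replace=True).mean()
            - rng.choice(agg_r, size=len(agg_r), replace=True).mean()
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return LOHMethylationResult(
        context=context,
        n_probes=len(probes),
        mean_difference=observed,
        ci_low=float(lo),
        ci_high=float(hi),
        proportion_lower=prop_lower,
        proportion_higher=prop_higher,
        per_probe=per_probe,
    )


@dataclass
class IsletSignatureResult:
    """Per-sample nearest-profile call over the islet signature probes."""

    signature_probes: pd.Index
    table: pd.DataFrame  # sample, score, call

    def calls(self) -> pd.Series:
        return self.table.set_index("sample")["call"]


def islet_signature(
    beta: BetaMatrix,
    reference: pd.DataFrame,
    diff_threshold: float = 0.3,
) -> IsletSignatureResult:
    """Score tumours against alpha-like / beta-like islet reference profiles.

    Signature probes are those where the two reference profiles differ by
    more than ``diff_threshold`` in mean beta.  Per sample,
    score = mean |beta - alpha profile| - mean |beta - beta profile|; the
    call is the nearest profile (score > 0: beta-like), exact ties are
    unclassified.  The call is invariant to adding non-signature probes.
    """
    if not {"alpha", "beta_like"} <= set(reference.columns):
        raise ValueError("reference needs columns 'alpha' and 'beta_like'")
    shared = beta.probe_ids.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("reference shares no probes with the beta matrix")
    ref = reference.loc[shared]
    sig = shared[(np.abs(ref["alpha"] - ref["beta_like"]) > diff_threshold).to_numpy()]
    if len(sig) == 0:
        raise ValueError(f"no probes exceed the {diff_threshold} reference difference")
    tumours = beta.tumour_values().loc[sig]
    alpha = ref.loc[sig, "alpha"].to_numpy()[:, None]
    blike = ref.loc[sig, "beta_like"].to_numpy()[:, None]
    t = tumours.to_numpy(dtype=float)
    score = np.abs(t - alpha).mean(axis=0) - np.abs(t - blike).mean(axis=0)
    call = np.where(score > 0, "beta-like", np.where(score < 0, "alpha-like", "unclassified"))
    table = pd.DataFrame({"sample": tumours.columns, "score": score, "call": call})
    return IsletSignatureResult(signature_probes=sig, table=table)
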