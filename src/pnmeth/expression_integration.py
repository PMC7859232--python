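"""Expression processing and methylation-expression integration.

Counts are scaled to CPM, genes below the expression detection limit are
removed (>= 3 CPM in at least max(2, floor(0.05 * n)) samples), libraries
are normalized by the trimmed mean of M-values (TMM: doubly trimmed,
precision-weighted mean of log2 expression ratios against an
upper-quartile-matched reference, factors rescaled to geometric mean 1),
and methylation is related to log2(TMM-adjusted CPM + 1) by Pearson
correlation over the differentially methylated sites that map to a gene
footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BetaMatrix, CountMatrix, ProbeAnnotation, REGION_GROUPS
from .group_association import bh_adjust, rank_sum_p

__all__ = [
    "NormalizedExpression",
    "TMMDiagnostics",
    "GeneMethylationReport",
    "cpm",
    "expressed_filter",
    "tmm_factors",
    "normalize_expression",
    "methylation_expression_correlation",
    "gene_report",
]

logger = logging.getLogger(__name__)


def _counts_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.values if isinstance(counts, CountMatrix) else counts


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, library size = column
    sum of raw counts.  Every column sums to 1e6."""
    df = _counts_frame(counts)
    lib = df.sum(axis=0)
    if (lib == 0).any():
        empty = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size for samples: {empty[:5]}")
    return df / lib * 1e6


def expressed_filter(
    counts: CountMatrix | pd.DataFrame,
    min_cpm: float = 3.0,
    min_fraction: float = 0.05,
) -> pd.Index:
    """Genes with cpm >= min_cpm in at least max(2, floor(min_fraction * n))
    samples.  The floor of 2 reproduces the n = 2 sample threshold at a
    47-sample cohort."""
    c = cpm(counts)
    n = c.shape[1]
    threshold = max(2, int(np.floor(min_fraction * n)))
    keep = (c >= min_cpm).sum(axis=1) >= threshold
    return c.index[keep.to_numpy()]


@dataclass
class TMMDiagnostics:
    reference: str
    trim_m: float
    trim_a: float
    per_sample: dict = field(default_factory=dict)  # sample -> dict(M, A, keep)


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    """Trimmed, precision-weighted mean M-value of one sample against the
    reference; returns (factor, M, A, keep mask over finite entries)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log2((obs / lib_obs) / (ref / lib_ref))
        abse = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(logr) & np.isfinite(abse)
    logr, abse, v = logr[finite], abse[finite], v[finite]
    if logr.size == 0:
        raise ValueError("sample shares no positive genes with the reference")
    if np.max(np.abs(logr)) < 1e-6:
        return 1.0, logr, abse, np.ones(logr.size, dtype=bool)
    n = logr.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(logr)
    rank_a = stats.rankdata(abse)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        raise ValueError("trimming removed all genes")
    f = np.sum(logr[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2 ** f), logr, abse, keep


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    expressed_genes: pd.Index | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[pd.Series, TMMDiagnostics]:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference is the sample whose upper quartile of CPM is closest to
    the mean upper quartile; M and A are computed over genes positive in
    both the sample and the reference, doubly trimmed (``trim_m`` on M,
    ``trim_a`` on A), and averaged with precision (inverse asymptotic
    variance) weights.
    """
    if not 0 <= trim_m < 0.5 or not 0 <= trim_a < 0.5:
        raise ValueError("trim fractions must lie in [0, 0.5)")
    df = _counts_frame(counts)
    if expressed_genes is not None:
        df = df.loc[pd.Index(expressed_genes)]
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    arr = df.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    uq = np.array([np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = arr[:, ref_idx]
    diag = TMMDiagnostics(reference=str(df.columns[ref_idx]), trim_m=trim_m, trim_a=trim_a)
    factors = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        f, m, a, keep = _tmm_pair(arr[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        factors[j] = f
        diag.per_sample[str(df.columns[j])] = {"M": m, "A": a, "keep": keep}
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor"), diag


@dataclass
class NormalizedExpression:
    """CPM, TMM factors, and log2(TMM-adjusted CPM + 1)."""

    cpm: pd.DataFrame
    tmm_factor: pd.Series
    log_expression: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.log_expression.columns


def normalize_expression(
    counts: CountMatrix | pd.DataFrame,
    expressed_genes: pd.Index | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizedExpression:
    """CPM + TMM + log transform in one step.  TMM factors are estimated on
    ``expressed_genes`` (all genes when None); the returned matrices cover
    all genes."""
    df = _counts_frame(counts)
    c = cpm(df)
    factors, _ = tmm_factors(df, expressed_genes, trim_m, trim_a)
    lib = df.sum(axis=0)
    eff = lib * factors
    log_expr = np.log2(df / eff * 1e6 + 1)
    return NormalizedExpression(cpm=c, tmm_factor=factors, log_expression=log_expr)


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-distributed p for Pearson r at df = n - 2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def methylation_expression_correlation(
    beta: BetaMatrix,
    expression: NormalizedExpression,
    annotation: ProbeAnnotation,
    dm_sites: pd.Index,
    expressed_genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Pearson correlation of probe beta with gene log-expression.

    The tested universe is every (probe, gene) pair where the probe is a DM
    site mapping to the gene's footprint (TSS1500/TSS200/5'UTR/1stExon/
    Body/3'UTR) and the gene passes the expressed filter.  BH adjustment is
    across all tested pairs.  Constant-beta probes are skipped and logged.
    """
    if expressed_genes is None:
        expressed_genes = expressed_filter(expression.cpm)
    shared = beta.sample_ids.intersection(expression.sample_ids)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    gm = annotation.gene_map
    pairs = gm[
        gm["probe_id"].isin(set(dm_sites))
        & gm["region"].isin(REGION_GROUPS)
        & gm["gene"].isin(set(expressed_genes) & set(expression.log_expression.index))
    ].drop_duplicates(["probe_id", "gene"])
    if len(pairs) == 0:
        return pd.DataFrame(
            columns=["probe_id", "gene", "region", "r", "p_raw", "p_adj", "n"]
        )
    b = beta.values.loc[pairs["probe_id"], shared].to_numpy(dtype=float)
    e = expression.log_expression.loc[pairs["gene"], shared].to_numpy(dtype=float)
    n = len(shared)
    bc = b - b.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    var_b = (bc ** 2).sum(axis=1)
    var_e = (ec ** 2).sum(axis=1)
    denom = np.sqrt(var_b * var_e)
    # sum-of-squares below 1e-20 is numerically constant (float centering
    # leaves ~1e-31 residue on a truly flat row)
    constant = (var_b <= 1e-20) | (var_e <= 1e-20)
    if constant.any():
        logger.info("skipping %d constant probe/gene pairs", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(constant, np.nan, (bc * ec).sum(axis=1) / np.where(constant, 1, denom))
    out = pd.DataFrame({
        "probe_id": pairs["probe_id"].to_numpy(),
        "gene": pairs["gene"].to_numpy(),
        "region": pairs["region"].to_numpy(),
        "r": r,
        "n": n,
    })
    out = out[~constant].reset_index(drop=True)
    out["p_raw"] = _pearson_p(out["r"].to_numpy(), n)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out[["probe_id", "gene", "region", "r", "p_raw", "p_adj", "n"]]


@dataclass
class GeneMethylationReport:
    """Per-gene methylation/expression report (gene-body medians, subgroup
    means, expression correlation and one-vs-rest contrasts)."""

    gene: str
    probes: pd.DataFrame  # probe_id, position, region (5'->3' order)
    subgroup_mean_beta: pd.DataFrame  # probe x subgroup
    normal_mean_beta: pd.Series
    sample_median_body_beta: pd.Series
    body_probes_used: pd.Index
    correlation_r: float
    correlation_p: float
    contrasts: pd.DataFrame  # subgroup, p (one-vs-rest rank-sum on body median)


def gene_report(
    gene: str,
    beta: BetaMatrix,
    expression: NormalizedExpression | None,
    annotation: ProbeAnnotation,
    labels: pd.Series,
) -> GeneMethylationReport:
    """MGMT-style gene report: probes ordered by genomic position, mean beta
    per probe per subgroup, per-sample median gene-body beta, its Pearson
    correlation with log-expression (when expression is available) and
    one-vs-rest rank-sum contrasts of the body median per subgroup.

    Genes without Body-annotated probes fall back to all their probes for
    the median (a single-probe gene's median is that probe's beta).
    """
    probe_ids = annotation.probes_for_gene(gene)
    probe_ids = probe_ids[probe_ids.isin(beta.probe_ids)]
    if len(probe_ids) == 0:
        raise ValueError(f"gene {gene!r} has no annotated probes in the matrix")
    pos = annotation.probes.loc[probe_ids, "position"].sort_values(kind="mergesort")
    probe_ids = pos.index
    gm = annotation.gene_map
    region = (
        gm[(gm["gene"] == gene) & gm["probe_id"].isin(set(probe_ids))]
        .drop_duplicates("probe_id").set_index("probe_id")["region"]
        .reindex(probe_ids)
    )
    probes = pd.DataFrame({"probe_id": probe_ids, "position": pos.to_numpy(),
                           "region": region.to_numpy()}).reset_index(drop=True)

    tumours = beta.tumour_values().loc[probe_ids]
    shared = tumours.columns.intersection(labels.index)
    lab = labels.loc[shared].astype(str)
    sub_means = tumours[shared].T.groupby(lab).mean().T
    normal_mean = beta.normal_values().loc[probe_ids].mean(axis=1)

    body = annotation.body_probes_for_gene(gene)
    body = body[body.isin(probe_ids)]
    if len(body) == 0:
        body = probe_ids
    median_body = tumours.loc[body].median(axis=0)

    r = p = float("nan")
    if expression is not None and gene in expression.log_expression.index:
        expr_shared = median_body.index.intersection(expression.sample_ids)
        if len(expr_shared) >= 3:
            m = median_body.loc[expr_shared].to_numpy()
            e = expression.log_expression.loc[gene, expr_shared].to_numpy(dtype=float)
            if np.std(m) > 0 and np.std(e) > 0:
                r, p = stats.pearsonr(m, e)
                r, p = float(r), float(p)

    rows = []
    for grp in sorted(lab.unique()):
        in_g = median_body.loc[shared][lab == grp].to_numpy()
        rest = median_body.loc[shared][lab != grp].to_numpy()
        rows.append((grp, rank_sum_p(in_g, rest)))
    contrasts = pd.DataFrame(rows, columns=["subgroup", "p"])

    return GeneMethylationReport(
        gene=gene,
        probes=probes,
        subgroup_mean_beta=sub_means,
        normal_mean_beta=normal_mean,
        sample_median_body_beta=median_body,
        body_probes_used=body,
        correlation_r=r,
        correlation_p=p,
        contrasts=contrasts,
    )
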