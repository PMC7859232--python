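"""Readers, writers and validation for the tabular formats the pipeline touches.

All genomic coordinates are 1-based inclusive (array-manifest / SEG
convention).  Missing values are written as ``NA`` in every TSV; readers
accept both ``NA`` and the empty string as missing.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "BetaMatrix",
    "ProbeAnnotation",
    "ClinicalTable",
    "SegmentTable",
    "CountMatrix",
    "CohortSummary",
    "PROMOTER_REGIONS",
    "REGION_GROUPS",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_segments",
    "write_segments",
    "read_clinical_table",
    "write_clinical_table",
    "read_counts",
    "write_counts",
    "summarize_cohort",
]

NA_VALUES = ["NA", ""]

#: Manifest region groups counted as promoter context.
PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon"})
#: All region groups accepted in annotations (gene footprint).
REGION_GROUPS = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR"})

VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

#: Canonical clinical column layout.  A reader-side ``column_map`` may rename
#: arbitrary source columns onto these.
CLINICAL_COLUMNS = [
    "sex",
    "grade",
    "functional",
    "tumour_size",
    "telomere_ratio",
    "alt_status",
    "mut_ATRX",
    "mut_DAXX",
    "mut_MEN1",
    "mut_mTOR",
    "inv_extrapancreatic",
    "inv_perineural",
    "inv_vascular",
    "tmb",
]

MUTATION_COLUMNS = ["mut_ATRX", "mut_DAXX", "mut_MEN1", "mut_mTOR"]


class FormatError(ValueError):
    """Raised when an input table violates the documented dialect."""


def _check_unique(ids: Iterable, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dupes[:5]}")


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta-values in [0, 1].

    ``values`` is indexed by probe id with one column per sample; missing
    cells are NaN.  ``sample_role`` maps every sample id to ``tumour`` or
    ``normal``.
    """

    values: pd.DataFrame
    sample_role: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "sample id")
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise FormatError(
                f"beta matrix needs >=1 probe and >=2 samples, got {self.values.shape}"
            )
        self.sample_role = pd.Series(self.sample_role)
        missing = self.values.columns.difference(self.sample_role.index)
        if len(missing):
            raise FormatError(f"samples without a role: {list(missing)[:5]}")
        self.sample_role = self.sample_role.reindex(self.values.columns)
        bad_roles = set(self.sample_role.unique()) - {"tumour", "normal"}
        if bad_roles:
            raise FormatError(f"unknown sample roles: {sorted(bad_roles)}")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out = (arr < 0) | (arr > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise FormatError(
                "beta value outside [0,1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}: "
                f"{arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tumour_ids(self) -> pd.Index:
        return self.values.columns[self.sample_role.to_numpy() == "tumour"]

    @property
    def normal_ids(self) -> pd.Index:
        return self.values.columns[self.sample_role.to_numpy() == "normal"]

    def tumour_values(self) -> pd.DataFrame:
        return self.values[self.tumour_ids]

    def normal_values(self) -> pd.DataFrame:
        return self.values[self.normal_ids]

    def subset_probes(self, probe_ids: Sequence) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[pd.Index(probe_ids)], self.sample_role)

    def subset_samples(self, sample_ids: Sequence) -> "BetaMatrix":
        ids = pd.Index(sample_ids)
        return BetaMatrix(self.values[ids], self.sample_role.loc[ids])


def read_beta_matrix(path, role_map: Mapping[str, str]) -> BetaMatrix:
    """Read a TSV beta matrix (first column probe ids, header sample ids).

    ``role_map`` assigns every sample id a role in ``{tumour, normal}``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    role = pd.Series({s: role_map[s] for s in df.columns if s in role_map})
    missing = [s for s in df.columns if s not in role_map]
    if missing:
        raise FormatError(f"no role for samples: {missing[:5]}")
    return BetaMatrix(df.astype(float), role)


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    bm.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation plus exploded (probe, gene, region) map.

    ``probes``: indexed by probe id with columns chromosome, position,
    is_cpg, is_snp_masked, is_multimap.
    ``gene_map``: one row per (probe_id, gene, region) tuple, deduplicated;
    intergenic probes have no rows here.
    """

    probes: pd.DataFrame
    gene_map: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.probes.index, "probe id")
        bad_chrom = set(self.probes["chromosome"].astype(str)) - VALID_CHROMOSOMES
        if bad_chrom:
            raise FormatError(f"invalid chromosomes: {sorted(bad_chrom)[:5]}")
        if (self.probes["position"] < 1).any():
            raise FormatError("probe positions must be >= 1")
        bad_region = set(self.gene_map["region"]) - REGION_GROUPS
        if bad_region:
            raise FormatError(f"invalid region groups: {sorted(bad_region)[:5]}")
        unknown = set(self.gene_map["probe_id"]) - set(self.probes.index)
        if unknown:
            raise FormatError(f"gene_map probes missing from table: {sorted(unknown)[:5]}")
        self.gene_map = self.gene_map.drop_duplicates().reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def promoter_probes(self) -> pd.Index:
        """Probes with any (gene, region) pair in a promoter region group."""
        hit = self.gene_map["region"].isin(PROMOTER_REGIONS)
        return pd.Index(self.gene_map.loc[hit, "probe_id"].unique())

    def footprint_probes(self) -> pd.Index:
        """Probes mapping to any gene footprint region (all six groups)."""
        return pd.Index(self.gene_map["probe_id"].unique())

    def probes_for_gene(self, gene: str) -> pd.Index:
        hit = self.gene_map["gene"] == gene
        return pd.Index(self.gene_map.loc[hit, "probe_id"].unique())

    def body_probes_for_gene(self, gene: str) -> pd.Index:
        hit = (self.gene_map["gene"] == gene) & (self.gene_map["region"] == "Body")
        return pd.Index(self.gene_map.loc[hit, "probe_id"].unique())

    def subset(self, probe_ids: Sequence) -> "ProbeAnnotation":
        ids = pd.Index(probe_ids)
        gm = self.gene_map[self.gene_map["probe_id"].isin(set(ids))]
        return ProbeAnnotation(self.probes.loc[ids], gm.reset_index(drop=True))


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a manifest-dialect CSV probe annotation.

    Columns: probe_id, chromosome, position, genes, regions, is_cpg,
    is_snp_masked, is_multimap.  ``genes`` and ``regions`` are
    semicolon-delimited parallel lists; an empty gene field means intergenic.
    """
    df = pd.read_csv(path, dtype={"chromosome": str}, na_values=NA_VALUES,
                     keep_default_na=False)
    df["probe_id"] = df["probe_id"].astype(str)
    records = []
    for row in df.itertuples(index=False):
        genes = str(row.genes).split(";") if isinstance(row.genes, str) and row.genes else []
        regions = str(row.regions).split(";") if isinstance(row.regions, str) and row.regions else []
        if len(genes) != len(regions):
            raise FormatError(
                f"probe {row.probe_id}: {len(genes)} genes but {len(regions)} regions"
            )
        for g, r in zip(genes, regions):
            records.append((row.probe_id, g, r))
    probes = df.set_index("probe_id")[
        ["chromosome", "position", "is_cpg", "is_snp_masked", "is_multimap"]
    ].copy()
    probes["position"] = probes["position"].astype(int)
    for c in ("is_cpg", "is_snp_masked", "is_multimap"):
        probes[c] = probes[c].astype(bool)
    gene_map = pd.DataFrame(records, columns=["probe_id", "gene", "region"])
    return ProbeAnnotation(probes, gene_map)


def write_probe_annotation(annot: ProbeAnnotation, path) -> None:
    grouped = annot.gene_map.groupby("probe_id", sort=False)
    genes = grouped["gene"].agg(";".join)
    regions = grouped["region"].agg(";".join)
    out = annot.probes.copy()
    out["genes"] = genes.reindex(out.index).fillna("")
    out["regions"] = regions.reindex(out.index).fillna("")
    out = out[["chromosome", "position", "genes", "regions",
               "is_cpg", "is_snp_masked", "is_multimap"]]
    out.to_csv(path, index_label="probe_id")


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Per-sample clinical/genomic covariates (canonical column layout).

    Unknowns are NaN and are never imputed; boolean columns are stored as
    nullable pandas booleans.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample id")
        for col in ("tumour_size", "telomere_ratio", "tmb"):
            if col in self.table and (self.table[col].dropna() < 0).any():
                raise FormatError(f"negative values in {col}")
        sex = set(self.table.get("sex", pd.Series(dtype=object)).dropna())
        if sex - {"F", "M"}:
            raise FormatError(f"invalid sex values: {sorted(sex - {'F', 'M'})}")
        grade = set(self.table.get("grade", pd.Series(dtype=object)).dropna())
        if grade - {"G1", "G2", "G3"}:
            raise FormatError(f"invalid grades: {sorted(grade - {'G1', 'G2', 'G3'})}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


BOOL_CLINICAL = ["functional", "inv_extrapancreatic", "inv_perineural",
                 "inv_vascular"] + MUTATION_COLUMNS


def read_clinical_table(path, column_map: Mapping[str, str] | None = None) -> ClinicalTable:
    """Read a clinical TSV.  ``column_map`` renames source columns onto the
    canonical layout (source name -> canonical name)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in BOOL_CLINICAL:
        if col in df:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False,
                 "true": True, "false": False, 1: True, 0: False,
                 "1": True, "0": False}
            ).astype("boolean")
    return ClinicalTable(df)


def write_clinical_table(clin: ClinicalTable, path) -> None:
    clin.table.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


# ---------------------------------------------------------------------------
# SegmentTable
# ---------------------------------------------------------------------------

@dataclass
class SegmentTable:
    """SEG-like copy-number segments with an LOH flag and logR per segment.

    Sorted by (sample, chrom, start); segments are non-overlapping within a
    sample-chromosome (abutting is allowed: coordinates are 1-based
    inclusive, so [1,100] and [101,200] do not overlap).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample", "chrom", "start", "end", "loh", "logr"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"segment table missing columns: {missing}")
        if (t["start"] > t["end"]).any():
            bad = t[t["start"] > t["end"]].iloc[0]
            raise FormatError(
                f"segment start > end: {bad['sample']} {bad['chrom']}:"
                f"{bad['start']}-{bad['end']}"
            )
        t = t.sort_values(["sample", "chrom", "start"], kind="mergesort")
        for (sample, chrom), grp in t.groupby(["sample", "chrom"], sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = starts[1:] <= ends[:-1]
            if overlap.any():
                i = int(np.argmax(overlap))
                raise FormatError(
                    f"overlapping segments for {sample} chr{chrom}: "
                    f"[{starts[i]},{ends[i]}] and [{starts[i + 1]},{ends[i + 1]}]"
                )
        self.table = t.reset_index(drop=True)

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.table["sample"].unique())


def read_segments(path) -> SegmentTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=NA_VALUES,
                     keep_default_na=False)
    df["sample"] = df["sample"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["loh"] = df["loh"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
    ).astype(bool)
    df["logr"] = df["logr"].astype(float)
    return SegmentTable(df)


def write_segments(seg: SegmentTable, path) -> None:
    seg.table.to_csv(path, sep="\t", na_rep="NA", index=False)


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene-level RNA read counts (genes x samples, nonnegative integers)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            as_int = self.values.astype(np.int64)
            if not np.array_equal(as_int.to_numpy(), arr):
                raise FormatError("counts must be integers")
            self.values = as_int
        if (self.values.to_numpy() < 0).any():
            raise FormatError("counts must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    cm.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Cohort summarization
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Exact category counts over a clinical table; unknowns counted apart."""

    n_tumours: int
    n_normals: int
    sex_counts: "OrderedDict[str, int]" = field(default_factory=OrderedDict)
    grade_counts: "OrderedDict[str, int]" = field(default_factory=OrderedDict)
    functional: int = 0
    functional_unknown: int = 0
    mutation_counts: "OrderedDict[str, int]" = field(default_factory=OrderedDict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_cohort(clinical: ClinicalTable, n_normals: int = 0) -> CohortSummary:
    """Count cohort composition: sex, grade, functional status and mutation
    flags.  Unknown (missing) entries are counted under ``unknown`` keys and
    never imputed; counts are invariant to row order."""
    t = clinical.table
    if len(t) == 0:
        raise FormatError("empty clinical table")
    summary = CohortSummary(n_tumours=len(t), n_normals=n_normals)
    for level in ("F", "M"):
        summary.sex_counts[level] = int((t.get("sex") == level).sum()) if "sex" in t else 0
    if "sex" in t:
        summary.sex_counts["unknown"] = int(t["sex"].isna().sum())
    for level in ("G1", "G2", "G3"):
        summary.grade_counts[level] = int((t.get("grade") == level).sum()) if "grade" in t else 0
    if "grade" in t:
        summary.grade_counts["unknown"] = int(t["grade"].isna().sum())
    if "functional" in t:
        func = t["functional"]
        summary.functional = int((func == True).sum())  # noqa: E712 (nullable boolean)
        summary.functional_unknown = int(func.isna().sum())
    else:
        summary.functional_unknown = len(t)
    for col in MUTATION_COLUMNS:
        if col in t:
            gene = col.removeprefix("mut_")
            summary.mutation_counts[gene] = int((t[col] == True).sum())  # noqa: E712
    return summary
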