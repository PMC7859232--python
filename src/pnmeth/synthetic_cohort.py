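"""Synthetic methylome cohort generator with planted ground truth.

The generator emulates the structure of a tumour/normal 450K-style study:
bimodal beta-values drawn from two beta-distribution modes (low ~0.1, high
~0.8), a set of promoter probes hypermethylated in one latent tumour
subgroup each, subgroup-dependent clinical/genomic covariates, subgroup-
specific whole-arm LOH (deliberately uncoupled from methylation), and gene
expression linked to gene-level methylation for a subset of genes.

Planted hypermethylation is partial: within the target subgroup each
(gene, sample) is methylated with probability
q = planted_delta_beta / (high_mean - low_mean), so the planted group-mean
beta difference equals ``planted_delta_beta`` while the across-tumour SD of
a planted probe stays above the 0.20 variability cutoff used by the
subtyping cascade (a uniform shift of 0.4 at a one-third subgroup fraction
would have SD just below 0.20 and select nothing).

All randomness flows from a single generator stream in a fixed, documented
order (samples -> probe layout -> clinical -> methylation -> QC matrices ->
segments -> expression), so the same seed reproduces the cohort
bit-identically and partial regeneration is not supported.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BetaMatrix,
    ClinicalTable,
    CountMatrix,
    ProbeAnnotation,
    SegmentTable,
    write_beta_matrix,
    write_clinical_table,
    write_counts,
    write_probe_annotation,
    write_segments,
)
from .genome_context import default_arm_table, _DEFAULT_CHROM_LENGTH

__all__ = [
    "ClinicalAssociations",
    "SimConfig",
    "CohortTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "truth_recovery_report",
    "RecoveryReport",
    "write_cohort",
]

PROMOTER_CHOICES = ("TSS1500", "TSS200", "5'UTR", "1stExon")


@dataclass
class ClinicalAssociations:
    """Per-subgroup covariate distributions (index order = subgroup order).

    Defaults emulate a three-subgroup PanNET-like cohort: T1 mostly
    ATRX/DAXX/MEN1 wild-type and enriched for functional tumours; T2
    ATRX/DAXX-mutant, larger, ALT-positive, longer telomeres, higher
    mutation burden; T3 MEN1-mutant with more G1 tumours and less invasion.
    """

    p_mut_ATRX: tuple = (0.02, 0.25, 0.05)
    p_mut_DAXX: tuple = (0.03, 0.55, 0.10)
    p_mut_MEN1: tuple = (0.10, 0.45, 0.55)
    p_mut_mTOR: tuple = (0.05, 0.25, 0.05)
    p_functional: tuple = (0.30, 0.05, 0.07)
    p_female: tuple = (0.38, 0.38, 0.38)
    p_grade: tuple = ((0.40, 0.58, 0.02), (0.25, 0.72, 0.03), (0.60, 0.39, 0.01))
    p_alt_positive: tuple = (0.05, 0.70, 0.10)
    p_inv_extrapancreatic: tuple = (0.40, 0.50, 0.15)
    p_inv_perineural: tuple = (0.35, 0.45, 0.15)
    p_inv_vascular: tuple = (0.40, 0.50, 0.20)
    size_meanlog: tuple = (3.0, 3.5, 3.0)  # log mm; exp(3.5) ~ 33 mm
    size_sdlog: float = 0.45
    telomere_meanlog: tuple = (-0.10, 0.40, -0.10)
    telomere_sdlog: float = 0.30
    tmb_shape: float = 4.0
    tmb_scale: tuple = (0.18, 0.30, 0.18)  # mean = shape * scale mut/Mb

    def binary_probs(self) -> dict:
        return {
            "mut_ATRX": self.p_mut_ATRX,
            "mut_DAXX": self.p_mut_DAXX,
            "mut_MEN1": self.p_mut_MEN1,
            "mut_mTOR": self.p_mut_mTOR,
            "functional": self.p_functional,
            "inv_extrapancreatic": self.p_inv_extrapancreatic,
            "inv_perineural": self.p_inv_perineural,
            "inv_vascular": self.p_inv_vascular,
        }


def _default_loh_arms() -> dict:
    t2 = [f"{c}{arm}" for c in (1, 2, 3, 6, 8, 10, 11, 15, 16, 21, 22) for arm in "pq"]
    return {"T1": [], "T2": t2, "T3": ["11p", "11q"]}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    The defaults are the conditions the generator is meant to emulate:
    3 subgroups x 30 tumours, 11 normals, bimodal beta modes at 0.1/0.8
    with concentration 50, 200 planted promoter probes per subgroup at a
    group-mean delta beta of 0.4, 5% dichotomized-state flip noise, 47
    tumours with expression data and a target methylation-expression
    correlation magnitude of 0.8.
    """

    n_subgroups: int = 3
    tumours_per_subgroup: int = 30
    n_normals: int = 11
    n_probes: int = 5000
    promoter_fraction: float = 0.40
    dm_probes_per_subgroup: int = 200
    planted_delta_beta: float = 0.4
    beta_low_mean: float = 0.10
    beta_high_mean: float = 0.80
    beta_concentration: float = 50.0
    flip_noise: float = 0.05
    high_background_fraction: float = 0.25
    clinical_assoc: ClinicalAssociations = field(default_factory=ClinicalAssociations)
    loh_arms_per_subgroup: dict = field(default_factory=_default_loh_arms)
    loh_logr: float = -0.3
    n_genes: int = 300
    probes_per_dm_gene: int = 10
    body_probes_per_dm_gene: int = 5
    linked_gene_fraction: float = 0.5
    linkage_r: float = 0.8
    positive_linkage_fraction: float = 0.5
    linkage_amplitude: float = 1.5
    n_rnaseq_samples: int = 47
    library_size_range: tuple = (8_000_000, 12_000_000)
    n_islet_probes: int = 150
    sex_probe_fraction: float = 0.02
    non_cpg_fraction: float = 0.01
    snp_fraction: float = 0.01
    multimap_fraction: float = 0.01
    qc_fail_fraction: float = 0.005
    islet_like_subgroup: str = "T1"
    seed: int = 0

    def validate(self) -> None:
        if self.tumours_per_subgroup < 2:
            raise ValueError("tumours_per_subgroup must be >= 2")
        if not 0 < self.planted_delta_beta < 1:
            raise ValueError("planted_delta_beta must lie in (0, 1)")
        if not 0 <= self.flip_noise <= 1:
            raise ValueError("flip_noise must lie in [0, 1]")
        q = self.planted_delta_beta / (self.beta_high_mean - self.beta_low_mean)
        if not 0 < q <= 1:
            raise ValueError(
                "planted_delta_beta exceeds the beta-mode separation: "
                f"required methylation frequency {q:.2f} not in (0, 1]"
            )
        n_dm_total = self.dm_probes_per_subgroup * self.n_subgroups
        n_body = self.n_dm_genes_per_subgroup * self.body_probes_per_dm_gene * self.n_subgroups
        if n_dm_total + n_body + self.n_islet_probes > self.n_probes:
            raise ValueError(
                f"{n_dm_total} planted promoter + {n_body} planted body + "
                f"{self.n_islet_probes} islet probes exceed n_probes={self.n_probes}"
            )
        if self.n_rnaseq_samples > self.n_subgroups * self.tumours_per_subgroup:
            raise ValueError("n_rnaseq_samples exceeds the tumour count")
        if self.n_dm_genes_per_subgroup * self.n_subgroups > self.n_genes:
            raise ValueError("not enough genes to host the planted DM probes")

    @property
    def methylation_frequency(self) -> float:
        """Per-(gene, sample) probability of the methylated state within the
        target subgroup, chosen so the planted group-mean difference equals
        planted_delta_beta."""
        return self.planted_delta_beta / (self.beta_high_mean - self.beta_low_mean)

    @property
    def n_dm_genes_per_subgroup(self) -> int:
        return int(np.ceil(self.dm_probes_per_subgroup / self.probes_per_dm_gene))

    @property
    def subgroup_names(self) -> list:
        return [f"T{i + 1}" for i in range(self.n_subgroups)]


@dataclass
class CohortTruth:
    """Planted ground truth: labels, DM probe/gene sets, linked genes with
    correlation signs, LOH arm map, and the pre-noise methylation template
    (planted probes x tumours, binary)."""

    labels: pd.Series
    dm_probes: dict  # subgroup -> list of probe ids (promoter + body planted)
    dm_promoter_probes: dict
    dm_genes: dict  # subgroup -> list of gene ids
    linked_genes: pd.DataFrame  # gene, subgroup, sign, target_r
    loh_arms: dict
    islet_probes: list
    methylation_template: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "labels": self.labels.to_dict(),
            "dm_probes": {k: list(v) for k, v in self.dm_probes.items()},
            "dm_promoter_probes": {k: list(v) for k, v in self.dm_promoter_probes.items()},
            "dm_genes": {k: list(v) for k, v in self.dm_genes.items()},
            "linked_genes": self.linked_genes.to_dict(orient="records"),
            "loh_arms": {k: list(v) for k, v in self.loh_arms.items()},
            "islet_probes": list(self.islet_probes),
        }


@dataclass
class SyntheticCohort:
    """All pipeline inputs plus the planted truth."""

    beta: BetaMatrix
    annotation: ProbeAnnotation
    clinical: ClinicalTable
    segments: SegmentTable
    counts: CountMatrix
    islet_reference: pd.DataFrame
    detection_p: pd.DataFrame
    beadcount: pd.DataFrame
    truth: CohortTruth
    config: SimConfig


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    return rng.beta(mean * conc, (1.0 - mean) * conc)


def simulate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate a complete, internally consistent synthetic cohort.

    Same config and seed give bit-identical output.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.subgroup_names
    n_tumours = config.n_subgroups * config.tumours_per_subgroup

    # --- samples -----------------------------------------------------------
    tumour_ids = [f"PT{i + 1:03d}" for i in range(n_tumours)]
    normal_ids = [f"NP{i + 1:02d}" for i in range(config.n_normals)]
    labels = pd.Series(
        np.repeat(names, config.tumours_per_subgroup), index=tumour_ids, name="subgroup"
    )
    roles = pd.Series(
        ["tumour"] * n_tumours + ["normal"] * config.n_normals,
        index=tumour_ids + normal_ids,
    )

    # --- probe & gene layout ----------------------------------------------
    probe_ids = np.array([f"cg{i:08d}" for i in range(config.n_probes)])
    n_dm_genes = config.n_dm_genes_per_subgroup
    gene_ids = np.array([f"GENE{i + 1:04d}" for i in range(config.n_genes)])
    autosomes = [str(c) for c in range(1, 23)]
    gene_chrom = np.array([autosomes[i % 22] for i in range(config.n_genes)])
    # Balance: every subgroup's j-th planted gene sits on the same
    # chromosome, so per-chromosome planted hyper/hypo contributions cancel
    # between any subgroup and the rest (keeps arm LOH uncoupled from
    # aggregate methylation contrasts by construction, not by luck).
    for g in range(config.n_subgroups):
        for j in range(n_dm_genes):
            gene_chrom[g * n_dm_genes + j] = autosomes[j % 22]
    gene_tss = np.empty(config.n_genes, dtype=np.int64)
    for i in range(config.n_genes):
        length = _DEFAULT_CHROM_LENGTH[gene_chrom[i]]
        gene_tss[i] = int(rng.integers(100_000, length - 300_000))
    gene_span = 50_000  # gene body length downstream of the TSS

    # planted DM genes: first n_subgroups * n_dm_genes genes, blockwise
    dm_gene_idx = {
        name: np.arange(g * n_dm_genes, (g + 1) * n_dm_genes)
        for g, name in enumerate(names)
    }

    chrom = np.empty(config.n_probes, dtype=object)
    position = np.zeros(config.n_probes, dtype=np.int64)
    is_cpg = np.ones(config.n_probes, dtype=bool)
    is_snp = np.zeros(config.n_probes, dtype=bool)
    is_multi = np.zeros(config.n_probes, dtype=bool)
    gene_of = np.full(config.n_probes, "", dtype=object)
    region_of = np.full(config.n_probes, "", dtype=object)
    probe_class = np.full(config.n_probes, "low_bg", dtype=object)
    probe_subgroup = np.full(config.n_probes, "", dtype=object)
    # per-probe index of the gene whose methylated state it follows (-1: none)
    state_gene = np.full(config.n_probes, -1, dtype=np.int64)

    cursor = 0

    def _place_on_gene(idx, gi, promoter: bool):
        chrom[idx] = gene_chrom[gi]
        if promoter:
            offset = rng.integers(-1500, 201, size=len(idx))
            region_of[idx] = rng.choice(PROMOTER_CHOICES, size=len(idx))
        else:
            offset = rng.integers(2_000, gene_span + 1, size=len(idx))
            region_of[idx] = "Body"
        position[idx] = gene_tss[gi] + offset
        gene_of[idx] = gene_ids[gi]

    # planted promoter probes
    for name in names:
        for j, gi in enumerate(dm_gene_idx[name]):
            take = min(config.probes_per_dm_gene,
                       config.dm_probes_per_subgroup - j * config.probes_per_dm_gene)
            if take <= 0:
                break
            idx = np.arange(cursor, cursor + take)
            cursor += take
            _place_on_gene(idx, gi, promoter=True)
            probe_class[idx] = "planted_promoter"
            probe_subgroup[idx] = name
            state_gene[idx] = gi
    # planted body probes (shared gene state -> gene-body methylation signal)
    for name in names:
        for gi in dm_gene_idx[name]:
            take = config.body_probes_per_dm_gene
            if take <= 0:
                continue
            idx = np.arange(cursor, cursor + take)
            cursor += take
            _place_on_gene(idx, gi, promoter=False)
            probe_class[idx] = "planted_body"
            probe_subgroup[idx] = name
            state_gene[idx] = gi

    # islet-signature probes: a clonal cell-of-origin signature, methylated
    # in every tumour of the islet-like subgroup and in no other sample;
    # intergenic so they stay out of the promoter cascade and gene contexts
    islet_idx = np.arange(cursor, cursor + config.n_islet_probes)
    cursor += config.n_islet_probes
    if len(islet_idx):
        ichrom = rng.choice(autosomes, size=len(islet_idx))
        chrom[islet_idx] = ichrom
        for j, i in enumerate(islet_idx):
            position[i] = int(rng.integers(1, _DEFAULT_CHROM_LENGTH[ichrom[j]]))
        probe_class[islet_idx] = "islet_sig"

    # background probes: assign genes/regions and flags
    rest = np.arange(cursor, config.n_probes)
    n_rest = len(rest)
    non_dm_genes = np.arange(config.n_subgroups * n_dm_genes, config.n_genes)
    u = rng.random(n_rest)
    promoter_bg = rest[u < config.promoter_fraction]
    body_bg = rest[(u >= config.promoter_fraction) & (u < config.promoter_fraction + 0.35)]
    intergenic = rest[u >= config.promoter_fraction + 0.35]
    for idx_set, promoter in ((promoter_bg, True), (body_bg, False)):
        gis = rng.choice(non_dm_genes, size=len(idx_set), replace=True)
        for j, i in enumerate(idx_set):
            _place_on_gene(np.array([i]), gis[j], promoter=promoter)
    ig_chrom = rng.choice(autosomes, size=len(intergenic))
    for j, i in enumerate(intergenic):
        chrom[i] = ig_chrom[j]
        position[i] = int(rng.integers(1, _DEFAULT_CHROM_LENGTH[ig_chrom[j]]))

    # high-background (methylated everywhere, incl. normals) among background
    v = rng.random(n_rest)
    probe_class[rest[v < config.high_background_fraction]] = "high_bg"

    # QC flags only on background probes (planted probes stay clean so the
    # planted design is what the cascade sees)
    w = rng.random(n_rest)
    edges = np.cumsum([config.sex_probe_fraction, config.non_cpg_fraction,
                       config.snp_fraction, config.multimap_fraction])
    sex_idx = rest[w < edges[0]]
    chrom[sex_idx] = rng.choice(["X", "Y"], size=len(sex_idx))
    gene_of[sex_idx] = ""
    region_of[sex_idx] = ""
    state_gene[sex_idx] = -1
    is_cpg[rest[(w >= edges[0]) & (w < edges[1])]] = False
    is_snp[rest[(w >= edges[1]) & (w < edges[2])]] = True
    is_multi[rest[(w >= edges[2]) & (w < edges[3])]] = True

    probes_df = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": position,
            "is_cpg": is_cpg,
            "is_snp_masked": is_snp,
            "is_multimap": is_multi,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    has_gene = gene_of != ""
    gene_map = pd.DataFrame({
        "probe_id": probe_ids[has_gene],
        "gene": gene_of[has_gene],
        "region": region_of[has_gene],
    })
    annotation = ProbeAnnotation(probes_df, gene_map)

    # --- clinical ----------------------------------------------------------
    assoc = config.clinical_assoc
    sub_idx = labels.map({name: i for i, name in enumerate(names)}).to_numpy()
    clin = pd.DataFrame(index=pd.Index(tumour_ids, name="sample_id"))
    clin["sex"] = np.where(
        rng.random(n_tumours) < np.take(assoc.p_female, sub_idx), "F", "M"
    )
    grade_levels = np.array(["G1", "G2", "G3"])
    grades = np.empty(n_tumours, dtype=object)
    for i in range(n_tumours):
        grades[i] = rng.choice(grade_levels, p=np.asarray(assoc.p_grade[sub_idx[i]]))
    clin["grade"] = grades
    for colname, probs in assoc.binary_probs().items():
        clin[colname] = rng.random(n_tumours) < np.take(probs, sub_idx)
    clin["tumour_size"] = np.exp(
        rng.normal(np.take(assoc.size_meanlog, sub_idx), assoc.size_sdlog)
    )
    clin["telomere_ratio"] = np.exp(
        rng.normal(np.take(assoc.telomere_meanlog, sub_idx), assoc.telomere_sdlog)
    )
    clin["alt_status"] = np.where(
        rng.random(n_tumours) < np.take(assoc.p_alt_positive, sub_idx),
        "positive", "negative",
    )
    clin["tmb"] = rng.gamma(assoc.tmb_shape, np.take(assoc.tmb_scale, sub_idx))
    for col in ("functional", "mut_ATRX", "mut_DAXX", "mut_MEN1", "mut_mTOR",
                "inv_extrapancreatic", "inv_perineural", "inv_vascular"):
        clin[col] = clin[col].astype("boolean")
    clinical = ClinicalTable(clin)

    # --- methylation -------------------------------------------------------
    q = config.methylation_frequency
    # gene methylated-state matrix for DM genes (gene x tumour)
    all_dm_gis = np.concatenate([dm_gene_idx[name] for name in names])
    gene_state = np.zeros((config.n_genes, n_tumours), dtype=np.int8)
    for name in names:
        cols = (labels == name).to_numpy()
        gis = dm_gene_idx[name]
        gene_state[np.ix_(gis, cols)] = (
            rng.random((len(gis), int(cols.sum()))) < q
        ).astype(np.int8)

    low, high = config.beta_low_mean, config.beta_high_mean
    mean_t = np.full((config.n_probes, n_tumours), low)
    planted = state_gene >= 0
    mean_t[planted] = np.where(gene_state[state_gene[planted]] == 1, high, low)
    mean_t[probe_class == "high_bg"] = high
    islet_cols = (labels == config.islet_like_subgroup).to_numpy()
    mean_t[np.ix_(probe_class == "islet_sig", islet_cols)] = high
    template = (mean_t >= 0.5).astype(np.int8)  # pre-noise methylation states

    if config.flip_noise > 0:
        flip = rng.random((config.n_probes, n_tumours)) < config.flip_noise
        mean_t = np.where(flip, low + high - mean_t, mean_t)

    mean_n = np.full((config.n_probes, config.n_normals), low)
    mean_n[probe_class == "high_bg"] = high

    beta_t = _beta_draw(rng, mean_t, config.beta_concentration)
    beta_n = _beta_draw(rng, mean_n, config.beta_concentration)
    beta_values = pd.DataFrame(
        np.concatenate([beta_t, beta_n], axis=1),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=tumour_ids + normal_ids,
    )
    beta = BetaMatrix(beta_values, roles)

    # --- QC matrices -------------------------------------------------------
    n_all = n_tumours + config.n_normals
    detection_p = pd.DataFrame(
        rng.uniform(0.0, 0.005, size=(config.n_probes, n_all)),
        index=beta_values.index, columns=beta_values.columns,
    )
    beadcount = pd.DataFrame(
        rng.integers(5, 25, size=(config.n_probes, n_all)),
        index=beta_values.index, columns=beta_values.columns,
    )
    # a small set of background probes fails detection-p or beadcount in
    # 10% of samples (>= the 5%-of-samples rule)
    z = rng.random(n_rest)
    fail_det = rest[z < config.qc_fail_fraction / 2]
    fail_bead = rest[(z >= config.qc_fail_fraction / 2) & (z < config.qc_fail_fraction)]
    n_fail_samples = max(1, int(np.ceil(0.10 * n_all)))
    for i in fail_det:
        cols = rng.choice(n_all, size=n_fail_samples, replace=False)
        detection_p.iloc[i, cols] = 0.05
    for i in fail_bead:
        cols = rng.choice(n_all, size=n_fail_samples, replace=False)
        beadcount.iloc[i, cols] = 1

    # --- segments (LOH uncoupled from methylation by design) ---------------
    arms = default_arm_table().set_index("arm")
    seg_rows = []
    for sample in tumour_ids:
        loh_set = set(config.loh_arms_per_subgroup.get(labels[sample], []))
        for arm, row in arms.iterrows():
            loh = arm in loh_set
            logr = (config.loh_logr if loh else 0.0) + rng.normal(0.0, 0.02)
            seg_rows.append((sample, row["chrom"], row["start"], row["end"], loh, logr))
    segments = SegmentTable(pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "loh", "logr"]
    ))

    # --- expression --------------------------------------------------------
    rna_samples = sorted(rng.choice(tumour_ids, size=config.n_rnaseq_samples,
                                    replace=False).tolist())
    n_linked = int(round(config.linked_gene_fraction * len(all_dm_gis)))
    linked_gis = rng.choice(all_dm_gis, size=n_linked, replace=False)
    signs = np.where(rng.random(n_linked) < config.positive_linkage_fraction, 1, -1)
    base_log2cpm = rng.uniform(3.0, 9.0, size=config.n_genes)
    noise = rng.normal(0.0, 1.0, size=(config.n_genes, len(rna_samples)))

    rna_cols = [tumour_ids.index(s) for s in rna_samples]
    log2cpm = np.empty((config.n_genes, len(rna_samples)))
    r = config.linkage_r
    linked_rows = []
    gi_to_sub = {}
    for name in names:
        for gi in dm_gene_idx[name]:
            gi_to_sub[gi] = name
    for g in range(config.n_genes):
        eps = noise[g]
        if g in set(linked_gis):
            sign = int(signs[list(linked_gis).index(g)])
            # gene methylation across RNA samples: mean beta of the gene's
            # planted probes follows the gene state
            probes_g = np.where(state_gene == g)[0]
            m = beta_t[np.ix_(probes_g, rna_cols)].mean(axis=0)
            sd = m.std()
            z_m = (m - m.mean()) / sd if sd > 0 else np.zeros_like(m)
            y = sign * r * z_m + np.sqrt(1 - r ** 2) * eps
            linked_rows.append({"gene": gene_ids[g], "subgroup": gi_to_sub[g],
                                "sign": sign, "target_r": sign * r})
        else:
            y = eps
        log2cpm[g] = base_log2cpm[g] + config.linkage_amplitude * y
    lib = rng.integers(config.library_size_range[0], config.library_size_range[1] + 1,
                       size=len(rna_samples))
    expected = (2.0 ** log2cpm) / 1e6 * lib[None, :]
    counts = CountMatrix(pd.DataFrame(
        rng.poisson(expected).astype(np.int64),
        index=pd.Index(gene_ids, name="gene_id"), columns=rna_samples,
    ))

    # --- islet reference ----------------------------------------------------
    # alpha-like profile = the background tumour profile; the beta-like
    # profile is additionally methylated on the clonal islet-signature
    # probes, so those (|diff| = high - low > 0.3) form the signature set.
    alpha_profile = np.full(config.n_probes, low)
    alpha_profile[probe_class == "high_bg"] = high
    beta_profile = alpha_profile.copy()
    beta_profile[probe_class == "islet_sig"] = high
    islet_reference = pd.DataFrame(
        {"alpha": alpha_profile, "beta_like": beta_profile},
        index=beta_values.index,
    )

    # --- truth --------------------------------------------------------------
    dm_probes = {
        name: probe_ids[(probe_subgroup == name) & planted].tolist() for name in names
    }
    dm_promoter = {
        name: probe_ids[(probe_subgroup == name) & (probe_class == "planted_promoter")].tolist()
        for name in names
    }
    dm_genes = {name: gene_ids[dm_gene_idx[name]].tolist() for name in names}
    truth = CohortTruth(
        labels=labels,
        dm_probes=dm_probes,
        dm_promoter_probes=dm_promoter,
        dm_genes=dm_genes,
        linked_genes=pd.DataFrame(linked_rows,
                                  columns=["gene", "subgroup", "sign", "target_r"]),
        loh_arms=dict(config.loh_arms_per_subgroup),
        islet_probes=probe_ids[probe_class == "islet_sig"].tolist(),
        methylation_template=pd.DataFrame(
            template[planted], index=pd.Index(probe_ids[planted], name="probe_id"),
            columns=tumour_ids,
        ),
    )
    return SyntheticCohort(
        beta=beta,
        annotation=annotation,
        clinical=clinical,
        segments=segments,
        counts=counts,
        islet_reference=islet_reference,
        detection_p=detection_p,
        beadcount=beadcount,
        truth=truth,
        config=config,
    )


@dataclass
class RecoveryReport:
    """Agreement between an assignment and the planted labels."""

    ari: float
    confusion: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"adjusted Rand index {self.ari:.3f}\n{self.confusion}"


def truth_recovery_report(cohort: SyntheticCohort, assignment) -> RecoveryReport:
    """Adjusted Rand index and confusion table between an assignment's
    labels and the planted subgroup labels.  The assignment must cover every
    tumour sample."""
    from sklearn.metrics import adjusted_rand_score

    labels = assignment.labels if hasattr(assignment, "labels") else pd.Series(assignment)
    truth = cohort.truth.labels
    missing = truth.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"assignment missing tumour samples: {list(missing)[:5]}")
    pred = labels.loc[truth.index]
    ari = float(adjusted_rand_score(truth.to_numpy(), pred.to_numpy()))
    confusion = pd.crosstab(truth, pred, rownames=["truth"], colnames=["assigned"])
    return RecoveryReport(ari=ari, confusion=confusion)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write every input file in the pipeline dialects plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(cohort.beta, out / "beta.tsv")
    write_probe_annotation(cohort.annotation, out / "annotation.csv")
    write_clinical_table(cohort.clinical, out / "clinical.tsv")
    write_segments(cohort.segments, out / "segments.tsv")
    write_counts(cohort.counts, out / "counts.tsv")
    cohort.islet_reference.to_csv(out / "islet_reference.tsv", sep="\t",
                                  index_label="probe_id")
    cohort.detection_p.to_csv(out / "detection_p.tsv", sep="\t", index_label="probe_id")
    cohort.beadcount.to_csv(out / "beadcount.tsv", sep="\t", index_label="probe_id")
    cohort.beta.sample_role.rename("role").to_csv(out / "roles.tsv", sep="\t",
                                                  index_label="sample_id")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_json_dict(), fh, indent=1)
    with open(out / "config.json", "w") as fh:
        cfg = dataclasses.asdict(cohort.config)
        cfg["clinical_assoc"] = dataclasses.asdict(cohort.config.clinical_assoc)
        json.dump(cfg, fh, indent=1, default=str)
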