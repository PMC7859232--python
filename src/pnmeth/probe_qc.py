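"""Probe-level quality-control filters producing the analysis probe set.

Rules (all conjunctive, so the retained set is order-independent; the
report attributes each removed probe to the FIRST applicable rule in the
documented order): detection p-value, beadcount, non-CpG, sex chromosome,
SNP-masked, multi-mapping.  By default the "in at least 5% of samples"
scoping applies symmetrically to both the detection-p and the beadcount
criterion; ``any_sample=True`` removes a probe as soon as a single sample
fails either.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import BetaMatrix, ProbeAnnotation

__all__ = ["QCConfig", "FilterReport", "apply_probe_filters", "drop_incomplete_probes"]

logger = logging.getLogger(__name__)

RULE_ORDER = [
    "detection_p",
    "beadcount",
    "non_cpg",
    "sex_chromosome",
    "snp_masked",
    "multimap",
]


@dataclass
class QCConfig:
    detection_p_threshold: float = 0.01
    min_beads: int = 3
    sample_fraction: float = 0.05
    any_sample: bool = False
    drop_non_cpg: bool = True
    drop_sex_chromosomes: bool = True
    drop_snp_masked: bool = True
    drop_multimap: bool = True

    def __post_init__(self) -> None:
        if self.detection_p_threshold <= 0 or self.min_beads <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class FilterReport:
    """Per-rule removed counts, rule order, and the retained probe list."""

    n_input: int
    removed_counts: "OrderedDict[str, int]" = field(default_factory=OrderedDict)
    removed_ids: dict = field(default_factory=dict)
    retained: pd.Index | None = None
    rule_order: list = field(default_factory=lambda: list(RULE_ORDER))
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_counts": dict(self.removed_counts),
            "n_retained": len(self.retained) if self.retained is not None else 0,
            "rule_order": self.rule_order,
            "skipped_rules": self.skipped,
        }


def _check_ids(beta: BetaMatrix, other: pd.DataFrame, name: str) -> None:
    if not beta.probe_ids.equals(other.index) or not beta.sample_ids.equals(other.columns):
        raise ValueError(f"{name} matrix probe/sample ids do not match beta matrix")


def apply_probe_filters(
    beta: BetaMatrix,
    detection_p: pd.DataFrame | None = None,
    beadcount: pd.DataFrame | None = None,
    annotation: ProbeAnnotation | None = None,
    config: QCConfig | None = None,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the probe exclusion rules; returns the retained matrix and an
    itemized report.  Rules whose inputs are absent are skipped and logged."""
    config = config or QCConfig()
    report = FilterReport(n_input=len(beta.probe_ids))
    n_samples = len(beta.sample_ids)
    min_fail = 1 if config.any_sample else max(
        1, math.ceil(config.sample_fraction * n_samples)
    )

    fail_sets: "OrderedDict[str, set]" = OrderedDict()

    if detection_p is not None:
        _check_ids(beta, detection_p, "detection p")
        n_fail = (detection_p > config.detection_p_threshold).sum(axis=1)
        fail_sets["detection_p"] = set(beta.probe_ids[(n_fail >= min_fail).to_numpy()])
    else:
        report.skipped.append("detection_p")
        logger.info("detection-p matrix absent: rule skipped")

    if beadcount is not None:
        _check_ids(beta, beadcount, "beadcount")
        n_fail = (beadcount < config.min_beads).sum(axis=1)
        fail_sets["beadcount"] = set(beta.probe_ids[(n_fail >= min_fail).to_numpy()])
    else:
        report.skipped.append("beadcount")
        logger.info("beadcount matrix absent: rule skipped")

    if annotation is not None:
        annot = annotation.probes.reindex(beta.probe_ids)
        if annot["position"].isna().any():
            missing = beta.probe_ids[annot["position"].isna()][:5].tolist()
            raise ValueError(f"probes missing from annotation: {missing}")
        if config.drop_non_cpg:
            fail_sets["non_cpg"] = set(beta.probe_ids[~annot["is_cpg"].astype(bool)])
        if config.drop_sex_chromosomes:
            on_sex = annot["chromosome"].astype(str).isin(["X", "Y"])
            fail_sets["sex_chromosome"] = set(beta.probe_ids[on_sex.to_numpy()])
        if config.drop_snp_masked:
            fail_sets["snp_masked"] = set(beta.probe_ids[annot["is_snp_masked"].astype(bool)])
        if config.drop_multimap:
            fail_sets["multimap"] = set(beta.probe_ids[annot["is_multimap"].astype(bool)])
    else:
        skipped = [r for r in RULE_ORDER[2:]]
        report.skipped.extend(skipped)
        logger.info("annotation absent: rules %s skipped", skipped)

    removed_so_far: set = set()
    for rule in RULE_ORDER:
        if rule not in fail_sets:
            continue
        newly = fail_sets[rule] - removed_so_far
        report.removed_counts[rule] = len(newly)
        report.removed_ids[rule] = newly
        removed_so_far |= newly

    retained = beta.probe_ids[~beta.probe_ids.isin(removed_so_far)]
    report.retained = retained
    if len(retained) == 0:
        raise ValueError("all probes removed by QC filters")
    return beta.subset_probes(retained), report


def drop_incomplete_probes(beta: BetaMatrix) -> BetaMatrix:
    """Remove probes with any missing beta value; downstream statistics
    assume complete rows."""
    complete = beta.values.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d probes with missing values", n_dropped)
    return beta.subset_probes(beta.probe_ids[complete.to_numpy()])
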