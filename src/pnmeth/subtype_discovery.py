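"""Methylation subtype discovery.

The subtyping procedure selects promoter CpG probes that are unmethylated
(beta < 0.3) in every normal sample and variable (SD > 0.20) across tumours,
dichotomizes their beta-values at 0.3 into methylation presence/absence, and
clusters tumours on the asymmetric-binary (Jaccard) distance with Ward
linkage.

The Ward agglomeration is implemented here (naive O(n^3) Lance-Williams,
fine for cohort-scale n) so that the variant (ward.D2 on distances, or the
classic ward.D update applied to the distances directly) and the tie-break
(lexicographically smallest cluster-id pair among equal merge costs) are
explicit and deterministic across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ProbeAnnotation

__all__ = [
    "BinaryMatrix",
    "SubtypeAssignment",
    "SelectionTrace",
    "SubtypeConfig",
    "select_unmethylated_in_normals",
    "select_promoter_probes",
    "select_variable_probes",
    "dichotomize",
    "binary_distance_matrix",
    "ward_cluster",
    "run_subtyping",
    "silhouette_scan",
    "merges_to_newick",
]


@dataclass
class BinaryMatrix:
    """Dichotomized methylation states (1 = presence, beta >= cut)."""

    values: pd.DataFrame  # probes x samples, int8 in {0, 1}
    cut: float = 0.3

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class SubtypeAssignment:
    """Sample -> subgroup labels plus the merge history that produced them.

    ``merges`` follows the scipy convention: leaves are cluster ids
    ``0..n-1`` in input sample order; merge ``i`` creates cluster ``n+i``
    from ``(left, right)`` at ``height``.
    """

    labels: pd.Series
    merges: list  # [(left_id, right_id, height), ...]
    k: int
    leaf_order: list  # sample ids in dendrogram left-to-right order

    def label_of(self, sample_id) -> str:
        return self.labels.loc[sample_id]


@dataclass
class SelectionTrace:
    """Probe counts after each cascade step (non-increasing)."""

    counts: dict = field(default_factory=dict)
    retained: pd.Index | None = None


@dataclass
class SubtypeConfig:
    k: int = 3
    normal_threshold: float = 0.3
    sd_threshold: float = 0.20
    beta_cut: float = 0.3
    genome_wide: bool = False
    ward_variant: str = "ward.D2"  # or "ward.D"


# ---------------------------------------------------------------------------
# Probe-selection cascade
# ---------------------------------------------------------------------------

def select_unmethylated_in_normals(beta: BetaMatrix, threshold: float = 0.3) -> pd.Index:
    """Probes with beta strictly below ``threshold`` in EVERY normal sample."""
    normals = beta.normal_values()
    if normals.shape[1] == 0:
        raise ValueError("no normal samples in matrix")
    keep = (normals < threshold).all(axis=1) & normals.notna().all(axis=1)
    return beta.probe_ids[keep.to_numpy()]


def select_promoter_probes(annotation: ProbeAnnotation) -> pd.Index:
    """Probes with any (gene, region) pair in TSS1500/TSS200/5'UTR/1stExon."""
    return annotation.promoter_probes()


def select_variable_probes(
    beta: BetaMatrix,
    sd_threshold: float = 0.20,
    inclusive: bool = False,
) -> pd.Index:
    """Probes whose tumour beta sample SD (n-1 denominator) exceeds the
    threshold; the boundary is excluded (strict ``>``) unless
    ``inclusive=True``."""
    tumours = beta.tumour_values()
    if tumours.shape[1] < 2:
        raise ValueError("need >=2 tumour samples for an SD")
    sd = tumours.std(axis=1, ddof=1)
    keep = (sd >= sd_threshold) if inclusive else (sd > sd_threshold)
    return beta.probe_ids[keep.to_numpy()]


def dichotomize(values: pd.DataFrame | BetaMatrix, cut: float = 0.3) -> BinaryMatrix:
    """Threshold beta at ``cut``: state 1 iff beta >= cut (boundary is
    presence).  Missing values are an error — run ``drop_incomplete_probes``
    first."""
    df = values.values if isinstance(values, BetaMatrix) else values
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing beta values (e.g. probes {bad}); "
                         "drop incomplete probes before dichotomizing")
    return BinaryMatrix((df >= cut).astype(np.int8), cut=cut)


# ---------------------------------------------------------------------------
# Binary distance
# ---------------------------------------------------------------------------

def binary_distance_matrix(bm: BinaryMatrix) -> pd.DataFrame:
    """Asymmetric-binary (Jaccard) sample-sample distances.

    For samples x, y with a = #probes present in both, b + c = #discordant:
    d = (b + c) / (a + b + c); joint absence is ignored.  Pairs with
    a + b + c = 0 (both all-absent) get distance 0 with a warning so
    clustering stays total.
    """
    X = bm.values.to_numpy(dtype=np.int64)
    if X.shape[1] < 2:
        raise ValueError("need >=2 samples")
    ones = X.sum(axis=0)
    a = X.T @ X
    denom = ones[:, None] + ones[None, :] - a  # a + b + c
    disc = denom - a  # b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, disc / np.where(denom == 0, 1, denom), 0.0)
    degenerate = denom == 0
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        warnings.warn("all-absent sample pair(s): distance defined as 0")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=bm.sample_ids, columns=bm.sample_ids)


# ---------------------------------------------------------------------------
# Ward agglomeration
# ---------------------------------------------------------------------------

def ward_cluster(distances: pd.DataFrame, k: int, variant: str = "ward.D2") -> SubtypeAssignment:
    """Agglomerative Ward clustering on a precomputed distance matrix.

    ``ward.D2`` (default) applies the Lance-Williams Ward update to squared
    distances and reports sqrt heights, treating the input distances as
    Euclidean; ``ward.D`` applies the update to the distances as given.
    Ties in merge cost are broken toward the lexicographically smallest
    (cluster-id) pair.  Labels ``T1..Tk`` are assigned by cutting the tree at
    ``k`` clusters and numbering them in dendrogram left-to-right order.
    """
    n = distances.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    if variant not in ("ward.D2", "ward.D"):
        raise ValueError(f"unknown Ward variant {variant!r}")
    D = distances.to_numpy(dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    # Working matrix over cluster ids 0..2n-2 (scipy id convention).
    total = 2 * n - 1
    W = np.full((total, total), np.inf)
    work = D ** 2 if variant == "ward.D2" else D.copy()
    W[:n, :n] = work
    sizes = np.zeros(total, dtype=np.int64)
    sizes[:n] = 1
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        # lexicographically smallest argmin over active pairs
        best = np.inf
        bi = bj = -1
        for ii in range(len(active)):
            i = active[ii]
            row = W[i]
            for jj in range(ii + 1, len(active)):
                j = active[jj]
                if row[j] < best:
                    best = row[j]
                    bi, bj = i, j
        new = n + step
        height = float(np.sqrt(best)) if variant == "ward.D2" else float(best)
        merges.append((bi, bj, height))
        ni, nj = sizes[bi], sizes[bj]
        for m in active:
            if m in (bi, bj):
                continue
            nm = sizes[m]
            upd = ((ni + nm) * W[bi, m] + (nj + nm) * W[bj, m] - nm * best) / (ni + nj + nm)
            W[new, m] = W[m, new] = upd
        sizes[new] = ni + nj
        active.remove(bi)
        active.remove(bj)
        active.append(new)

    leaf_order_idx = _leaf_order(merges, n)
    labels = _cut_tree(merges, n, k, leaf_order_idx)
    sample_ids = distances.index
    return SubtypeAssignment(
        labels=pd.Series(labels, index=sample_ids, name="subgroup"),
        merges=merges,
        k=k,
        leaf_order=[sample_ids[i] for i in leaf_order_idx],
    )


def _children(merges: Sequence, n: int, node: int) -> tuple[int, int] | None:
    if node < n:
        return None
    left, right, _ = merges[node - n]
    return left, right


def _leaf_order(merges: Sequence, n: int) -> list[int]:
    """Left-to-right leaf indices by depth-first traversal (left child =
    first member of each recorded merge)."""
    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        kids = _children(merges, n, node)
        if kids is None:
            order.append(node)
        else:
            left, right = kids
            stack.append(right)
            stack.append(left)
    return order


def _cut_tree(merges: Sequence, n: int, k: int, leaf_order_idx: Sequence[int]) -> list[str]:
    """Cut after n-k merges; number clusters T1..Tk by leaf order."""
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        left, right, _ = merges[step]
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new

    label_by_root: dict[int, str] = {}
    for leaf in leaf_order_idx:
        root = find(leaf)
        if root not in label_by_root:
            label_by_root[root] = f"T{len(label_by_root) + 1}"
    return [label_by_root[find(i)] for i in range(n)]


def merges_to_newick(assignment: SubtypeAssignment) -> str:
    """Render the merge history as a Newick string (branch lengths are merge
    heights)."""
    n = len(assignment.labels)
    names = list(assignment.labels.index)

    def render(node: int) -> str:
        if node < n:
            return str(names[node])
        left, right, h = assignment.merges[node - n]
        return f"({render(left)},{render(right)}):{h:g}"

    return render(2 * n - 2) + ";"


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_subtyping(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    config: SubtypeConfig | None = None,
) -> tuple[SubtypeAssignment, SelectionTrace, BinaryMatrix]:
    """Execute the full subtyping cascade on a QC'd, complete beta matrix.

    Steps: unmethylated-in-all-normals -> promoter membership (skipped in
    genome-wide mode) -> tumour SD > threshold -> dichotomize at 0.3 ->
    binary distance -> Ward clustering cut at ``k``.  Clustering runs over
    tumour samples only.
    """
    config = config or SubtypeConfig()
    trace = SelectionTrace()
    probes = beta.probe_ids
    trace.counts["input"] = len(probes)

    unmeth = select_unmethylated_in_normals(beta, config.normal_threshold)
    probes = probes.intersection(unmeth)
    trace.counts["unmethylated_in_normals"] = len(probes)

    if not config.genome_wide:
        probes = probes.intersection(select_promoter_probes(annotation))
    trace.counts["promoter"] = len(probes)

    variable = select_variable_probes(beta, config.sd_threshold)
    probes = probes.intersection(variable)
    trace.counts["variable"] = len(probes)
    # preserve matrix row order for determinism
    probes = beta.probe_ids[beta.probe_ids.isin(probes)]
    trace.retained = probes

    if len(probes) == 0:
        raise ValueError(f"probe cascade left no probes (trace: {trace.counts})")

    selected = beta.subset_probes(probes)
    bm = dichotomize(selected.tumour_values(), config.beta_cut)
    dist = binary_distance_matrix(bm)
    assignment = ward_cluster(dist, config.k, config.ward_variant)
    return assignment, trace, bm


def silhouette_scan(distances: pd.DataFrame, k_range: Sequence[int] = range(2, 7),
                    variant: str = "ward.D2") -> pd.Series:
    """Mean silhouette width of the Ward partition for each candidate k.

    A report to support choosing k; never an automatic override of the
    configured k.
    """
    from sklearn.metrics import silhouette_score

    scores = {}
    for k in k_range:
        labels = ward_cluster(distances, k, variant).labels
        scores[k] = float(
            silhouette_score(distances.to_numpy(), labels.to_numpy(), metric="precomputed")
        )
    return pd.Series(scores, name="silhouette")
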