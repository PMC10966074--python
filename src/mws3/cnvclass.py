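"""Pseudobulk CNV estimation and iterative malignant-cell classification.

The workflow mirrors how large copy-number events are read out of sparse
single-nucleus expression data:

1.  Cells are grouped by sample x cell type and, within each group, Ward
    hierarchical clustering on Euclidean distances cuts them into a preset
    number of pseudobulks; pseudobulk profiles are the cumulative sums of
    their member cells, normalized to a common total
    (``build_pseudobulks``).
2.  A windowed relative-expression estimator turns each pseudobulk into a
    per-gene CNV track: log2 ratio against the mean of reference
    pseudobulks, smoothed by a centered moving average along each
    chromosome, then scaled into [-1, 1] (``estimate_cnv_windowed``).
    Externally produced region x pseudobulk CNV matrices can be imported
    instead (``read_cnv_matrix``), keeping the classifier tool-agnostic.
3.  Each pseudobulk gets a CNV score: the quadratic sum of its scaled
    region (cytoband) values (``cnv_score``).
4.  Tissue-level expectations anchor the decision: the mean score of
    tumor-adjacent pseudobulks ("normal expectation") and of tumor
    pseudobulks ("malignant expectation"), after one round of outlier
    removal (``compute_expectations``).
5.  Pseudobulks are hierarchically clustered into k clusters; clusters with
    mean score <= normal expectation become normal, >= malignant
    expectation become malignant, and the rest are re-clustered recursively
    until nothing new resolves or the recursion cap is reached
    (``iterative_classify``).  Cells inherit their pseudobulk's label
    (``propagate_to_cells``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pseudobulks
# ---------------------------------------------------------------------------


@dataclass
class PseudobulkSet:
    """Aggregated profiles: ``profiles`` normalized, ``raw_profiles`` exact
    member-cell column sums; ``members`` maps pseudobulk -> member cells."""

    profiles: pd.DataFrame
    raw_profiles: pd.DataFrame
    members: dict
    groups: pd.Series
    normalization_total: float
    dropped_groups: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for pb, cells in self.members.items():
            dup = seen & set(cells)
            if dup:
                raise ValueError(f"cells {sorted(dup)[:3]} belong to several pseudobulks")
            seen |= set(cells)


def _cut_tree(X: np.ndarray, n_clusters: int, method: str) -> np.ndarray:
    """Cluster rows of X into exactly ``n_clusters`` flat clusters."""
    n = X.shape[0]
    if n_clusters >= n:
        return np.arange(n)
    if n_clusters == 1:
        return np.zeros(n, dtype=int)
    Z = sch.linkage(X, method=method)
    return sch.fcluster(Z, t=n_clusters, criterion="maxclust") - 1


def build_pseudobulks(
    matrix: pd.DataFrame,
    groups: pd.Series,
    n_per_group: Mapping[str, int],
    normalization_total: float = 1e7,
    linkage_method: str = "ward",
    log_transform: bool = True,
) -> PseudobulkSet:
    """Cluster cells of each group into pseudobulks and sum their counts.

    ``matrix`` is genes x cells; ``groups`` maps cell -> group (sample x
    cell type).  Groups with fewer cells than their requested pseudobulk
    count are dropped and recorded.  Clustering operates on log2(1 + x)
    values by default (variance stabilization); profiles are summed from
    the untransformed matrix and normalized so each pseudobulk totals
    ``normalization_total``.
    """
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    for g, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"n_per_group[{g!r}] must be >= 1")
    raw_cols, members, pb_groups = {}, {}, {}
    dropped = []
    for group, n in n_per_group.items():
        cells = groups.index[groups == group]
        cells = [c for c in cells if c in matrix.columns]
        if len(cells) < n:
            dropped.append({"group": group, "cells": len(cells), "requested": n})
            logger.info("group %s dropped: %d cells < %d pseudobulks", group, len(cells), n)
            continue
        X = matrix[cells].to_numpy().T
        if log_transform:
            X = np.log2(1.0 + X)
        assignment = _cut_tree(X, n, linkage_method)
        for cl in range(assignment.max() + 1):
            idx = [cells[i] for i in np.nonzero(assignment == cl)[0]]
            if not idx:
                continue
            pb = f"{group}.pb{cl:03d}"
            raw_cols[pb] = matrix[idx].to_numpy().sum(axis=1)
            members[pb] = idx
            pb_groups[pb] = group
    if not raw_cols:
        raise ValueError("no group had enough cells to build pseudobulks")
    raw = pd.DataFrame(raw_cols, index=matrix.index)
    totals = raw.sum(axis=0)
    profiles = raw * (normalization_total / totals)
    return PseudobulkSet(
        profiles=profiles,
        raw_profiles=raw,
        members=members,
        groups=pd.Series(pb_groups, name="group"),
        normalization_total=normalization_total,
        dropped_groups=dropped,
    )


# ---------------------------------------------------------------------------
# Windowed CNV estimation
# ---------------------------------------------------------------------------


@dataclass
class CnvMatrix:
    """Scaled CNV values (genes x pseudobulks) with genomic metadata."""

    values: pd.DataFrame
    gene_meta: pd.DataFrame
    scale_range: tuple = (-1.0, 1.0)
    prescale_max_abs: float = 1.0

    def __post_init__(self):
        lo, hi = self.scale_range
        v = self.values.to_numpy()
        if v.size and (v.min() < lo - 1e-9 or v.max() > hi + 1e-9):
            raise ValueError("values outside scale_range")


def estimate_cnv_windowed(
    expression: pd.DataFrame,
    gene_meta: pd.DataFrame,
    reference: Sequence[str],
    window: int = 101,
    pseudocount: float = 1.0,
) -> CnvMatrix:
    """Windowed relative-expression CNV estimate against a reference.

    Genes are ordered along the genome; each pseudobulk's log2 ratio to the
    reference mean is smoothed by a centered moving average of ``window``
    genes within each chromosome (edges use the available span), then the
    whole matrix is scaled into [-1, 1] by its maximum absolute value so
    that zero stays neutral.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    missing = [r for r in reference if r not in expression.columns]
    if not list(reference) or missing:
        raise ValueError(f"reference pseudobulks missing from matrix: {missing}")
    meta = gene_meta.loc[expression.index].sort_values(["chrom", "start"], kind="stable")
    expr = expression.loc[meta.index]
    ref_mean = expr[list(reference)].mean(axis=1)
    log_ratio = np.log2((expr.add(pseudocount, axis=0)).div(ref_mean + pseudocount, axis=0))
    smoothed = log_ratio.groupby(meta["chrom"], sort=False, group_keys=False).apply(
        lambda df: df.rolling(window, center=True, min_periods=1).mean()
    )
    smoothed = smoothed.loc[meta.index]
    max_abs = float(np.abs(smoothed.to_numpy()).max()) if smoothed.size else 0.0
    scaled = smoothed / max_abs if max_abs > 0 else smoothed
    return CnvMatrix(values=scaled, gene_meta=meta, prescale_max_abs=max_abs)


def aggregate_cytobands(cnv: CnvMatrix) -> pd.DataFrame:
    """Mean scaled CNV value per cytoband (regions x pseudobulks),
    genome-ordered."""
    if "cytoband" not in cnv.gene_meta.columns:
        raise ValueError("gene metadata lacks a cytoband column")
    bands = cnv.gene_meta["cytoband"]
    order = bands.drop_duplicates().tolist()
    out = cnv.values.groupby(bands, sort=False).mean()
    return out.loc[order]


def read_cnv_matrix(path) -> pd.DataFrame:
    """Import an externally produced region x pseudobulk CNV matrix (TSV,
    first column = region id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Scores, expectations, classification
# ---------------------------------------------------------------------------


def cnv_score(profile) -> float:
    """Quadratic sum of a scaled CNV profile (values in [-1, 1])."""
    v = np.asarray(profile, dtype=float)
    if v.size and (np.abs(v) > 1 + 1e-9).any():
        raise ValueError("profile values outside [-1, 1]; scale first")
    return float((v**2).sum())


def cnv_scores(region_values: pd.DataFrame) -> pd.Series:
    """Per-pseudobulk CNV score over a regions x pseudobulks matrix."""
    return pd.Series(
        {pb: cnv_score(region_values[pb]) for pb in region_values.columns}, name="cnv_score"
    )


@dataclass
class Expectations:
    """Tissue-level score anchors after one round of outlier removal."""

    normal_expectation: float
    malignant_expectation: float
    outliers_removed: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.normal_expectation <= self.malignant_expectation


def compute_expectations(scores: pd.Series, tissue: pd.Series) -> Expectations:
    """Normal/malignant expectations from tumor-adjacent and tumor scores.

    Initial means are taken per tissue; outliers (adjacent pseudobulks with
    score >= the initial malignant expectation, tumor pseudobulks with
    score <= the initial normal expectation) are removed and the means
    recomputed once on the survivors.
    """
    tissue = tissue.reindex(scores.index)
    adjacent = scores[tissue == "adjacent"]
    tumor = scores[tissue == "tumor"]
    if adjacent.empty or tumor.empty:
        raise ValueError("both tumor and adjacent pseudobulks are required")
    ne0, me0 = float(adjacent.mean()), float(tumor.mean())
    out_adj = adjacent.index[adjacent >= me0].tolist()
    out_tum = tumor.index[tumor <= ne0].tolist()
    adj_kept = adjacent.drop(out_adj)
    tum_kept = tumor.drop(out_tum)
    if adj_kept.empty or tum_kept.empty:
        raise ValueError("outlier removal emptied a tissue; expectations undefined")
    exp = Expectations(
        normal_expectation=float(adj_kept.mean()),
        malignant_expectation=float(tum_kept.mean()),
        outliers_removed=sorted(out_adj + out_tum),
    )
    if exp.normal_expectation == exp.malignant_expectation:
        logger.warning("degenerate expectations: normal == malignant (%.4g)", exp.normal_expectation)
    return exp


@dataclass
class ClassLabels:
    """Pseudobulk labels plus the recursion depth actually used."""

    labels: pd.Series
    recursion_depth_used: int


def iterative_classify(
    scores: pd.Series,
    profiles: pd.DataFrame,
    expectations: Expectations,
    k: int = 50,
    max_recursion: int = 5,
    linkage_method: str = "ward",
) -> ClassLabels:
    """Iterative hierarchical normal/malignant calling of pseudobulks.

    Profiles (regions x pseudobulks) are Ward-clustered into
    ``min(k, n_remaining)`` clusters; clusters whose mean score falls at or
    below the normal expectation become normal, at or above the malignant
    expectation malignant, and the remainder is re-clustered with the same
    k until a round resolves nothing new or ``max_recursion`` is reached.
    Pseudobulks still undecided at the end stay ``intermediate``.
    """
    if not expectations.valid:
        raise ValueError("normal expectation exceeds malignant expectation")
    if k < 1 or max_recursion < 1:
        raise ValueError("k and max_recursion must be >= 1")
    pbs = list(scores.index)
    labels = pd.Series("intermediate", index=scores.index, dtype=object)
    remaining = list(pbs)
    depth = 0
    while remaining and depth < max_recursion:
        depth += 1
        X = profiles[remaining].to_numpy().T
        assignment = _cut_tree(X, min(k, len(remaining)), linkage_method)
        resolved_any = False
        next_remaining = []
        for cl in range(assignment.max() + 1):
            members = [remaining[i] for i in np.nonzero(assignment == cl)[0]]
            if not members:
                continue
            mean_score = float(scores[members].mean())
            if mean_score <= expectations.normal_expectation:
                labels[members] = "normal"
                resolved_any = True
            elif mean_score >= expectations.malignant_expectation:
                labels[members] = "malignant"
                resolved_any = True
            else:
                next_remaining.extend(members)
        remaining = next_remaining
        if not resolved_any:
            break
    return ClassLabels(labels=labels, recursion_depth_used=depth)


def propagate_to_cells(labels: ClassLabels, members: Mapping[str, Sequence[str]]) -> pd.Series:
    """Each cell inherits the label of its pseudobulk."""
    rows = {}
    for pb, label in labels.labels.items():
        for cell in members.get(pb, ()):
            if cell in rows:
                raise ValueError(f"cell {cell} belongs to several pseudobulks")
            rows[cell] = label
    missing = set(members) - set(labels.labels.index)
    if missing:
        raise ValueError(f"pseudobulks without labels: {sorted(missing)[:3]}")
    return pd.Series(rows, name="label")


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


@dataclass
class MalignancyResult:
    pseudobulks: PseudobulkSet
    cnv: CnvMatrix
    region_values: pd.DataFrame
    scores: pd.Series
    expectations: Expectations
    pb_labels: ClassLabels
    cell_labels: pd.Series


def classify_malignancy(
    matrix: pd.DataFrame,
    gene_meta: pd.DataFrame,
    cell_groups: pd.Series,
    n_per_group: Mapping[str, int],
    tissue_of_group: Optional[Mapping[str, str]] = None,
    reference_group: str = "adjacent",
    window: int = 101,
    k: int = 50,
    max_recursion: int = 5,
    normalization_total: float = 1e7,
) -> MalignancyResult:
    """End-to-end malignant-cell calling from an expression matrix.

    ``tissue_of_group`` maps each cell group to "tumor"/"adjacent" for the
    expectation computation (groups mapped to anything else are classified
    but do not anchor the expectations); by default group names are taken
    literally.  Reference pseudobulks for the CNV estimate come from
    ``reference_group`` (tumor-adjacent tissue).
    """
    pbs = build_pseudobulks(
        matrix, cell_groups, n_per_group, normalization_total=normalization_total
    )
    tissue_of_group = tissue_of_group or {g: g for g in n_per_group}
    reference = [pb for pb in pbs.profiles.columns if pbs.groups[pb] == reference_group]
    if not reference:
        raise ValueError(f"no pseudobulks in reference group {reference_group!r}")
    cnv = estimate_cnv_windowed(pbs.profiles, gene_meta, reference, window=window)
    region_values = aggregate_cytobands(cnv)
    scores = cnv_scores(region_values)
    tissue = pbs.groups.map(lambda g: tissue_of_group.get(g, ""))
    expectations = compute_expectations(scores, tissue)
    pb_labels = iterative_classify(scores, region_values, expectations, k=k, max_recursion=max_recursion)
    cell_labels = propagate_to_cells(pb_labels, pbs.members)
    return MalignancyResult(
        pseudobulks=pbs,
        cnv=cnv,
        region_values=region_values,
        scores=scores,
        expectations=expectations,
        pb_labels=pb_labels,
        cell_labels=cell_labels,
    )
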