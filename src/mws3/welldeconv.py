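"""Reconstruction of "cell-containing wells with beads".

A Microwell-seq3 chip loads several barcoded beads and several nuclei into
each microwell.  All beads in one well sample the same molecule pool, so
their feature sets — 17-nt random molecule tags in RNA mode, fragment
insertion coordinates plus 14-nt spike-in oligos in ATAC mode — overlap far
more than feature sets of beads from different wells.  The pipeline here:

1. rank beads by deduplicated units and keep the top n (``top_barcodes``);
2. build per-bead feature sets (``build_feature_sets``);
3. score every pair of beads sharing at least one feature with the Jaccard
   index over their feature sets, via an inverted index (``jaccard_pairs``);
4. call a threshold on the ranked Jaccard curve (``knee_threshold``);
5. merge beads connected by above-threshold pairs into wells and drop
   overloaded wells with more than ``max_beads`` members (``merge_beads``);
6. split each well into single cells by preindex and emit per-cell count
   matrices or fragment files (``assign_cells``).

``deconvolve`` chains the steps and keeps per-stage tallies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse

from .chipio import CountMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BeadFeatureSet:
    """Well-identifying features observed on one bead.

    ``features`` drive the Jaccard index.  ``confirm`` is only populated in
    ATAC ``refine`` mode, where candidate pairs found on insertion
    coordinates must additionally share at least one spike-in oligo.
    ``total_units`` counts raw reads; ``len(features)`` is the deduplicated
    unit count used for bead ranking.
    """

    bead_barcode: str
    features: frozenset
    total_units: int
    confirm: frozenset = frozenset()


@dataclass(frozen=True)
class PairScore:
    bead_a: str
    bead_b: str
    jaccard: float
    shared: int

    def __post_init__(self):
        if self.bead_a >= self.bead_b:
            raise ValueError("pairs are stored with bead_a < bead_b")


@dataclass
class WellPartition:
    """Bead -> well assignment after merging and overload filtering.

    ``wells`` maps a well id (the lexicographically smallest member barcode)
    to its sorted member list; ``dropped_wells`` records components removed
    with their reason (e.g. ``overloaded``).
    """

    wells: dict
    dropped_wells: list = field(default_factory=list)
    bead_to_well: dict = field(init=False)

    def __post_init__(self):
        self.bead_to_well = {}
        for well_id, members in self.wells.items():
            if not members:
                raise ValueError("empty well")
            if well_id != min(members):
                raise ValueError("well id must be the smallest member barcode")
            for bead in members:
                if bead in self.bead_to_well:
                    raise ValueError(f"bead {bead} assigned to two wells")
                self.bead_to_well[bead] = well_id

    def n_beads(self) -> int:
        return len(self.bead_to_well)

    def member_pairs(self, include_dropped: bool = False) -> set:
        """Unordered same-well bead pairs implied by the partition."""
        groups: Iterable[Sequence[str]] = list(self.wells.values())
        if include_dropped:
            groups = itertools.chain(groups, (d["members"] for d in self.dropped_wells))
        pairs = set()
        for members in groups:
            for a, b in itertools.combinations(sorted(members), 2):
                pairs.add((a, b))
        return pairs

    def to_dict(self) -> dict:
        return {
            "wells": {w: list(m) for w, m in sorted(self.wells.items())},
            "dropped_wells": [
                {"members": list(d["members"]), "reason": d["reason"]}
                for d in self.dropped_wells
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "WellPartition":
        return cls(wells=payload["wells"], dropped_wells=payload.get("dropped_wells", []))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def top_barcodes(unit_counts: Mapping[str, int], n: int) -> list:
    """Barcodes with the highest unit counts; ties break lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    items = sorted(unit_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(items) < n:
        logger.info("top_barcodes: only %d barcodes available (requested %d)", len(items), n)
    return [bc for bc, _ in items[:n]]


def build_feature_sets(
    reads: pd.DataFrame, assay: str, spikein_mode: str = "union"
) -> dict:
    """Collect per-bead feature sets from a tagged-read table.

    RNA features are the 17-nt molecule-tag strings.  ATAC features are
    fragment coordinate triples; spike-in 14-mers are pooled into the same
    set (``union``), kept as a secondary confirmation set (``refine``), or
    ignored (``none``).
    """
    if assay not in ("rna", "atac"):
        raise ValueError(f"unknown assay {assay!r}")
    if spikein_mode not in ("none", "union", "refine"):
        raise ValueError(f"unknown spikein_mode {spikein_mode!r}")

    features: dict[str, set] = {}
    confirm: dict[str, set] = {}
    totals: dict[str, int] = {}

    if assay == "rna":
        tags = reads["feature_tag"].fillna("").astype(object)
        if (tags == "").all() and len(reads):
            raise ValueError("rna assay requires feature_tag values")
        sub = reads.loc[tags != "", ["bead_barcode", "feature_tag"]]
        for bead, grp in sub.groupby("bead_barcode", sort=False):
            features[bead] = set(grp["feature_tag"])
            totals[bead] = int(len(grp))
    else:
        chrom = reads["chrom"].fillna("").astype(object)
        spike_col = reads["spikein_tag"].fillna("").astype(object) if "spikein_tag" in reads else pd.Series("", index=reads.index)
        frag_rows = reads[chrom != ""]
        if len(frag_rows) == 0 and not (spike_col != "").any():
            if len(reads):
                raise ValueError("atac assay requires fragment coordinates or spike-in tags")
        for bead, grp in frag_rows.groupby("bead_barcode", sort=False):
            features[bead] = {
                ("frag", c, int(s), int(e))
                for c, s, e in zip(grp["chrom"], grp["start"], grp["end"])
            }
            totals[bead] = int(len(grp))
        if spikein_mode != "none" and "spikein_tag" in reads:
            spikes = reads[spike_col != ""]
            for bead, grp in spikes.groupby("bead_barcode", sort=False):
                keys = {("spike", t) for t in grp["spikein_tag"]}
                totals[bead] = totals.get(bead, 0) + int(len(grp))
                if spikein_mode == "union":
                    features.setdefault(bead, set()).update(keys)
                else:
                    confirm.setdefault(bead, set()).update(keys)

    out = {}
    for bead in sorted(features):
        out[bead] = BeadFeatureSet(
            bead_barcode=bead,
            features=frozenset(features[bead]),
            total_units=totals.get(bead, 0),
            confirm=frozenset(confirm.get(bead, ())),
        )
    return out


def dedup_unit_counts(feature_sets: Mapping[str, BeadFeatureSet]) -> dict:
    """Per-bead deduplicated unit counts (unique tags / unique fragments)."""
    return {bead: len(fs.features) for bead, fs in feature_sets.items()}


def jaccard_pairs(
    feature_sets: Mapping[str, BeadFeatureSet],
    min_shared: int = 1,
    require_confirm: bool = False,
) -> list:
    """Sparse pairwise Jaccard indices via an inverted feature->bead index.

    Only pairs sharing at least ``min_shared`` features appear.  With
    ``require_confirm`` a pair is kept only if the beads also share at least
    one confirmation feature (ATAC spike-in refinement).
    """
    beads = [b for b in sorted(feature_sets) if feature_sets[b].features]
    for b in sorted(feature_sets):
        if not feature_sets[b].features:
            logger.info("jaccard_pairs: bead %s has an empty feature set, excluded", b)
    if len(beads) < 2:
        return []
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")

    index: dict = {}
    for bead in beads:
        for feat in feature_sets[bead].features:
            index.setdefault(feat, []).append(bead)
    shared_counts: dict = {}
    for members in index.values():
        if len(members) < 2:
            continue
        for a, b in itertools.combinations(sorted(members), 2):
            shared_counts[(a, b)] = shared_counts.get((a, b), 0) + 1

    confirm_shared: dict = {}
    if require_confirm:
        cindex: dict = {}
        for bead in beads:
            for feat in feature_sets[bead].confirm:
                cindex.setdefault(feat, []).append(bead)
        for members in cindex.values():
            if len(members) < 2:
                continue
            for a, b in itertools.combinations(sorted(members), 2):
                confirm_shared[(a, b)] = confirm_shared.get((a, b), 0) + 1

    pairs = []
    for (a, b), shared in sorted(shared_counts.items()):
        if shared < min_shared:
            continue
        if require_confirm and confirm_shared.get((a, b), 0) < 1:
            continue
        union = len(feature_sets[a].features) + len(feature_sets[b].features) - shared
        pairs.append(PairScore(bead_a=a, bead_b=b, jaccard=shared / union, shared=shared))
    return pairs


def jaccard_pairs_dense(feature_sets: Mapping[str, BeadFeatureSet]) -> list:
    """Brute-force double-loop Jaccard; oracle for small instances."""
    beads = [b for b in sorted(feature_sets) if feature_sets[b].features]
    pairs = []
    for a, b in itertools.combinations(beads, 2):
        fa, fb = feature_sets[a].features, feature_sets[b].features
        shared = len(fa & fb)
        if shared:
            pairs.append(PairScore(a, b, shared / len(fa | fb), shared))
    return pairs


def knee_threshold(values, strategy: str = "max_distance") -> float:
    """Threshold on a ranked Jaccard curve separating signal from background.

    Values are sorted descending and log10-transformed.  ``max_distance``
    places the knee at the point of maximum perpendicular distance to the
    chord joining the first and last points of the normalized rank-value
    curve; ``second_diff`` at the maximum discrete second difference;
    ``otsu`` at the exact two-class split of the log10 values maximizing
    between-class variance (robust when the background mode is heavy and
    decays smoothly rather than forming a sharp corner).  Pairs strictly
    above the returned threshold are same-well candidates.  A constant
    input has no knee: the maximum value is returned (retaining nothing)
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if (values <= 0).any():
        raise ValueError("Jaccard values must be positive")
    order = np.sort(values)[::-1]
    if order[0] == order[-1]:
        logger.warning("knee_threshold: constant input, no knee; retaining nothing")
        return float(order[0])
    y = np.log10(order)
    x = np.arange(order.size, dtype=float)
    # normalize both axes so the knee is scale-free
    xn = x / x[-1]
    yn = (y - y[-1]) / (y[0] - y[-1])
    if strategy == "max_distance":
        # |cross product| of (point - first) with the chord direction
        dx, dy = xn[-1] - xn[0], yn[-1] - yn[0]
        dist = np.abs(dx * (yn - yn[0]) - dy * (xn - xn[0]))
        knee = int(np.argmax(dist))
    elif strategy == "second_diff":
        if order.size < 3:
            knee = 0
        else:
            d2 = np.abs(np.diff(yn, 2))
            knee = int(np.argmax(d2)) + 1
    elif strategy == "otsu":
        return _otsu_threshold(np.sort(y), np.sort(values))
    else:
        raise ValueError(f"unknown knee strategy {strategy!r}")
    return float(order[knee])


def _otsu_threshold(y_ascending: np.ndarray, values_ascending: np.ndarray) -> float:
    """Exact (binning-free) Otsu split of sorted log10 values.

    Returns the untransformed value of the largest lower-class member, so
    that "strictly above threshold" retains exactly the upper class.
    """
    y = y_ascending
    n = y.size
    csum = np.cumsum(y)
    total = csum[-1]
    i = np.arange(1, n)  # lower class = y[:i]
    mu0 = csum[:-1] / i
    mu1 = (total - csum[:-1]) / (n - i)
    var_between = (i / n) * (1 - i / n) * (mu0 - mu1) ** 2
    valid = y[1:] > y[:-1]  # split only between distinct values
    var_between = np.where(valid, var_between, -np.inf)
    best = int(np.argmax(var_between))
    return float(values_ascending[best])


def merge_beads(
    pairs: Sequence[PairScore],
    beads: Iterable[str],
    max_beads: int = 6,
) -> WellPartition:
    """Connected components of the pair graph become wells.

    ``pairs`` must already be threshold-filtered.  Beads without any partner
    become singleton wells.  Components larger than ``max_beads`` are dropped
    entirely and recorded as overloaded.
    """
    graph = nx.Graph()
    graph.add_nodes_from(beads)
    for p in pairs:
        if p.bead_a not in graph or p.bead_b not in graph:
            raise ValueError(f"pair references unknown bead: {p.bead_a}/{p.bead_b}")
        graph.add_edge(p.bead_a, p.bead_b)
    wells, dropped = {}, []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if len(members) > max_beads:
            dropped.append({"members": members, "reason": "overloaded"})
        else:
            wells[members[0]] = members
    return WellPartition(wells=wells, dropped_wells=dropped)


@dataclass
class CellAssignment:
    """Per-cell output after splitting wells by preindex.

    Cell barcodes are ``preindex + '-' + representative bead barcode``.  RNA
    mode yields a gene x cell UMI count matrix; ATAC mode a fragments table
    keyed by cell barcode.
    """

    matrix: Optional[CountMatrix]
    fragments: Optional[pd.DataFrame]
    stats: dict


def assign_cells(
    reads: pd.DataFrame, partition: WellPartition, assay: str
) -> CellAssignment:
    """Relabel reads to (preindex, well representative) single-cell barcodes."""
    if assay not in ("rna", "atac"):
        raise ValueError(f"unknown assay {assay!r}")
    rep = reads["bead_barcode"].map(partition.bead_to_well)
    kept = rep.notna()
    stats = {
        "input_reads": int(len(reads)),
        "dropped_unassigned_bead": int((~kept).sum()),
    }
    sub = reads.loc[kept].copy()
    sub["cell"] = sub["preindex"].astype(str) + "-" + rep[kept].astype(str)

    if assay == "rna":
        genes = sub["annotation"].astype(object)
        with_gene = sub.loc[genes != ""]
        stats["dropped_unannotated"] = int(len(sub) - len(with_gene))
        # UMI collapse: one count per distinct (cell, gene, umi)
        dedup = with_gene.drop_duplicates(subset=["cell", "annotation", "umi"])
        stats["umi_deduplicated_reads"] = int(len(with_gene) - len(dedup))
        counts = dedup.groupby(["annotation", "cell"], sort=True).size()
        gene_index = sorted(dedup["annotation"].unique())
        cell_index = sorted(dedup["cell"].unique())
        gi = {g: i for i, g in enumerate(gene_index)}
        ci = {c: i for i, c in enumerate(cell_index)}
        rows = [gi[g] for g, _ in counts.index]
        cols = [ci[c] for _, c in counts.index]
        matrix = scipy.sparse.coo_matrix(
            (counts.to_numpy(), (rows, cols)), shape=(len(gene_index), len(cell_index))
        ).tocsr()
        cm = CountMatrix(features=gene_index, cells=cell_index, matrix=matrix)
        cm.obs["total_counts"] = cm.total_counts()
        cm.obs["genes_detected"] = cm.features_detected()
        stats["cells"] = len(cell_index)
        return CellAssignment(matrix=cm, fragments=None, stats=stats)

    frags = sub.loc[sub["chrom"].astype(object) != ""].copy()
    stats["dropped_non_fragment"] = int(len(sub) - len(frags))
    frags["start"] = frags["start"].astype(int)
    frags["end"] = frags["end"].astype(int)
    grouped = (
        frags.groupby(["chrom", "start", "end", "cell"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"cell": "barcode"})
    )
    stats["cells"] = int(grouped["barcode"].nunique())
    return CellAssignment(matrix=None, fragments=grouped, stats=stats)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


@dataclass
class DeconvResult:
    partition: WellPartition
    pairs: list
    threshold: Optional[float]
    feature_sets: dict
    assignment: CellAssignment
    report: dict


def deconvolve(
    reads: pd.DataFrame,
    assay: str,
    top_n: int = 20_000,
    max_beads: int = 6,
    spikein_mode: str = "union",
    min_shared: int = 1,
    knee_strategy: str = "otsu",
    threshold: Optional[float] = None,
) -> DeconvResult:
    """Full bead->well->cell deconvolution of a tagged-read table.

    ``threshold`` overrides knee-calling when given; otherwise a threshold
    is called on the ranked pair-Jaccard curve (``otsu`` by default, which
    tolerates a heavy smoothly-decaying background; ``max_distance`` and
    ``second_diff`` give classic knee geometry).  With fewer than two pairs
    no threshold is called and every bead stays a singleton well.
    """
    feature_sets = build_feature_sets(reads, assay, spikein_mode=spikein_mode)
    counts = dedup_unit_counts(feature_sets)
    retained = set(top_barcodes(counts, min(top_n, max(len(counts), 1))))
    feature_sets = {b: fs for b, fs in feature_sets.items() if b in retained}

    pairs = jaccard_pairs(
        feature_sets, min_shared=min_shared, require_confirm=(spikein_mode == "refine")
    )
    called = threshold
    if called is None and len(pairs) >= 2:
        called = knee_threshold([p.jaccard for p in pairs], strategy=knee_strategy)
    kept_pairs = [p for p in pairs if called is not None and p.jaccard > called]

    partition = merge_beads(kept_pairs, feature_sets.keys(), max_beads=max_beads)
    assignment = assign_cells(reads, partition, assay)
    report = {
        "beads_with_features": len(feature_sets),
        "candidate_pairs": len(pairs),
        "threshold": called,
        "pairs_above_threshold": len(kept_pairs),
        "wells": len(partition.wells),
        "dropped_wells": len(partition.dropped_wells),
        **{f"assign_{k}": v for k, v in assignment.stats.items()},
    }
    return DeconvResult(
        partition=partition,
        pairs=pairs,
        threshold=called,
        feature_sets=feature_sets,
        assignment=assignment,
        report=report,
    )
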