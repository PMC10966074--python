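"""Bead ranking, Jaccard scoring, knee-calling, merging and cell splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mws3 import synthdata, welldeconv
from mws3.welldeconv import (
    BeadFeatureSet,
    PairScore,
    WellPartition,
    assign_cells,
    build_feature_sets,
    deconvolve,
    jaccard_pairs,
    jaccard_pairs_dense,
    knee_threshold,
    merge_beads,
    top_barcodes,
)


def _fs(mapping):
    return {
        bead: BeadFeatureSet(bead_barcode=bead, features=frozenset(feats), total_units=len(feats))
        for bead, feats in mapping.items()
    }


def _tagged(rows):
    df = pd.DataFrame(rows)
    for col in ("umi", "feature_tag", "chrom", "spikein_tag", "annotation"):
        if col not in df:
            df[col] = ""
        df[col] = df[col].fillna("")
    for col in ("start", "end"):
        if col not in df:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


class TestTopBarcodes:
    def test_takes_highest_counts(self):
        assert top_barcodes({"A": 10, "B": 8, "C": 3, "D": 1}, 3) == ["A", "B", "C"]

    def test_short_population_returned_whole(self):
        assert top_barcodes({"A": 1}, 5) == ["A"]

    def test_tie_broken_lexicographically(self):
        assert top_barcodes({"B": 5, "A": 5}, 1) == ["A"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_barcodes({"A": 1}, 0)


class TestBuildFeatureSets:
    def test_rna_tags_deduplicate(self):
        reads = _tagged(
            [
                {"bead_barcode": "X", "preindex": "p", "feature_tag": t}
                for t in ["t1", "t1", "t2"]
            ]
        )
        fs = build_feature_sets(reads, "rna")
        assert fs["X"].features == frozenset({"t1", "t2"})
        assert fs["X"].total_units == 3

    def test_atac_shared_fragment_lands_on_both_beads(self):
        reads = _tagged(
            [
                {"bead_barcode": b, "preindex": "p", "chrom": "chr1", "start": 100, "end": 250}
                for b in ["X", "Y"]
            ]
        )
        fs = build_feature_sets(reads, "atac", spikein_mode="none")
        key = ("frag", "chr1", 100, 250)
        assert key in fs["X"].features and key in fs["Y"].features

    def test_spikein_union_counts_both_key_types(self):
        reads = _tagged(
            [
                {"bead_barcode": "X", "preindex": "p", "chrom": "chr1", "start": 0, "end": 100},
                {"bead_barcode": "X", "preindex": "p", "spikein_tag": "S" * 14},
            ]
        )
        fs = build_feature_sets(reads, "atac", spikein_mode="union")
        assert len(fs["X"].features) == 2

    def test_spikein_refine_keeps_confirm_separate(self):
        reads = _tagged(
            [
                {"bead_barcode": "X", "preindex": "p", "chrom": "chr1", "start": 0, "end": 100},
                {"bead_barcode": "X", "preindex": "p", "spikein_tag": "S" * 14},
            ]
        )
        fs = build_feature_sets(reads, "atac", spikein_mode="refine")
        assert len(fs["X"].features) == 1 and len(fs["X"].confirm) == 1

    def test_assay_feature_mismatch_raises(self):
        reads = _tagged([{"bead_barcode": "X", "preindex": "p", "feature_tag": "t1"}])
        with pytest.raises(ValueError):
            build_feature_sets(reads, "atac")


class TestJaccardPairs:
    def test_identical_sets(self):
        pairs = jaccard_pairs(_fs({"A": {1, 2}, "B": {1, 2}}))
        assert pairs == [PairScore("A", "B", 1.0, 2)]

    def test_half_overlap(self):
        (p,) = jaccard_pairs(_fs({"A": {1, 2, 3}, "B": {2, 3, 4}}))
        assert p.jaccard == 0.5 and p.shared == 2

    def test_disjoint_pair_absent(self):
        assert jaccard_pairs(_fs({"A": {1}, "B": {2}})) == []

    def test_refine_requires_shared_spikein(self):
        fs = {
            "A": BeadFeatureSet("A", frozenset({1, 2}), 2, confirm=frozenset({"s1"})),
            "B": BeadFeatureSet("B", frozenset({1, 2}), 2, confirm=frozenset({"s2"})),
            "C": BeadFeatureSet("C", frozenset({1, 3}), 2, confirm=frozenset({"s1"})),
        }
        pairs = jaccard_pairs(fs, require_confirm=True)
        assert [(p.bead_a, p.bead_b) for p in pairs] == [("A", "C")]

    @pytest.mark.parametrize("seed", range(10))
    def test_sparse_equals_brute_force_oracle(self, seed):
        """Inverted-index output must equal the double-loop oracle exactly
        on random 100-bead instances."""
        rng = np.random.default_rng(seed)
        fs = _fs(
            {
                f"b{i:03d}": set(rng.integers(0, 400, size=rng.integers(1, 40)).tolist())
                for i in range(100)
            }
        )
        sparse = jaccard_pairs(fs)
        dense = jaccard_pairs_dense(fs)
        assert sparse == dense  # exact equality incl. float jaccard values

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.dictionaries(
            st.text(alphabet="ABCD", min_size=1, max_size=3),
            st.sets(st.integers(0, 25), max_size=8),
            min_size=2,
            max_size=10,
        )
    )
    def test_sparse_matches_oracle_on_arbitrary_sets(self, mapping):
        fs = _fs(mapping)
        assert jaccard_pairs(fs) == jaccard_pairs_dense(fs)


class TestKneeThreshold:
    @pytest.mark.parametrize("strategy", ["max_distance", "otsu"])
    def test_bimodal_isolates_high_mode(self, strategy):
        rng = np.random.default_rng(1)
        high = rng.uniform(0.35, 0.45, 100)
        low = rng.uniform(0.0015, 0.0025, 5000)
        values = np.concatenate([high, low])
        thr = knee_threshold(values, strategy=strategy)
        assert low.max() <= thr < high.min()
        assert (values > thr).sum() == 100

    def test_constant_input_retains_nothing(self):
        thr = knee_threshold([0.2, 0.2, 0.2])
        assert thr == 0.2  # strictly-above rule retains nothing

    def test_appending_low_mode_values_keeps_high_mode(self):
        rng = np.random.default_rng(2)
        high = rng.uniform(0.3, 0.5, 80)
        low = rng.uniform(0.001, 0.003, 2000)
        base = np.concatenate([high, low])
        extended = np.concatenate([base, rng.uniform(0.001, 0.003, 3000)])
        kept_base = set(np.flatnonzero(base > knee_threshold(base))[:80])
        kept_ext = set(np.flatnonzero(extended > knee_threshold(extended))[:80])
        assert kept_base == kept_ext == set(range(80))

    def test_rejects_nonpositive_or_tiny_input(self):
        with pytest.raises(ValueError):
            knee_threshold([0.5])
        with pytest.raises(ValueError):
            knee_threshold([0.5, 0.0])


class TestMergeBeads:
    def test_transitive_closure(self):
        pairs = [PairScore("A", "B", 0.5, 1), PairScore("B", "C", 0.5, 1)]
        part = merge_beads(pairs, ["A", "B", "C"])
        assert part.wells == {"A": ["A", "B", "C"]}

    def test_overloaded_component_dropped(self):
        beads = [f"b{i}" for i in range(7)]
        pairs = [PairScore(beads[i], beads[i + 1], 0.5, 1) for i in range(6)]
        part = merge_beads(pairs, beads)
        assert part.wells == {}
        assert part.dropped_wells[0]["reason"] == "overloaded"
        assert sorted(part.dropped_wells[0]["members"]) == beads

    def test_no_pairs_gives_singletons(self):
        part = merge_beads([], ["A", "B"])
        assert part.wells == {"A": ["A"], "B": ["B"]}

    def test_unknown_bead_rejected(self):
        with pytest.raises(ValueError):
            merge_beads([PairScore("A", "Z", 0.5, 1)], ["A"])

    def test_partition_covers_each_bead_once(self):
        part = WellPartition(wells={"A": ["A", "B"], "C": ["C"]})
        assert part.bead_to_well == {"A": "A", "B": "A", "C": "C"}
        with pytest.raises(ValueError):
            WellPartition(wells={"A": ["A", "B"], "B": ["B"]})


class TestAssignCells:
    def _partition(self):
        return WellPartition(wells={"A": ["A", "B"]})

    def test_two_preindexes_two_cells(self):
        reads = _tagged(
            [
                {"bead_barcode": "A", "preindex": "p1", "umi": "u1", "feature_tag": "t1", "annotation": "g1"},
                {"bead_barcode": "B", "preindex": "p2", "umi": "u2", "feature_tag": "t2", "annotation": "g1"},
            ]
        )
        out = assign_cells(reads, self._partition(), "rna")
        assert out.matrix.cells == ["p1-A", "p2-A"]

    def test_umi_collapse(self):
        reads = _tagged(
            [
                {"bead_barcode": "A", "preindex": "p1", "umi": "u1", "feature_tag": "t", "annotation": "g1"},
                {"bead_barcode": "B", "preindex": "p1", "umi": "u1", "feature_tag": "t", "annotation": "g1"},
            ]
        )
        out = assign_cells(reads, self._partition(), "rna")
        assert out.matrix.matrix.sum() == 1

    def test_read_on_dropped_well_excluded(self):
        part = WellPartition(wells={"A": ["A"]}, dropped_wells=[{"members": ["X"], "reason": "overloaded"}])
        reads = _tagged(
            [
                {"bead_barcode": "A", "preindex": "p1", "umi": "u1", "feature_tag": "t1", "annotation": "g1"},
                {"bead_barcode": "X", "preindex": "p1", "umi": "u2", "feature_tag": "t2", "annotation": "g2"},
            ]
        )
        out = assign_cells(reads, part, "rna")
        assert out.stats["dropped_unassigned_bead"] == 1
        assert out.matrix.cells == ["p1-A"]

    def test_atac_fragments_keyed_by_cell(self):
        reads = _tagged(
            [
                {"bead_barcode": "A", "preindex": "p1", "chrom": "chr1", "start": 0, "end": 100},
                {"bead_barcode": "B", "preindex": "p1", "chrom": "chr1", "start": 0, "end": 100},
            ]
        )
        out = assign_cells(reads, self._partition(), "atac")
        assert len(out.fragments) == 1
        assert out.fragments.iloc[0]["barcode"] == "p1-A"
        assert out.fragments.iloc[0]["count"] == 2


class TestDeconvolveEndToEnd:
    def test_recovers_simulated_wells_rna(self, small_chip_rna):
        sim = small_chip_rna
        res = deconvolve(sim.reads, "rna", threshold=0.0)  # no background: fixed floor
        truth = sim.truth.same_well_pairs()
        pred = res.partition.member_pairs(include_dropped=True)
        m = synthdata.pair_metrics(truth, pred)
        assert m["precision"] >= 0.99 and m["recall"] >= 0.99

    def test_recovers_simulated_wells_atac(self, small_chip_atac):
        sim = small_chip_atac
        res = deconvolve(sim.reads, "atac")
        truth = sim.truth.same_well_pairs()
        pred = res.partition.member_pairs(include_dropped=True)
        m = synthdata.pair_metrics(truth, pred)
        assert m["precision"] >= 0.99 and m["recall"] >= 0.99
        assert all(len(members) <= 6 for members in res.partition.wells.values())

    def test_deterministic_partitions(self, small_chip_atac):
        reads = small_chip_atac.reads
        a = deconvolve(reads, "atac")
        b = deconvolve(reads, "atac")
        assert a.partition.to_dict() == b.partition.to_dict()
        assert a.threshold == b.threshold
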