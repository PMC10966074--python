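"""Pseudobulk construction, windowed CNV estimation and iterative calling."""

import numpy as np
import pandas as pd
import pytest

from mws3 import cnvclass, synthdata
from mws3.cnvclass import (
    Expectations,
    aggregate_cytobands,
    build_pseudobulks,
    classify_malignancy,
    cnv_score,
    cnv_scores,
    compute_expectations,
    estimate_cnv_windowed,
    iterative_classify,
    propagate_to_cells,
)


def _matrix(n_genes=30, cells=("a", "b", "c", "d"), seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.integers(0, 50, size=(n_genes, len(cells))).astype(float),
        index=[f"g{i}" for i in range(n_genes)],
        columns=list(cells),
    )


class TestBuildPseudobulks:
    def test_single_cluster_equals_column_sum(self):
        m = _matrix()
        groups = pd.Series("t", index=m.columns)
        pbs = build_pseudobulks(m, groups, {"t": 1}, normalization_total=1e6)
        np.testing.assert_allclose(pbs.raw_profiles.iloc[:, 0], m.sum(axis=1))

    def test_small_group_dropped_and_recorded(self):
        m = _matrix(cells=("a", "b", "c"))
        groups = pd.Series(["t", "t", "u"], index=m.columns)
        pbs = build_pseudobulks(m, groups, {"t": 2, "u": 5})
        assert pbs.dropped_groups == [{"group": "u", "cells": 1, "requested": 5}]
        assert set(pbs.groups) == {"t"}

    def test_normalization_totals(self):
        m = _matrix(cells=tuple("abcdefgh"))
        groups = pd.Series("t", index=m.columns)
        pbs = build_pseudobulks(m, groups, {"t": 3}, normalization_total=1e7)
        totals = pbs.profiles.sum(axis=0)
        np.testing.assert_allclose(totals, 1e7, rtol=1e-6)

    def test_profiles_conserve_member_cell_sums(self, small_cnv_study):
        matrix, _, cell_meta = small_cnv_study
        pbs = build_pseudobulks(
            matrix, cell_meta["group"], {"tumor": 50, "adjacent": 35, "normal": 15}
        )
        for pb in list(pbs.raw_profiles.columns)[::7]:
            oracle = matrix[pbs.members[pb]].sum(axis=1)
            np.testing.assert_allclose(pbs.raw_profiles[pb], oracle, rtol=1e-12)
        # every cell in exactly one pseudobulk
        all_cells = [c for cells in pbs.members.values() for c in cells]
        assert len(all_cells) == len(set(all_cells)) == matrix.shape[1]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_pseudobulks(pd.DataFrame(), pd.Series(dtype=object), {"t": 1})


class TestEstimateCnvWindowed:
    def _meta(self, n, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "start": np.arange(n) * 1000, "end": np.arange(n) * 1000 + 500},
            index=[f"g{i}" for i in range(n)],
        )

    def test_identity_to_reference_gives_zeros(self):
        m = _matrix(n_genes=20, cells=("p1", "p2"))
        m["p2"] = m["p1"]
        cnv = estimate_cnv_windowed(m, self._meta(20), reference=["p1"], window=5)
        np.testing.assert_allclose(cnv.values.to_numpy(), 0.0)

    def test_step_gain_plateau_log2(self):
        """A noiseless 2x gain over a contiguous block shows an interior
        plateau at log2(2)=1 before scaling (closed-form moving average)."""
        n = 900
        m = pd.DataFrame({"ref": np.full(n, 100.0)}, index=[f"g{i}" for i in range(n)])
        q = np.full(n, 100.0)
        q[300:600] = 200.0
        m["q"] = q
        cnv = estimate_cnv_windowed(m, self._meta(n), reference=["ref"], window=101, pseudocount=0.0)
        interior = cnv.values["q"].to_numpy()[360:540]
        plateau = np.log2(2.0) / cnv.prescale_max_abs
        np.testing.assert_allclose(interior, plateau)
        assert cnv.prescale_max_abs == pytest.approx(1.0)

    def test_window_one_is_identity(self):
        m = _matrix(n_genes=15, cells=("r", "q"), seed=3) + 1.0
        cnv = estimate_cnv_windowed(m, self._meta(15), reference=["r"], window=1, pseudocount=0.0)
        raw = np.log2(m["q"] / m["r"])
        np.testing.assert_allclose(
            cnv.values["q"], raw / np.abs(np.log2(m / m["r"].to_numpy()[:, None])).max().max()
        )

    def test_smoothing_respects_chromosome_boundaries(self):
        meta = self._meta(40)
        meta.loc[meta.index[20:], "chrom"] = "chr2"
        m = pd.DataFrame(
            {"ref": np.full(40, 10.0), "q": np.r_[np.full(20, 40.0), np.full(20, 10.0)]},
            index=meta.index,
        )
        cnv = estimate_cnv_windowed(m, meta, reference=["ref"], window=9, pseudocount=0.0)
        # chr2 values would be dragged up if smoothing leaked across chroms
        np.testing.assert_allclose(cnv.values["q"].to_numpy()[20:], 0.0)

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            estimate_cnv_windowed(_matrix(), self._meta(30), reference=["a"], window=window)


class TestCnvScore:
    def test_quadratic_sum(self):
        assert cnv_score([0.5, -0.5]) == pytest.approx(0.5)

    def test_zero_profile(self):
        assert cnv_score(np.zeros(10)) == 0.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-1, 1, 20)
        flip = v.copy()
        flip[3] *= -1
        assert cnv_score(v) == pytest.approx(cnv_score(flip))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cnv_score([1.5])


class TestComputeExpectations:
    def test_means_without_outliers(self):
        scores = pd.Series({"a1": 0.1, "a2": 0.2, "t1": 0.8, "t2": 1.0})
        tissue = pd.Series({"a1": "adjacent", "a2": "adjacent", "t1": "tumor", "t2": "tumor"})
        exp = compute_expectations(scores, tissue)
        assert exp.normal_expectation == pytest.approx(0.15)
        assert exp.malignant_expectation == pytest.approx(0.9)
        assert exp.outliers_removed == []

    def test_adjacent_outlier_removed_before_recomputation(self):
        scores = pd.Series({"a1": 0.1, "a2": 0.95, "t1": 0.8, "t2": 1.0})
        tissue = pd.Series({"a1": "adjacent", "a2": "adjacent", "t1": "tumor", "t2": "tumor"})
        exp = compute_expectations(scores, tissue)  # initial me = 0.9 <= 0.95
        assert exp.outliers_removed == ["a2"]
        assert exp.normal_expectation == pytest.approx(0.1)

    def test_tumor_outlier_removed(self):
        scores = pd.Series({"a1": 0.2, "a2": 0.4, "t1": 0.1, "t2": 1.0})
        tissue = pd.Series({"a1": "adjacent", "a2": "adjacent", "t1": "tumor", "t2": "tumor"})
        exp = compute_expectations(scores, tissue)  # initial ne = 0.3 >= 0.1
        assert exp.outliers_removed == ["t1"]
        assert exp.malignant_expectation == pytest.approx(1.0)

    def test_identical_tissues_degenerate_flagged(self):
        # identical score sets: initial means coincide, the inclusive outlier
        # rule trims symmetrically and the ordering invariant still holds
        scores = pd.Series({"a1": 0.1, "a2": 0.2, "t1": 0.1, "t2": 0.2})
        tissue = pd.Series({"a1": "adjacent", "a2": "adjacent", "t1": "tumor", "t2": "tumor"})
        exp = compute_expectations(scores, tissue)
        assert exp.normal_expectation <= exp.malignant_expectation
        assert sorted(exp.outliers_removed) == ["a2", "t1"]

    def test_outlier_removal_emptying_a_tissue_errors(self):
        scores = pd.Series({"a1": 0.5, "t1": 0.5})
        tissue = pd.Series({"a1": "adjacent", "t1": "tumor"})
        with pytest.raises(ValueError):
            compute_expectations(scores, tissue)

    def test_missing_tissue_rejected(self):
        with pytest.raises(ValueError):
            compute_expectations(pd.Series({"a": 1.0}), pd.Series({"a": "adjacent"}))


class TestIterativeClassify:
    def _profiles(self, scores):
        # one-region profiles whose score equals value**2
        return pd.DataFrame({pb: [np.sqrt(s)] for pb, s in scores.items()}, index=["r1"])

    def test_separated_modes_resolve_in_one_round(self):
        scores = pd.Series({"n1": 0.01, "n2": 0.02, "m1": 0.9, "m2": 0.95})
        exp = Expectations(normal_expectation=0.05, malignant_expectation=0.8)
        out = iterative_classify(scores, self._profiles(scores), exp, k=2)
        direct = scores.map(lambda s: "normal" if s <= 0.05 else "malignant" if s >= 0.8 else "intermediate")
        assert (out.labels == direct).all()
        assert out.recursion_depth_used == 1

    def test_identical_profiles_between_expectations_stay_intermediate(self):
        scores = pd.Series({f"p{i}": 0.5 for i in range(6)})
        profiles = pd.DataFrame({pb: [0.7] for pb in scores.index}, index=["r1"])
        exp = Expectations(normal_expectation=0.1, malignant_expectation=0.9)
        out = iterative_classify(scores, profiles, exp, k=3, max_recursion=4)
        assert (out.labels == "intermediate").all()

    def test_boundary_score_equal_to_expectation_is_normal(self):
        scores = pd.Series({"p1": 0.1, "m1": 2.0})
        exp = Expectations(normal_expectation=0.1, malignant_expectation=1.5)
        out = iterative_classify(scores, self._profiles(scores), exp, k=2)
        assert out.labels["p1"] == "normal"

    def test_invalid_expectations_rejected(self):
        exp = Expectations(normal_expectation=0.9, malignant_expectation=0.1)
        with pytest.raises(ValueError):
            iterative_classify(pd.Series({"p": 0.5}), self._profiles({"p": 0.5}), exp)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.uniform(0, 1, 40), index=[f"p{i}" for i in range(40)])
        profiles = pd.DataFrame(
            rng.normal(size=(6, 40)), columns=scores.index, index=[f"r{i}" for i in range(6)]
        )
        exp = Expectations(normal_expectation=0.3, malignant_expectation=0.7)
        a = iterative_classify(scores, profiles, exp, k=10)
        b = iterative_classify(scores, profiles, exp, k=10)
        assert (a.labels == b.labels).all()


class TestPropagateToCells:
    def test_inheritance_counts(self):
        labels = cnvclass.ClassLabels(
            labels=pd.Series({"p1": "malignant", "p2": "normal", "p3": "intermediate"}),
            recursion_depth_used=1,
        )
        members = {"p1": [f"c{i}" for i in range(40)], "p2": ["x"], "p3": ["y", "z"]}
        cells = propagate_to_cells(labels, members)
        assert cells.value_counts().to_dict() == {"malignant": 40, "intermediate": 2, "normal": 1}

    def test_duplicate_cell_rejected(self):
        labels = cnvclass.ClassLabels(
            labels=pd.Series({"p1": "normal", "p2": "normal"}), recursion_depth_used=1
        )
        with pytest.raises(ValueError):
            propagate_to_cells(labels, {"p1": ["c"], "p2": ["c"]})


class TestClassifierRecovery:
    def test_recovers_planted_clones(self, small_cnv_study):
        matrix, gene_meta, cell_meta = small_cnv_study
        res = classify_malignancy(
            matrix, gene_meta, cell_meta["group"],
            n_per_group={"tumor": 50, "adjacent": 35, "normal": 15},
        )
        truth = cell_meta["malignant"].map({True: "malignant", False: "normal"})
        acc = (res.cell_labels.reindex(truth.index) == truth).mean()
        assert acc >= 0.95
        assert res.expectations.normal_expectation < res.expectations.malignant_expectation
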