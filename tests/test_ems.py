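"""Coherence, turnover, boundary clumping and the structure decision tree."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metacommunity.ems import (
    ClumpingResult,
    NullModelConfig,
    NullSummary,
    boundary_clumping,
    boundary_counts,
    classify,
    count_embedded_absences,
    count_replacements,
    ems_analysis,
    fill_ranges,
    morisita_index,
    simulate_coherence_null,
    simulate_turnover_null,
)
from metacommunity.ordination import correspondence_ordination

from conftest import brute_embedded_absences, brute_replacements, random_binary


class TestEmbeddedAbsences:
    def test_single_gap_column(self):
        m = np.array([[1], [0], [1]])
        # one interruption in the column; rows are single cells (no gaps)
        assert count_embedded_absences(m) == 1
        assert count_embedded_absences(m, axis="columns") == 1

    def test_contiguous_matrix_has_none(self):
        m = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]])
        assert count_embedded_absences(m) == 0

    def test_hand_enumerated_4x4(self):
        m = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 1], [0, 0, 0, 1]])
        # columns: one gap in column 2; rows: one gap in row 2
        assert count_embedded_absences(m) == 2
        assert count_embedded_absences(m) == brute_embedded_absences(m)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 7)), int(rng.integers(2, 7)))
        m = (rng.random(shape) < 0.5).astype(np.int8)
        for axis in ("both", "columns"):
            assert count_embedded_absences(m, axis=axis) == brute_embedded_absences(m, axis)


class TestFillRanges:
    def test_fills_single_gap(self):
        m = np.array([[1], [0], [1]])
        assert fill_ranges(m).tolist() == [[1], [1], [1]]

    def test_coherent_matrix_unchanged(self):
        m = np.array([[1, 0], [1, 1], [0, 1]])
        assert np.array_equal(fill_ranges(m), m)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_idempotent_and_gapless(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((6, 5)) < 0.4).astype(np.int8)
        filled = fill_ranges(m)
        assert np.all(filled >= m)
        assert np.array_equal(fill_ranges(filled), filled)
        assert count_embedded_absences(filled, axis="columns") == 0


class TestReplacements:
    def test_disjoint_pair_has_four(self):
        m = np.zeros((4, 2), dtype=int)
        m[[0, 1], 0] = 1
        m[[2, 3], 1] = 1
        assert count_replacements(m) == 4

    def test_subset_pair_has_none(self):
        m = np.zeros((4, 2), dtype=int)
        m[[0, 1, 2, 3], 0] = 1
        m[[1, 2], 1] = 1
        assert count_replacements(m) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadruple_loop(self, seed):
        rng = np.random.default_rng(seed + 50)
        m = (rng.random((5, 5)) < 0.5).astype(int)
        assert count_replacements(m) == brute_replacements(m)


class TestNullModels:
    def test_coherent_gradient_positive_coherence(self):
        # staggered bands: a perfectly coherent gradient matrix
        n, s = 20, 40
        m = np.zeros((n, s), np.int8)
        starts = (np.arange(s) * (n - 8)) // (s - 1)
        for j, a in enumerate(starts):
            m[a:a + 8, j] = 1
        ns = simulate_coherence_null(m, NullModelConfig(iterations=200, seed=4))
        assert ns.observed < ns.sim_mean
        assert ns.p < 0.05

    def test_turnover_null_mean_matches_exhaustive_enumeration(self):
        # two species of range length 2 on 4 sites: 3 x 3 equally likely
        # placements; replacements = d^2 for start offset d
        vals = [(abs(s1 - s2)) ** 2 for s1 in range(3) for s2 in range(3)]
        expected = np.mean(vals)
        m = np.zeros((4, 2), np.int8)
        m[0:2, 0] = 1
        m[1:3, 1] = 1
        ns = simulate_turnover_null(m, NullModelConfig("range_shift", 4000, seed=8))
        assert ns.sim_mean == pytest.approx(expected, rel=0.1)

    def test_full_range_species_degenerate(self):
        m = np.ones((5, 3), np.int8)
        ns = simulate_turnover_null(m, NullModelConfig("range_shift", 50, seed=0))
        assert ns.degenerate
        assert np.isnan(ns.p)

    def test_null_summary_z_identity(self):
        ns = NullSummary.from_simulations(5.0, [1.0, 2.0, 3.0])
        assert ns.z == pytest.approx((5.0 - ns.sim_mean) / ns.sim_sd)

    def test_seed_determinism(self):
        rng = np.random.default_rng(77)
        m = random_binary(rng, (10, 12))
        a = simulate_coherence_null(m, NullModelConfig(iterations=50, seed=5))
        b = simulate_coherence_null(m, NullModelConfig(iterations=50, seed=5))
        assert a == b


class TestBoundaryClumping:
    def test_maximal_clumping_closed_form(self):
        # all F boundaries at one of n positions: I = n
        f = np.array([6, 0, 0])
        assert morisita_index(f) == pytest.approx(3.0)

    def test_singleton_boundaries_closed_form(self):
        assert morisita_index(np.array([1, 1, 1, 1])) == 0.0

    def test_arithmetic_example(self):
        assert morisita_index(np.array([2, 2, 0])) == pytest.approx(1.0)

    def test_clumped_matrix_detected(self):
        # two compartments sharing identical range endpoints
        m = np.zeros((10, 12), np.int8)
        m[0:5, :6] = 1
        m[5:10, 6:] = 1
        res = boundary_clumping(m)
        assert res.morisita_index > 1
        assert res.p < 0.05

    def test_edge_censoring(self):
        # a species spanning the full gradient has no observable boundary
        m = np.column_stack([np.ones(6, np.int8), np.array([0, 1, 1, 0, 0, 0])])
        f = boundary_counts(m)
        assert f.sum() == 2  # only the interior start/end of species 2
        f_all = boundary_counts(m, include_edges=True)
        assert f_all.sum() == 4


class TestClassify:
    def _ns(self, observed, mean, p):
        return NullSummary(observed, mean, 1.0, observed - mean, p)

    def _cl(self, index, p):
        return ClumpingResult(index, 0.0, p, 5)

    def test_nonsignificant_coherence_is_random(self):
        lab = classify(self._ns(100, 105, 0.6), self._ns(0, 0, 1.0), self._cl(1.0, 0.5))
        assert lab.family == "random"

    def test_negative_coherence_is_checkerboard(self):
        lab = classify(self._ns(150, 100, 0.001), self._ns(0, 0, 1.0), self._cl(1.0, 0.5))
        assert lab.family == "checkerboard"

    def test_quasi_nested_clumped_loss(self):
        # positive coherence, non-significant negative turnover, I > 1 significant
        lab = classify(
            self._ns(94, 131, 1e-4), self._ns(1658, 2537, 0.271), self._cl(1.41, 0.008)
        )
        assert lab.family == "nested" and lab.quasi and lab.nested_loss == "clumped"

    def test_nested_random_loss(self):
        lab = classify(
            self._ns(57, 196, 1e-4), self._ns(1296, 1962, 0.003), self._cl(1.20, 0.107)
        )
        assert lab.family == "nested" and not lab.quasi and lab.nested_loss == "random"

    def test_positive_turnover_three_way_branch(self):
        coh = self._ns(50, 150, 1e-5)
        tur_sig = self._ns(3000, 2000, 0.01)
        assert classify(coh, tur_sig, self._cl(1.8, 0.01)).family == "clementsian"
        assert classify(coh, tur_sig, self._cl(0.5, 0.01)).family == "evenly_spaced"
        assert classify(coh, tur_sig, self._cl(1.1, 0.4)).family == "gleasonian"

    def test_label_consistency_invariant(self):
        with pytest.raises(ValueError):
            from metacommunity.ems import StructureLabel

            StructureLabel("gleasonian", nested_loss="clumped")


class TestEmsAnalysis:
    def test_same_seed_identical_result(self):
        rng = np.random.default_rng(3)
        m = random_binary(rng, (12, 15))
        a = ems_analysis(m, NullModelConfig(iterations=60, seed=9))
        b = ems_analysis(m, NullModelConfig(iterations=60, seed=9))
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_invariant_to_input_shuffling(self):
        rng = np.random.default_rng(21)
        m = random_binary(rng, (12, 15))
        shuffled = m[rng.permutation(12)][:, rng.permutation(15)]
        a = ems_analysis(m, NullModelConfig(iterations=60, seed=9))
        b = ems_analysis(shuffled, NullModelConfig(iterations=60, seed=9))
        assert a.coherence.observed == b.coherence.observed
        assert a.turnover.observed == b.turnover.observed
        assert a.clumping.morisita_index == pytest.approx(b.clumping.morisita_index)

    def test_degenerate_matrix_raises(self):
        from metacommunity.ordination import DegenerateOrdinationError

        with pytest.raises(DegenerateOrdinationError):
            ems_analysis(np.array([[1, 1], [1, 1]]), NullModelConfig(iterations=10, seed=0))


class TestTypeIError:
    """Both null-model tests keep their nominal size (checked at alpha=0.05)."""

    def test_coherence_on_iid_matrices(self):
        rejections = 0
        n_seeds = 200
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            m = (rng.random((20, 40)) < 0.5).astype(np.int8)
            m = m[m.sum(1) > 0][:, m.sum(0) > 0]
            ns = simulate_coherence_null(m, NullModelConfig(iterations=200, seed=s + 10_000))
            if ns.p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_seeds <= 0.10

    def test_turnover_on_uniform_range_placements(self):
        rejections = 0
        n_seeds = 200
        n, s_sp = 20, 40
        idx = np.arange(n)[:, None]
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            lengths = rng.integers(3, n, size=s_sp)
            starts = (rng.random(s_sp) * (n - lengths + 1)).astype(int)
            m = np.zeros((n, s_sp), np.int8)
            m[(idx >= starts) & (idx <= starts + lengths - 1)] = 1
            ns = simulate_turnover_null(m, NullModelConfig("range_shift", 200, seed=s + 20_000))
            if ns.p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_seeds <= 0.10
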